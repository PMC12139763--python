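"""Generator invariants: every planted intron satisfies the consensus
anatomy, datasets are deterministic under seed, and the documented fixtures
(trans-IEP genome, identical-intron pair) are present."""

import re

import numpy as np
import pytest
from scipy.stats import binom

from g2i.core_io import revcomp
from g2i.synthetic_data import (
    GeneratorConfig,
    generate_dataset,
    generate_intron,
    plant_intron,
    write_dataset,
)

GWYRG = re.compile(r"G[AT][CT][AG]G")


@pytest.mark.parametrize("subtype", ["IIA", "IIB", "IIC"])
@pytest.mark.parametrize("orf_mode", ["orfless", "rvt", "heg"])
def test_intron_anatomy_invariants(subtype, orf_mode):
    for seed in range(15):
        rng = np.random.default_rng(seed)
        seq, dm = generate_intron(subtype, orf_mode, rng)
        assert GWYRG.match(seq[:5]), "5' terminus must match GWYRG"
        assert seq[dm.d5.start : dm.d5.start + 3] in ("AGC", "CGC")
        assert seq[dm.branch_a] == "A"
        # branch point sits 7-8 nt from the intron 3' end
        assert 7 <= len(seq) - dm.branch_a - 1 <= 8
        # the bulged A is the single unpaired position of the D6 3' arm
        d6 = seq[dm.d6.start : dm.d6.end]
        assert len(d6) == 21
        # EBS loci recorded within D1 loops
        assert any(l.start <= dm.ebs1.start < l.end for l in dm.d1_loops)
        assert any(l.start <= dm.ebs2.start < l.end for l in dm.d1_loops)
        # length regimes
        if orf_mode == "orfless":
            assert 540 <= len(seq) <= 660
            assert dm.orf is None
        else:
            assert 1800 <= len(seq) <= 3300
            assert dm.orf is not None


def test_lambda_eps_feature_lengths_by_subtype():
    for seed in range(10):
        rng = np.random.default_rng(seed)
        for subtype, expected in (("IIA", 31), ("IIB", 36), ("IIC", 29)):
            seq, dm = generate_intron(subtype, "orfless", rng)
            assert len(dm.lambda_eps) == expected


def test_ebs_ibs_complementarity_after_planting(one_intron):
    from g2i.core_io import GenomeRecord

    seq, dm = one_intron
    rng = np.random.default_rng(3)
    host = GenomeRecord("h", "".join(np.random.default_rng(0).choice(list("ACGT"), size=2000)))
    rec, truth = plant_intron(host, seq, dm, 1000, "intergenic", rng)
    s = truth.intron_interval.start
    ibs1 = rec.seq[s - 6 : s]
    ibs2 = rec.seq[s - 11 : s - 6]
    assert ibs1 == revcomp(seq[dm.ebs1.start : dm.ebs1.end])
    assert ibs2 == revcomp(seq[dm.ebs2.start : dm.ebs2.end])


def test_plant_insertion_point_out_of_range(one_intron):
    from g2i.core_io import GenomeRecord

    seq, dm = one_intron
    host = GenomeRecord("h", "ACGT" * 100)
    with pytest.raises(ValueError, match="out of range"):
        plant_intron(host, seq, dm, 10_000, "intergenic", np.random.default_rng(0))


def test_truncated_plant_abuts_contig_end(one_intron):
    from g2i.core_io import GenomeRecord

    seq, dm = one_intron
    host = GenomeRecord("h", "".join(np.random.default_rng(5).choice(list("ACGT"), size=3000)))
    rec, truth = plant_intron(host, seq, dm, 1500, "truncated", np.random.default_rng(1))
    assert truth.intron_interval.end == len(rec.seq)
    assert len(rec.seq) < 1500 + len(seq)


def test_post_terminator_plant_fires_detector(one_intron):
    from g2i.boundary_context import detect_terminator
    from g2i.core_io import GenomeRecord

    seq, dm = one_intron
    host = GenomeRecord("h", "".join(np.random.default_rng(6).choice(list("ACGT"), size=3000)))
    rec, truth = plant_intron(host, seq, dm, 1500, "post_terminator", np.random.default_rng(2))
    s = truth.intron_interval.start
    fired, _ = detect_terminator(rec.seq[max(0, s - 200) : s])
    assert fired


def test_dataset_deterministic_under_seed(tmp_path):
    cfg = GeneratorConfig(n_genomes=12, seed=11)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_dataset(generate_dataset(cfg), d1)
    write_dataset(generate_dataset(cfg), d2)
    for name in ("genomes.fa", "truth.tsv", "truth.gff3", "homolog_proteins.faa"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name


def test_dedup_fixture_identical_pair(small_dataset):
    ds, _ = small_dataset
    seqs = {}
    rec = {r.id: r for r in ds.records}
    for t in ds.truths:
        iv = t.intron_interval
        seqs.setdefault(rec[t.genome_id].seq[iv.start : iv.end], []).append(t.genome_id)
    identical = [gids for gids in seqs.values() if len(gids) > 1]
    assert len(identical) == 1 and len(identical[0]) == 2


def test_trans_iep_fixture_present(small_dataset):
    ds, _ = small_dataset
    by_genome = {}
    for t in ds.truths:
        by_genome.setdefault(t.genome_id, []).append(t.orf_mode)
    assert any(
        modes.count("rvt") >= 1 and modes.count("orfless") >= 3
        for modes in by_genome.values()
    )


def test_carrier_rate_within_binomial_ci():
    cfg = GeneratorConfig(n_genomes=100, intron_prevalence=0.1, seed=7)
    ds = generate_dataset(cfg)
    carriers = len({t.genome_id for t in ds.truths})
    lo, hi = binom.ppf([0.005, 0.995], cfg.n_genomes, cfg.intron_prevalence)
    assert lo <= carriers <= hi


def test_truth_never_opened_by_pipeline(small_dataset, monkeypatch, tmp_path):
    """The pipeline must not read the truth files the generator wrote."""
    import builtins

    ds, out = small_dataset
    opened = []
    real_open = builtins.open

    def spy(file, *args, **kwargs):
        opened.append(str(file))
        return real_open(file, *args, **kwargs)

    monkeypatch.setattr(builtins, "open", spy)
    from g2i.pipeline import PipelineConfig, run_pipeline

    cfg = PipelineConfig(
        fasta=str(out / "genomes.fa"),
        homologs=str(out / "homolog_proteins.faa"),
        out_dir=str(tmp_path / "o"),
    )
    run_pipeline(cfg)
    in_dataset = [p for p in opened if p.startswith(str(out))]
    assert in_dataset, "pipeline should read the dataset inputs"
    assert not any("truth" in p for p in in_dataset)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        GeneratorConfig(n_genomes=0)
    with pytest.raises(ValueError):
        GeneratorConfig(intron_prevalence=1.5)
    with pytest.raises(ValueError):
        GeneratorConfig(subtype_weights={"IIA": 0.5, "IIB": 0.2, "IIC": 0.2})
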