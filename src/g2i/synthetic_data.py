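"""Phage-like synthetic genomes with planted group II introns and ground truth.

The generator emulates the statistical structure the analysis assumes, not
real phage composition: background sequence is i.i.d. over ACGT with
configurable GC, host genes are stop-free random-codon ORFs, and each planted
intron carries the full consensus anatomy — a GWYRG 5' terminus, D1 with EBS1
and EBS2 loops plus the tertiary-interaction partners, the lambda/epsilon'
subtype region (11-nt loop/AGC for IIA, 4-nt bulge/AARC for IIB, 7-12-nt
loop/AGG for IIC), D2-D4 (D4 hosting the intron-encoded ORF when present),
a D5 hairpin opening with an AGC/CGC catalytic triad, and a D6 helix with a
single bulged branch-point adenosine 7-8 nt from the intron 3' end.

ORF-less introns target ~600 nt and ORF-containing introns 2-3 kb. Intron
ORFs embed fixed sentinel peptide motifs (an RT-like token containing the
YADD reverse-transcriptase signature, a maturase-like token, and a
LAGLIDADG-containing endonuclease token) so ORF classification is testable
without external profile databases.

Exon rewriting at the insertion point makes IBS1 (last 6 nt of the 5' exon)
and IBS2 (the 5 nt 5' of IBS1) reverse-complement the intron's EBS1/EBS2,
mirroring homing-site complementarity. Truth is written to files the pipeline
never opens.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .core_io import GenomeRecord, Interval, revcomp, write_fasta
from .domains import DomainMap

SUBTYPES = ("IIA", "IIB", "IIC")
ORF_MODES = ("rvt", "heg", "orfless")
CONTEXTS = ("intragenic", "intergenic", "pseudogene", "truncated", "post_terminator")

#: sentinel peptide tokens embedded in generated intron ORFs
RT_SENTINEL = "GIRYADDMLV"  # RT-like; carries the YADD RT signature
MATURASE_SENTINEL = "WKQMAPGHLE"  # maturase-X-like token
HEG_SENTINEL = "NLAGLIDADGYE"  # endonuclease-like; carries LAGLIDADG

#: stops all three reading frames: TAA at offsets 0, 4 and 8
STOP_CASSETTE = "TAAATAAATAA"

STOP_CODONS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = sorted(
    c
    for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
    if c not in STOP_CODONS
)
_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in sorted(standard_dna_table.forward_table.items()):
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
AA_ALPHABET = sorted(_CODONS_BY_AA)

# Fixed helix arms of the lambda/epsilon' subtype region. 10-bp outer stems
# make the designed terminal ladder strictly the strongest in proximal D1,
# and the arms avoid AGC/AGG on both senses so the subtype consensus motifs
# occur only where planted.
_LE_ARM = "CTTACGGTAC"  # IIA / IIC outer stem (10 bp)
_LE_ARM_B1 = "CGTTACGTTC"  # IIB outer stem (10 bp)
_LE_ARM_B2 = "CTGC"  # IIB inner stem (4 bp)


@dataclass
class TruthRecord:
    """Ground truth for one planted intron (never read by the pipeline)."""

    genome_id: str
    intron_id: str
    intron_interval: Interval
    subtype: str
    orf_mode: str
    context: str
    domain_map: DomainMap
    homolog_id: str | None = None
    host_gene: Interval | None = None  # post-insertion gene extent incl. intron
    orf_interval: Interval | None = None  # intron-relative IEP/HEG ORF


@dataclass
class GeneratorConfig:
    n_genomes: int = 100
    intron_prevalence: float = 0.1
    subtype_weights: dict = field(
        default_factory=lambda: {"IIA": 0.15, "IIB": 0.80, "IIC": 0.05}
    )
    orf_mode_weights: dict = field(
        default_factory=lambda: {"rvt": 7 / 17, "heg": 4 / 17, "orfless": 6 / 17}
    )
    context_weights: dict = field(
        default_factory=lambda: {
            "intragenic": 0.80,
            "intergenic": 0.05,
            "pseudogene": 0.05,
            "truncated": 0.05,
            "post_terminator": 0.05,
        }
    )
    orfless_len: int = 600
    orf_len_range: tuple[int, int] = (2000, 3000)
    genome_len: int = 12000
    gc: float = 0.5
    seed: int = 7
    ensure_fixtures: bool = True  # force trans-IEP, dedup and context fixtures

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if not 0.0 <= self.intron_prevalence <= 1.0:
            raise ValueError("intron_prevalence must be in [0,1]")
        for name, w in (
            ("subtype_weights", self.subtype_weights),
            ("orf_mode_weights", self.orf_mode_weights),
            ("context_weights", self.context_weights),
        ):
            vals = list(w.values())
            if any(v < 0 for v in vals):
                raise ValueError(f"{name}: negative weight")
            if abs(sum(vals) - 1.0) > 1e-6:
                raise ValueError(f"{name}: weights must sum to 1")


# --- low-level sequence helpers -------------------------------------------


def _rng(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def _bg_ac(rng, n: int) -> str:
    """Unpairable linker/loop filler drawn from {A,G}.

    {A,G} admits no canonical or wobble pair on either strand sense: the
    plus sense lacks T and C, and the complement {C,T} lacks G and A, so
    filler never forms helices that confuse the structure detectors.
    """
    return "".join(rng.choice(["A", "G"], size=n))


def _bg_acgt(rng, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(["A", "C", "G", "T"], size=n, p=p))


def _motif(rng, n: int) -> str:
    return "".join(rng.choice(["A", "C", "G", "T"], size=n))


def _sense_codons(rng, n: int) -> str:
    return "".join(rng.choice(SENSE_CODONS, size=n))


def _aa_to_dna(rng, protein: str) -> str:
    return "".join(rng.choice(_CODONS_BY_AA[aa]) for aa in protein)


def _weighted_choice(rng, weights: dict) -> str:
    keys = sorted(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return str(rng.choice(keys, p=p / p.sum()))


# --- intron construction ---------------------------------------------------


def _lambda_eps_region(subtype: str, rng) -> tuple[str, str, int]:
    """Sequence of the lambda/epsilon' subtype region, its feature sequence,
    and the feature offset within the region."""
    if subtype == "IIA":
        loop = _bg_ac(rng, 4) + "AGC" + _bg_ac(rng, 4)  # 11 nt, contains AGC
        return _LE_ARM + loop + revcomp(_LE_ARM), loop, len(_LE_ARM)
    if subtype == "IIC":
        loop = _bg_ac(rng, 3) + "AGG" + _bg_ac(rng, 3)  # 9 nt, contains AGG
        return _LE_ARM + loop + revcomp(_LE_ARM), loop, len(_LE_ARM)
    if subtype == "IIB":
        bulge = "AA" + str(rng.choice(["A", "G"])) + "C"  # AARC
        seq = (
            _LE_ARM_B1
            + bulge
            + _LE_ARM_B2
            + _bg_ac(rng, 4)
            + revcomp(_LE_ARM_B2)
            + revcomp(_LE_ARM_B1)
        )
        return seq, bulge, len(_LE_ARM_B1)
    raise ValueError(f"unknown subtype {subtype!r}")


def _orf_protein(rng, n_aa: int, orf_mode: str) -> str:
    """Random protein with sentinel tokens at fixed relative positions."""
    core = "".join(rng.choice(AA_ALPHABET, size=n_aa))
    if orf_mode == "rvt":
        p1 = n_aa // 4
        p2 = n_aa // 2
        core = (
            core[:p1]
            + RT_SENTINEL
            + core[p1 + len(RT_SENTINEL) : p2]
            + MATURASE_SENTINEL
            + core[p2 + len(MATURASE_SENTINEL) :]
        )
    elif orf_mode == "heg":
        p1 = (2 * n_aa) // 5
        core = core[:p1] + HEG_SENTINEL + core[p1 + len(HEG_SENTINEL) :]
    return "M" + core[1:]


def _d4_filler(rng, n: int) -> str:
    """AC filler with stop cassettes roughly every 45 nt so no reading frame
    accumulates a long stop-free stretch."""
    out: list[str] = []
    remaining = n
    while remaining > 0:
        chunk = min(remaining, 45)
        if chunk >= len(STOP_CASSETTE) + 4:
            pad = chunk - len(STOP_CASSETTE)
            out.append(_bg_ac(rng, pad // 2) + STOP_CASSETTE + _bg_ac(rng, pad - pad // 2))
        else:
            out.append(_bg_ac(rng, chunk))
        remaining -= chunk
    return "".join(out)


def generate_intron(
    subtype: str, orf_mode: str, rng_or_seed, cfg: GeneratorConfig | None = None
) -> tuple[str, DomainMap]:
    """Build one intron sequence with its exact DomainMap.

    Total length is the orfless target (default 600 nt) with +-10% uniform
    jitter for orfless introns, or uniform in orf_len_range (default
    2000-3000 nt) for ORF-carrying introns.
    """
    if subtype not in SUBTYPES:
        raise ValueError(f"unknown subtype {subtype!r}")
    if orf_mode not in ORF_MODES:
        raise ValueError(f"unknown orf_mode {orf_mode!r}")
    rng = _rng(rng_or_seed)
    cfg = cfg or GeneratorConfig()

    parts: list[str] = []
    marks: dict[str, Interval] = {}
    pos = 0

    def add(seq: str, name: str | None = None) -> None:
        nonlocal pos
        parts.append(seq)
        if name:
            marks[name] = Interval(pos, pos + len(seq))
        pos += len(seq)

    # 5' terminus and EBS loci. Redraw until the insertion junction
    # (IBS2+IBS1 followed by the intron head) contains exactly one GWYRG
    # occurrence, at the splice site itself: planted truth boundaries must
    # be well-posed, not ambiguous by construction.
    from .candidate_scan import GWYRG_RE

    for _ in range(100):
        gwyrg = (
            "G"
            + str(rng.choice(["A", "T"]))
            + str(rng.choice(["C", "T"]))
            + str(rng.choice(["A", "G"]))
            + "G"
        )
        eps_prime = _motif(rng, 4)
        head_pad = _bg_ac(rng, 2)
        ebs1 = _motif(rng, 6)
        ebs2 = _motif(rng, 5)
        junction = revcomp(ebs2) + revcomp(ebs1) + gwyrg + eps_prime + head_pad
        if [m.start() for m in GWYRG_RE.finditer(junction)] == [11]:
            break
    add(gwyrg, "gwyrg")
    add(eps_prime, "eps_prime")
    add(head_pad)

    # D1: closing helix H1 around interior loops carrying the pairing loci
    d1_start = pos
    h1 = _motif(rng, 12)
    add(h1, "h1_open")
    add(_bg_ac(rng, 1))  # buffers keep the closing helix exactly 12 bp
    alpha = _motif(rng, 5)
    add(alpha, "alpha")
    add(_bg_ac(rng, 3))
    beta = _motif(rng, 5)
    add(beta, "beta")
    add(_bg_ac(rng, 2))
    lam = _motif(rng, 4)
    add(lam, "lambda")
    le_seq, _feat, _off = _lambda_eps_region(subtype, rng)
    add(le_seq, "lambda_eps")
    add(_bg_ac(rng, 2))
    add(revcomp(alpha), "alpha_prime")
    add(_bg_ac(rng, 2))
    add(revcomp(beta), "beta_prime")
    add(_bg_ac(rng, 2))
    add(revcomp(eps_prime), "eps")
    add(_bg_ac(rng, 2))
    zeta = _motif(rng, 4)
    add(zeta, "zeta")
    add(_bg_ac(rng, 2))
    # EBS2 hairpin
    st = _motif(rng, 4)
    add(st)
    ebs2_loop_start = pos
    add(_bg_ac(rng, 1))
    add(ebs2, "ebs2")
    add(_bg_ac(rng, 1))
    ebs2_loop = Interval(ebs2_loop_start, pos)
    add(revcomp(st))
    add(_bg_ac(rng, 2))
    # EBS1 hairpin
    st1 = _motif(rng, 4)
    add(st1)
    ebs1_loop_start = pos
    add(_bg_ac(rng, 1))
    add(ebs1, "ebs1")
    add(_bg_ac(rng, 1))
    ebs1_loop = Interval(ebs1_loop_start, pos)
    add(revcomp(st1))
    add(_bg_ac(rng, 2))
    add(_bg_ac(rng, 1))
    add(revcomp(h1), "h1_close")
    d1 = Interval(d1_start, pos)

    add(_bg_ac(rng, 3))  # J1/2
    # D2 with kappa in its loop
    st2 = _motif(rng, 4)
    d2_start = pos
    add(st2)
    add(_bg_ac(rng, 1))
    kappa = _motif(rng, 4)
    add(kappa, "kappa")
    add(_bg_ac(rng, 1))
    add(revcomp(st2))
    d2 = Interval(d2_start, pos)
    # J2/3 carries gamma
    add(_bg_ac(rng, 1))
    gamma = _motif(rng, 4)
    add(gamma, "gamma")
    add(_bg_ac(rng, 1))
    # D3 with delta in its loop
    st3 = _motif(rng, 4)
    d3_start = pos
    add(st3)
    add(_bg_ac(rng, 1))
    delta = _motif(rng, 4)
    add(delta, "delta")
    add(_bg_ac(rng, 1))
    add(revcomp(st3))
    d3 = Interval(d3_start, pos)
    add(_bg_ac(rng, 3))  # J3/4

    # everything downstream of D4 has fixed length; compute it to size D4
    tail_len = 2 + 4 + 4 + 2 + 22 + 9 + 21  # J4/5 + D5 + J5/6 + D6
    if orf_mode == "orfless":
        target = int(round(cfg.orfless_len * rng.uniform(0.9, 1.1)))
        d4_len = max(30, target - pos - tail_len)
        d4_start = pos
        add(_d4_filler(rng, d4_len))
        d4 = Interval(d4_start, pos)
        orf_iv = None
    else:
        target = int(round(rng.uniform(*cfg.orf_len_range)))
        overhead = len(STOP_CASSETTE) * 2 + 4
        n_aa = max(150, (target - pos - tail_len - overhead - 6) // 3 - 1)
        protein = _orf_protein(rng, n_aa, orf_mode)
        orf_dna = "ATG" + _aa_to_dna(rng, protein[1:]) + "TAA"
        d4_start = pos
        add(STOP_CASSETTE + _bg_ac(rng, 2))
        orf_iv = Interval(pos, pos + len(orf_dna))
        add(orf_dna, "orf")
        add(_bg_ac(rng, 2) + STOP_CASSETTE)
        d4 = Interval(d4_start, pos)

    # J4/5 with lambda' and kappa'
    add(_bg_ac(rng, 2))
    add(revcomp(lam), "lambda_prime")
    add(revcomp(kappa), "kappa_prime")
    add(_bg_ac(rng, 2))

    # D5: triad-opened hairpin, 9-bp stem, loop = zeta'
    triad = str(rng.choice(["AGC", "CGC"], p=[0.75, 0.25]))
    arm5 = triad + _motif(rng, 6)
    d5_start = pos
    add(arm5)
    d5_loop = Interval(pos, pos + 4)
    add(revcomp(zeta), "zeta_prime")
    add(revcomp(arm5))
    d5 = Interval(d5_start, pos)

    # J5/6 with gamma' and delta'
    add(revcomp(gamma), "gamma_prime")
    add(revcomp(delta), "delta_prime")
    add(_bg_ac(rng, 1))

    # D6: 8-bp stem with the single bulged branch-point A on the 3' arm
    arm6 = _motif(rng, 7) + str(rng.choice(["G", "A"]))
    d6_start = pos
    rc6 = revcomp(arm6)
    d6_seq = arm6 + _bg_ac(rng, 4) + rc6[0] + "A" + rc6[1:]
    add(d6_seq)
    d6 = Interval(d6_start, pos)
    branch_a = d6.end - 8  # 7 nt follow the bulged A

    seq = "".join(parts)
    assert len(seq) == pos
    assert seq[branch_a] == "A"

    dm = DomainMap(
        d1=d1,
        d2=d2,
        d3=d3,
        d4=d4,
        d5=d5,
        d6=d6,
        triad=d5.start,
        branch_a=branch_a,
        ebs1=marks["ebs1"],
        ebs2=marks["ebs2"],
        d1_loops=[ebs2_loop, ebs1_loop],
        lambda_eps=marks["lambda_eps"],
        d5_loop=d5_loop,
        interactions={
            "alpha": (marks["alpha"], marks["alpha_prime"]),
            "beta": (marks["beta"], marks["beta_prime"]),
            "gamma": (marks["gamma"], marks["gamma_prime"]),
            "delta": (marks["delta"], marks["delta_prime"]),
            "epsilon": (marks["eps"], marks["eps_prime"]),
            "lambda": (marks["lambda"], marks["lambda_prime"]),
            "kappa": (marks["kappa"], marks["kappa_prime"]),
            "zeta": (marks["zeta"], marks["zeta_prime"]),
        },
    )
    dm.orf = orf_iv
    return seq, dm


# --- host genomes and planting ---------------------------------------------


@dataclass
class _HostGenome:
    seq: str
    genes: list[Interval]


def _random_host(rng, length: int, gc: float) -> _HostGenome:
    parts: list[str] = []
    genes: list[Interval] = []
    pos = 0
    while pos < length:
        gap = int(rng.integers(80, 200))
        parts.append(_bg_acgt(rng, gap, gc))
        pos += gap
        if pos >= length:
            break
        gene = "ATG" + _sense_codons(rng, 298) + "TAA"
        genes.append(Interval(pos, pos + len(gene)))
        parts.append(gene)
        pos += len(gene)
    return _HostGenome("".join(parts), genes)


def _rewrite_ibs(seq: str, ip: int, dm: DomainMap, intron_seq: str) -> str:
    """Rewrite the 11 nt 5' of the insertion point so IBS1/IBS2 complement
    the intron's EBS1/EBS2."""
    ibs1 = revcomp(intron_seq[dm.ebs1.start : dm.ebs1.end])
    ibs2 = revcomp(intron_seq[dm.ebs2.start : dm.ebs2.end])
    block = ibs2 + ibs1
    if ip < len(block):
        raise ValueError("insertion point too close to contig start")
    return seq[: ip - len(block)] + block + seq[ip:]


def _creates_stop_in_gene(seq: str, gene: Interval, lo: int, hi: int) -> bool:
    """True if any codon of `gene` overlapping [lo,hi) is a stop."""
    c0 = gene.start + ((lo - gene.start) // 3) * 3
    for c in range(max(gene.start, c0), min(hi + 2, gene.end - 2), 3):
        if (c - gene.start) % 3 == 0 and seq[c : c + 3] in STOP_CODONS:
            return True
    return False


def plant_intron(
    host: GenomeRecord,
    intron_seq: str,
    dm: DomainMap,
    insertion_point: int,
    context: str,
    rng,
    intron_id: str = "i1",
) -> tuple[GenomeRecord, TruthRecord]:
    """Insert an intron at insertion_point with exon rewriting and
    context-specific dressing (terminator upstream, contig truncation)."""
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    if not 11 <= insertion_point <= len(host.seq):
        raise ValueError(
            f"insertion point {insertion_point} out of range for {host.id}"
        )
    seq = host.seq
    ip = insertion_point
    if context == "post_terminator":
        arm = "".join(rng.choice(["G", "C"], size=7)) + str(rng.choice(["A", "T"]))
        terminator = arm + _bg_ac(rng, 4) + revcomp(arm) + _bg_ac(rng, 2) + "TTTTTT"
        spacer = _bg_acgt(rng, 9, 0.5)
        ibs1 = revcomp(intron_seq[dm.ebs1.start : dm.ebs1.end])
        ibs2 = revcomp(intron_seq[dm.ebs2.start : dm.ebs2.end])
        block = terminator + spacer + ibs2 + ibs1
        seq = seq[:ip] + block + seq[ip:]
        ip = ip + len(block)
    else:
        seq = _rewrite_ibs(seq, ip, dm, intron_seq)
    mutated = seq[:ip] + intron_seq + seq[ip:]
    interval = Interval(ip, ip + len(intron_seq))
    if context == "truncated":
        clip = 2  # into the terminal D6 arm: intron runs off the contig
        mutated = mutated[: ip + len(intron_seq) - clip]
        interval = Interval(ip, len(mutated))
    rec = GenomeRecord(id=host.id, seq=mutated, circular=host.circular)
    truth = TruthRecord(
        genome_id=host.id,
        intron_id=f"{host.id}.{intron_id}",
        intron_interval=interval,
        subtype="",
        orf_mode="",
        context=context,
        domain_map=dm,
    )
    return rec, truth


# --- dataset generation -----------------------------------------------------


def _decay_gene(seq: str, gene: Interval, ip: int, rng) -> str:
    """Plant 3 in-frame stop codons in a gene: one on each side near the
    insertion point (so no stop-free frame spans the future junction) and
    one elsewhere, all clear of the 11-nt IBS rewrite window."""
    def frame_codons(lo: int, hi: int) -> list[int]:
        c0 = gene.start + ((lo - gene.start + 2) // 3) * 3
        return [c for c in range(c0, hi - 2, 3) if gene.start <= c < gene.end - 3]

    near_up = frame_codons(ip - 140, ip - 25)
    near_dn = frame_codons(ip + 25, ip + 140)
    anywhere = [c for c in frame_codons(gene.start + 30, gene.end - 30) if abs(c - ip) > 160]
    out = list(seq)
    for pool in (near_up, near_dn, anywhere):
        c = pool[int(rng.integers(0, len(pool)))]
        out[c : c + 3] = str(rng.choice(sorted(STOP_CODONS)))
    return "".join(out)


@dataclass
class SyntheticDataset:
    records: list[GenomeRecord]
    truths: list[TruthRecord]
    homolog_proteins: dict[str, str]
    config: GeneratorConfig


def _plant_in_gene(
    rng,
    host: _HostGenome,
    gene_idx: int,
    intron_seq: str,
    dm: DomainMap,
    decay: bool = False,
) -> tuple[str, int, Interval]:
    """Pick a stop-safe insertion point inside a gene, rewrite IBS, insert.

    Returns (new sequence, insertion point, post-insertion gene extent).
    """
    gene = host.genes[gene_idx]
    lo = gene.start + 420 if decay else gene.start + 150
    hi = gene.end - 420 if decay else gene.end - 150
    candidates = list(range(lo, hi))
    rng.shuffle(candidates)
    seq = host.seq
    if decay:
        probe = candidates[0]
        seq = _decay_gene(seq, gene, probe, rng)
        candidates = [probe]
    for ip in candidates:
        trial = _rewrite_ibs(seq, ip, dm, intron_seq)
        if decay or not _creates_stop_in_gene(trial, gene, ip - 11, ip):
            new_seq = trial[:ip] + intron_seq + trial[ip:]
            post_gene = Interval(gene.start, gene.end + len(intron_seq))
            return new_seq, ip, post_gene
    raise RuntimeError("no stop-safe insertion point found")  # pragma: no cover


def _translate_gene(seq: str, gene: Interval) -> str:
    from Bio.Seq import Seq

    prot = str(Seq(seq[gene.start : gene.end]).translate())
    return prot.rstrip("*")


def generate_dataset(
    config: GeneratorConfig | None = None, out_dir: str | Path | None = None
) -> SyntheticDataset:
    """Generate the full synthetic dataset, deterministically under seed.

    Fixtures (when enough intron-carrying genomes are drawn): one genome with
    one RVT intron plus three orfless introns (trans-IEP borrowing), two
    genomes with byte-identical intron regions (deduplication), and one
    genome each for the truncated, post-terminator, pseudogene and intergenic
    contexts. Remaining carriers draw subtype/ORF-mode/context from the
    configured weights. Per-genome random streams are split from the top
    seed, so one genome's content never depends on another's.
    """
    cfg = config or GeneratorConfig()
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_genomes + 2)
    shared_rng = np.random.default_rng(children[cfg.n_genomes])

    # pass 1: carrier draws (first draw of each per-genome stream)
    rngs = [np.random.default_rng(children[i]) for i in range(cfg.n_genomes)]
    carriers = [i for i in range(cfg.n_genomes) if rngs[i].random() < cfg.intron_prevalence]
    if cfg.ensure_fixtures:
        want = min(7, max(0, cfg.n_genomes - 3))
        extra = [i for i in range(cfg.n_genomes) if i not in carriers]
        while len(carriers) < want and extra:
            carriers.append(extra.pop(0))
        carriers.sort()

    roles: dict[int, str] = {}
    role_order = [
        "trans_iep",
        "dedup_a",
        "dedup_b",
        "truncated",
        "post_terminator",
        "pseudogene",
        "intergenic",
    ]
    for idx, role in zip(carriers, role_order):
        roles[idx] = role

    # the dedup pair shares one intron drawn from a dedicated stream
    shared_subtype = _weighted_choice(shared_rng, cfg.subtype_weights)
    shared_intron, shared_dm = generate_intron(shared_subtype, "orfless", shared_rng, cfg)

    records: list[GenomeRecord] = []
    truths: list[TruthRecord] = []

    for i in range(cfg.n_genomes):
        gid = f"SYN{i:04d}"
        rng = rngs[i]
        host = _random_host(rng, cfg.genome_len, cfg.gc)
        if i not in carriers:
            records.append(GenomeRecord(id=gid, seq=host.seq))
            continue
        role = roles.get(i, "weighted")
        if role == "trans_iep":
            plan = ["rvt", "orfless", "orfless", "orfless"]
            seq = host.seq
            gene_picks = sorted(rng.choice(len(host.genes), size=4, replace=False))
            offset = 0
            for k, orf_mode in enumerate(plan):
                subtype = _weighted_choice(rng, cfg.subtype_weights)
                iseq, dm = generate_intron(subtype, orf_mode, rng, cfg)
                g = host.genes[int(gene_picks[k])]
                shifted = _HostGenome(seq, [Interval(g.start + offset, g.end + offset)])
                seq, ip, post_gene = _plant_in_gene(rng, shifted, 0, iseq, dm)
                truths.append(
                    TruthRecord(
                        genome_id=gid,
                        intron_id=f"{gid}.i{k + 1}",
                        intron_interval=Interval(ip, ip + len(iseq)),
                        subtype=subtype,
                        orf_mode=orf_mode,
                        context="intragenic",
                        domain_map=dm,
                        host_gene=post_gene,
                        orf_interval=dm.orf,
                    )
                )
                offset += len(iseq)
            records.append(GenomeRecord(id=gid, seq=seq))
            continue

        # single-intron carriers
        if role in ("dedup_a", "dedup_b"):
            subtype, orf_mode, context = shared_subtype, "orfless", "intragenic"
            iseq, dm = shared_intron, shared_dm
        else:
            subtype = _weighted_choice(rng, cfg.subtype_weights)
            orf_mode = _weighted_choice(rng, cfg.orf_mode_weights)
            context = (
                role if role in CONTEXTS else _weighted_choice(rng, cfg.context_weights)
            )
            iseq, dm = generate_intron(subtype, orf_mode, rng, cfg)

        if context in ("intragenic", "pseudogene"):
            gene_idx = int(rng.integers(0, len(host.genes)))
            seq, ip, post_gene = _plant_in_gene(
                rng, host, gene_idx, iseq, dm, decay=(context == "pseudogene")
            )
            rec = GenomeRecord(id=gid, seq=seq)
            truth = TruthRecord(
                genome_id=gid,
                intron_id=f"{gid}.i1",
                intron_interval=Interval(ip, ip + len(iseq)),
                subtype=subtype,
                orf_mode=orf_mode,
                context=context,
                domain_map=dm,
                host_gene=post_gene,
                orf_interval=dm.orf,
            )
        else:
            # intergenic-like placements: pick a gap between genes
            gaps = []
            prev = 0
            for g in host.genes:
                if g.start - prev >= 120:
                    gaps.append((prev, g.start))
                prev = g.end
            lo, hi = gaps[int(rng.integers(0, len(gaps)))]
            ip = int((lo + hi) // 2)
            rec, truth = plant_intron(
                GenomeRecord(id=gid, seq=host.seq), iseq, dm, ip, context, rng
            )
            truth.subtype = subtype
            truth.orf_mode = orf_mode
            truth.orf_interval = dm.orf
        records.append(rec)
        truths.append(truth)

    # place intronless homolog genes in non-carrier genomes
    from Bio.Seq import Seq

    homolog_proteins: dict[str, str] = {}
    carrier_ids = {t.genome_id for t in truths}
    non_carriers = [r for r in records if r.id not in carrier_ids]
    rec_by_id = {r.id: r for r in records}
    k = 0
    for t in truths:
        if t.context != "intragenic" or t.host_gene is None:
            continue
        src = rec_by_id[t.genome_id]
        g, iv = t.host_gene, t.intron_interval
        gene_dna = src.seq[g.start : iv.start] + src.seq[iv.end : g.end]
        prot = str(Seq(gene_dna).translate()).rstrip("*")
        if non_carriers:
            target = non_carriers[k % len(non_carriers)]
            k += 1
            mid = len(target.seq) // 2
            target.seq = target.seq[:mid] + gene_dna + target.seq[mid:]
            t.homolog_id = target.id
            homolog_proteins[f"{target.id}|homolog_{t.intron_id}"] = prot
        else:  # pragma: no cover - degenerate tiny configs
            homolog_proteins[f"unplaced|homolog_{t.intron_id}"] = prot

    ds = SyntheticDataset(records, truths, homolog_proteins, cfg)
    if out_dir is not None:
        write_dataset(ds, out_dir)
    return ds


TRUTH_COLUMNS = [
    "genome_id", "intron_id", "start", "end", "strand", "subtype", "orf_mode",
    "context", "homolog_id", "triad_pos", "branch_a", "ebs1_start", "ebs1_end",
    "ebs2_start", "ebs2_end", "lambda_eps_start", "lambda_eps_end",
    "orf_start", "orf_end", "host_gene_start", "host_gene_end",
]


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> None:
    """Write genomes.fa, truth.tsv, truth.gff3 and homolog_proteins.faa."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(ds.records, out / "genomes.fa")
    import pandas as pd

    rows = []
    for t in ds.truths:
        dm = t.domain_map
        rows.append(
            {
                "genome_id": t.genome_id,
                "intron_id": t.intron_id,
                "start": t.intron_interval.start,
                "end": t.intron_interval.end,
                "strand": "+",
                "subtype": t.subtype,
                "orf_mode": t.orf_mode,
                "context": t.context,
                "homolog_id": t.homolog_id or "",
                "triad_pos": dm.triad,
                "branch_a": dm.branch_a,
                "ebs1_start": dm.ebs1.start,
                "ebs1_end": dm.ebs1.end,
                "ebs2_start": dm.ebs2.start,
                "ebs2_end": dm.ebs2.end,
                "lambda_eps_start": dm.lambda_eps.start,
                "lambda_eps_end": dm.lambda_eps.end,
                "orf_start": t.orf_interval.start if t.orf_interval else "",
                "orf_end": t.orf_interval.end if t.orf_interval else "",
                "host_gene_start": t.host_gene.start if t.host_gene else "",
                "host_gene_end": t.host_gene.end if t.host_gene else "",
            }
        )
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(
        out / "truth.tsv", sep="\t", index=False
    )
    from .core_io import GffFeature, write_gff3

    feats = [
        GffFeature(
            t.genome_id,
            "group_II_intron",
            t.intron_interval,
            None,
            {"ID": t.intron_id, "subtype": t.subtype, "context": t.context,
             "orf_mode": t.orf_mode},
        )
        for t in ds.truths
    ]
    write_gff3(feats, out / "truth.gff3")
    write_fasta(sorted(ds.homolog_proteins.items()), out / "homolog_proteins.faa")
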