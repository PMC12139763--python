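import numpy as np
import pytest

from g2i.core_io import GenomeRecord, revcomp
from g2i.synthetic_data import GeneratorConfig, generate_dataset, generate_intron


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """30-genome synthetic dataset with files on disk (session-shared)."""
    out = tmp_path_factory.mktemp("ds")
    cfg = GeneratorConfig(n_genomes=30, seed=7)
    ds = generate_dataset(cfg, out)
    return ds, out


def embed_intron(rng, seq, dm, flank=300):
    """Place an intron in random flanks with a complementary IBS junction."""
    letters = np.array(list("ACGT"))
    up = "".join(rng.choice(letters, size=flank))
    down = "".join(rng.choice(letters, size=flank))
    ibs = revcomp(seq[dm.ebs2.start : dm.ebs2.end]) + revcomp(
        seq[dm.ebs1.start : dm.ebs1.end]
    )
    genome = GenomeRecord("embed", up[:-11] + ibs + seq + down)
    return genome, flank, flank + len(seq)


@pytest.fixture
def one_intron():
    rng = np.random.default_rng(1)
    seq, dm = generate_intron("IIA", "orfless", rng)
    return seq, dm
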