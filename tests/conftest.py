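import numpy as np
import pytest

from mitotfbs.genome import CircularGenome, GeneAnnotation
from mitotfbs.motif import PositionFrequencyMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sharp_pfm():
    """AP-1-like TGACTCA with strong consensus columns."""
    consensus = "TGACTCA"
    counts = np.full((4, len(consensus)), 2.0)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i, b in enumerate(consensus):
        counts[base_idx[b], i] = 94.0
    return PositionFrequencyMatrix("AP1like", counts)


@pytest.fixture
def small_genome(rng):
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=200)])
    return CircularGenome("mini", seq)


@pytest.fixture
def plus_gene():
    return GeneAnnotation("gplus", 101, 160, "+", 0)
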