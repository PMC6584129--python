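import numpy as np
import pytest

from lsr2tools.annotation import ChromosomeRegions, ClusterDef, GeneModel
from lsr2tools.sequence import NucSequence


@pytest.fixture
def rng():
    return np.random.default_rng(20191)


@pytest.fixture
def small_genes():
    """Ten genes on a 10 kb chromosome, alternating strands."""
    genes = []
    for i in range(10):
        start = 500 + i * 900
        genes.append(
            GeneModel(
                locus_id=f"SYN_{i + 1:04d}",
                start=start,
                end=start + 600,
                strand="+" if i % 2 == 0 else "-",
            )
        )
    return genes


@pytest.fixture
def small_clusters():
    return [
        ClusterDef(name="clusterA", first_locus="SYN_0002", last_locus="SYN_0004"),
        ClusterDef(name="clusterB", first_locus="SYN_0008", last_locus="SYN_0009"),
    ]


@pytest.fixture
def small_regions():
    return ChromosomeRegions(left_arm=(1, 2500), core=(2501, 7500), right_arm=(7501, 10000))


def random_sequence(rng, length, p_at=0.5):
    at = rng.random(length) < p_at
    pick = rng.integers(0, 2, length)
    letters = np.where(at, np.where(pick == 0, "A", "T"), np.where(pick == 0, "G", "C"))
    return "".join(letters)


@pytest.fixture
def make_sequence(rng):
    def _make(length, p_at=0.5, id="test"):
        return NucSequence(id, random_sequence(rng, length, p_at))

    return _make
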