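import numpy as np
import pytest

from mrsummary import SummaryData


@pytest.fixture
def small_data():
    """Five strong, homogeneous variants with true ratio near 0.25."""
    rng = np.random.default_rng(7)
    gamma = rng.uniform(0.1, 0.3, 5)
    bxse = np.full(5, 0.01)
    byse = rng.uniform(0.008, 0.02, 5)
    bx = gamma + rng.normal(0, 1, 5) * bxse
    by = 0.25 * gamma + rng.normal(0, 1, 5) * byse
    return SummaryData(bx=bx, bxse=bxse, by=by, byse=byse)


@pytest.fixture
def allele_data():
    return SummaryData(
        bx=[0.2, -0.1, 0.3],
        bxse=[0.02, 0.02, 0.02],
        by=[0.05, 0.02, -0.04],
        byse=[0.01, 0.01, 0.01],
        variant_ids=["rs1", "rs2", "rs3"],
        effect_allele=["A", "C", "A"],
        other_allele=["G", "G", "T"],
        eaf=np.array([0.3, 0.4, 0.5]),
    )


def random_instance(rng, j=None):
    """A random small SummaryData for oracle comparisons."""
    j = j if j is not None else int(rng.integers(3, 9))
    return SummaryData(
        bx=rng.normal(0.2, 0.1, j),
        bxse=rng.uniform(0.01, 0.05, j),
        by=rng.normal(0.05, 0.05, j),
        byse=rng.uniform(0.01, 0.05, j),
    )
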