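import numpy as np
import pytest

from dmusage.data import GeneCounts


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_gene():
    """3 features x 4 samples with a mix of magnitudes."""
    counts = np.array([
        [30, 12, 25, 40],
        [10, 18, 15, 22],
        [5, 9, 4, 11],
    ])
    return GeneCounts("gA", ["t1", "t2", "t3"], ["s1", "s2", "s3", "s4"], counts)


@pytest.fixture
def two_group_design():
    return {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}


def enumerate_compositions(m, q):
    """All count vectors of length q summing to m (oracle helper)."""
    if q == 1:
        yield (m,)
        return
    for first in range(m + 1):
        for rest in enumerate_compositions(m - first, q - 1):
            yield (first,) + rest
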