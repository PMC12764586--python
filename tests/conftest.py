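import numpy as np
import pytest

from graphtad.io import ContactMatrix, TadInterval, TadSet
from graphtad.simulate import simulate_hic


@pytest.fixture(scope="session")
def sim600():
    """Seeded 600-bin synthetic matrix with known domains (10 Kb bins)."""
    return simulate_hic(n_bins=600, resolution=10_000, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tadset(bins, resolution=10_000, chrom="chrT"):
    """TadSet from a list of (start_bin, end_bin) pairs."""
    return TadSet(
        chrom=chrom,
        resolution=resolution,
        intervals=[
            TadInterval(chrom=chrom, start_bin=s, end_bin=e, resolution=resolution)
            for s, e in bins
        ],
    )


def random_symmetric(rng, n, scale=5.0):
    m = rng.random((n, n)) * scale
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return m


@pytest.fixture
def block_matrix():
    """60-bin matrix, three 15-bin domains with intra 10/8/6 on background 1."""
    n, res = 60, 10_000
    v = np.ones((n, n))
    tads = []
    for s, c in [(0, 10.0), (15, 8.0), (30, 6.0)]:
        v[s:s + 15, s:s + 15] = c
        tads.append(TadInterval("chrT", s, s + 15, res))
    cm = ContactMatrix("chrT", res, v)
    return cm, TadSet("chrT", res, tads)
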