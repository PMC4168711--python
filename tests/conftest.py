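import numpy as np
import pytest

from puffin import FragmentRecord, GenomicRegion, ProfileConfig


def make_fragments(midpoints, length=146, chrom="chr1"):
    """Fragments of one length with the given (integer) midpoints."""
    out = []
    for m in midpoints:
        start = int(m) - length // 2
        out.append(FragmentRecord(chrom, start, start + length))
    return out


@pytest.fixture
def small_config():
    """Reduced scale grid for fast unit tests; same alpha range as default."""
    return ProfileConfig(m=8)


@pytest.fixture
def single_fragment_region():
    frags = make_fragments([500])
    return frags, GenomicRegion("chr1", 0, 1000)


@pytest.fixture
def cluster_fragments():
    """Two well-separated clusters of 30 fragments each, 400 bp apart."""
    rng = np.random.default_rng(11)
    mids = np.concatenate([
        np.rint(rng.normal(600, 15, 30)),
        np.rint(rng.normal(1000, 15, 30)),
    ])
    return make_fragments(mids)


def random_uniform_length_fragments(seed, n_range=(20, 120), w_range=(100, 200),
                                    span=(200, 2800)):
    """A random fragment set sharing one random insert size."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(*n_range))
    w = int(rng.integers(*w_range))
    mids = rng.uniform(*span, n)
    return make_fragments(np.rint(mids), length=w)
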