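import numpy as np
import pytest

from ldrscan import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_model():
    return sd.DemographicModel()


@pytest.fixture(scope="session")
def small_locus():
    """A modest three-taxon locus reused by read-level tests."""
    model = sd.DemographicModel()
    return sd.simulate_locus(model, 10_000,
                             {"J": 6, "I": 6, "R": 10}, seed=99)


def make_counts(variant1, variant2, depth1=None, depth2=None,
                taxon="I", chrom="chr1"):
    """Build a two-platform count-table pair from per-site variant read
    counts (reference reads fill up to the requested depths)."""
    variant1 = np.asarray(variant1, dtype=np.int64)
    variant2 = np.asarray(variant2, dtype=np.int64)
    L = variant1.size
    depth1 = (np.full(L, 30) if depth1 is None
              else np.asarray(depth1, dtype=np.int64))
    depth2 = (np.full(L, 30) if depth2 is None
              else np.asarray(depth2, dtype=np.int64))
    tabs = []
    for platform, depth, var in (("GA", depth1, variant1),
                                 ("SOLiD", depth2, variant2)):
        tabs.append(sd.PlatformSiteCounts(
            taxon=taxon, platform=platform, chrom=chrom, length=L,
            allele_counts={"0": depth - var, "1": var.copy()}))
    return tabs[0], tabs[1]
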