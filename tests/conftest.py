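import numpy as np
import pytest

from focaldel import scars, simulate
from focaldel.coverage import BinnedCoverage, Region, normalize_pair

GRCH37_WINDOW = "chr5:98190408-98262740"
GRCH38_WINDOW = "chr5:98853485-98930272"


@pytest.fixture(scope="session")
def region37() -> Region:
    return Region.parse(GRCH37_WINDOW)


@pytest.fixture(scope="session")
def karyotype():
    return scars.toy_karyotype()


@pytest.fixture(scope="session")
def signature_library():
    return simulate.random_signature_library(n_signatures=5, seed=42)


def make_pair(truth: simulate.SimTruth, region: Region, bin_width: int = 50,
              **kwargs):
    """Simulate a paired coverage track and wrap it as a normalized pair."""
    normal, tumor, truth = simulate.simulate_paired_coverage(
        truth, window_length=region.length, bin_width=bin_width, **kwargs)
    return normalize_pair(
        BinnedCoverage("normal", region, bin_width, normal, truth.mean_depth_normal),
        BinnedCoverage("tumor", region, bin_width, tumor, truth.mean_depth_tumor),
    ), truth


@pytest.fixture(scope="session")
def het_pair_08_075(region37):
    truth = simulate.SimTruth(cellularity=0.8, subclonal_fraction=0.75,
                              zygosity="heterozygous", seed=11)
    return make_pair(truth, region37)
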