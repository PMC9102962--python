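import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from hybridqtl import simdata

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_config():
    """Two small chromosomes, 120 families — enough to exercise every stage."""
    return simdata.SimConfig(
        n_chromosomes=2,
        chrom_lengths_bp=(200_000_000, 150_000_000),
        snps_per_chrom=(50, 40),
        n_families=120,
        seed=1,
    )


@pytest.fixture(scope="session")
def tiny_pop(tiny_config):
    return simdata.simulate_bc1f3_population(tiny_config)


@pytest.fixture(scope="session")
def toy_scan():
    """Hand-built scan result: chr1 significant SNPs at 10, 25 and 60 Mb."""
    return pd.DataFrame({
        "marker": ["m1", "m2", "m3", "m4"],
        "chrom": ["chr1", "chr1", "chr1", "chr2"],
        "pos": [10_000_000, 25_000_000, 60_000_000, 40_000_000],
        "a": [1.0, 0.8, 0.5, 0.2],
        "d": [0.0, 0.1, 0.0, 0.0],
        "score": [8.0, 7.0, 6.0, 1.0],
        "significant": [True, True, True, False],
    })


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
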