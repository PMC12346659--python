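import warnings

import numpy as np
import pandas as pd
import pytest

from crcmeth.io_formats import GenomicInterval
from crcmeth.synthetic import SimulationConfig, simulate_beta_matrix, simulate_count_data

# statsmodels emits convergence chatter on tiny tiles; irrelevant to assertions
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def count_cohort():
    """6v6 count cohort with planted DMRs (the tissue-study conditions)."""
    config = SimulationConfig(seed=11, n_samples_per_group=(6, 6))
    records, truth = simulate_count_data(config)
    return config, records, truth


@pytest.fixture(scope="session")
def beta_cohort():
    """4-cluster beta matrix with stepwise hypermethylation + normals."""
    config = SimulationConfig(seed=23)
    beta, coords, truth = simulate_beta_matrix(config)
    return config, beta, coords, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def interval(chrom, start, end, name=""):
    return GenomicInterval(chrom=chrom, start=start, end=end, name=name)


@pytest.fixture
def make_interval():
    return interval
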