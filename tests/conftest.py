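import numpy as np
import pandas as pd
import pytest

from lcsem.cohort import default_config, generate_cohort
from lcsem.preprocess import average_bilateral


@pytest.fixture(scope="session")
def small_cohort():
    """Complete-data cohort (n=600, fixed seed) with tract averages."""
    cfg = default_config(n_participants=600, seed=42)
    return average_bilateral(generate_cohort(cfg))


@pytest.fixture(scope="session")
def big_cohort():
    """Large complete-data cohort for calibration checks."""
    cfg = default_config(n_participants=10000, seed=7)
    return average_bilateral(generate_cohort(cfg))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def saturated_spec(columns):
    """Fully saturated PathSpec over observed columns (free means,
    variances and covariances)."""
    from lcsem.ram import PathSpec
    ps = PathSpec(observed=list(columns))
    for i, c in enumerate(columns):
        ps.add_mean(c, label=f"mu_{c}")
        ps.add_cov(c, label=f"v_{c}")
        for d in columns[:i]:
            ps.add_cov(c, d, label=f"c_{d}_{c}")
    return ps
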