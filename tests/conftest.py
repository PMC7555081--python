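import numpy as np
import pandas as pd
import pytest

from regionage import FAST_PARAMS, default_config, simulate_cohort
from regionage.simulate import RegionSpec, SimulationConfig


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-condition cohort shared across read-only tests."""
    cfg = default_config(600, seed=123)
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_tiny_config(n=500, seed=0, **kw):
    """Three custom regions in two covariance blocks; confounders off."""
    regions = {
        "r_one": RegionSpec(5000.0, -12.0, 120.0, 1, "1"),
        "r_two": RegionSpec(3000.0, -8.0, 90.0, 1, "1"),
        "r_three": RegionSpec(800.0, -2.5, 30.0, 2, "2"),
    }
    cfg = SimulationConfig(n_participants=n, seed=seed, region_spec=regions,
                           missing_parity_rate=0.0, **kw)
    cfg.validate()
    return cfg


@pytest.fixture
def tiny_config():
    return make_tiny_config()


@pytest.fixture
def fast_params():
    return FAST_PARAMS
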