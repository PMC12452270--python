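import warnings

import numpy as np
import pytest

from ghsieve.pipeline import run_synthetic_study
from ghsieve.synthetic_data import SimulationConfig, simulate_study

# optimizer exploration legitimately visits overflowing parameter values
warnings.filterwarnings("ignore", category=RuntimeWarning,
                        message="overflow encountered in exp")


@pytest.fixture(scope="session")
def default_cfg() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def default_study(default_cfg):
    return simulate_study(default_cfg)


@pytest.fixture(scope="session")
def default_run(default_cfg):
    return run_synthetic_study(default_cfg)


def logistic_sample(seed: int, n: int, beta0: float = -1.0, beta1: float = 0.8,
                    x_sd: float = 2.0):
    """Draw (x, y) with y ~ Bernoulli(logistic(beta0 + beta1 x))."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, x_sd, n)
    p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * x)))
    y = (rng.random(n) < p).astype(int)
    return x, y
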