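import numpy as np
import pandas as pd
import pytest

from hccpipe.simulate import SimulationConfig, simulate_cohorts


@pytest.fixture(scope="session")
def small_bundle():
    """A small two-cohort simulation shared across read-only tests."""
    return simulate_cohorts(SimulationConfig(n_a=20, n_b=20, seed=42))


@pytest.fixture(scope="session")
def small_layers(small_bundle):
    from hccpipe.pipeline import run_layers

    return run_layers(small_bundle, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_survival_table(rng, n=150, coef=0.0, n_noise=9, censor_scale=100.0,
                        base_rate=0.03):
    """Exponential survival data with one (optionally) prognostic feature."""
    X = pd.DataFrame(
        rng.normal(size=(n, 1 + n_noise)),
        columns=["signal"] + [f"noise{i}" for i in range(n_noise)],
    )
    eta = coef * X["signal"].to_numpy()
    t = rng.exponential(1.0 / (base_rate * np.exp(eta)))
    c = rng.uniform(0, censor_scale, n)
    tab = X.copy()
    tab["os_time"] = np.minimum(t, c)
    tab["os_event"] = (t <= c).astype(int)
    return tab
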