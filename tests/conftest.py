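import numpy as np
import pandas as pd
import pytest

from shapalloc import CohortDistribution, experiment_layout, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """12 participants on the exp2 layout with the default biased regime."""
    records, truth = simulate_cohort(12, CohortDistribution(), experiment_layout("exp2"), seed=7)
    return records, truth


@pytest.fixture(scope="session")
def beta_panel():
    """Pure interior-beta panel with a known slope and random intercepts."""
    rng = np.random.default_rng(42)
    n, J = 600, 12
    g = np.repeat(np.arange(J), n // J)
    u = rng.normal(0, 0.3, J)
    x = rng.normal(size=n)
    mu = 1 / (1 + np.exp(-(0.3 + 0.5 * x + u[g])))
    y = rng.beta(mu * 20, (1 - mu) * 20)
    boundary = rng.uniform(size=n) < 0.08
    y[boundary] = (rng.uniform(size=n) < 0.5)[boundary].astype(float)
    df = pd.DataFrame({"y": y, "x": x, "pid": g})
    truth = {"intercept": 0.3, "slope": 0.5, "phi": 20.0, "sigma_u": 0.3, "zoi": 0.08}
    return df, truth
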