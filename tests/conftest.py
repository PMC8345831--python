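import numpy as np
import pandas as pd
import pytest

from saeprev import (
    PopulationConfig,
    draw_two_stage_sample,
    generate_population,
)


@pytest.fixture(scope="session")
def small_pop():
    cfg = PopulationConfig(
        n_districts=8, size_range=(300, 1200), clusters_per_district=8, seed=11
    )
    return generate_population(cfg)


@pytest.fixture(scope="session")
def small_sample(small_pop):
    return draw_two_stage_sample(small_pop, 5, 20, seed=22)


@pytest.fixture(scope="session")
def glmm_data():
    """70 districts x 60 units from the random-intercept logistic model."""
    from scipy.special import expit

    rng = np.random.default_rng(99)
    m, n = 70, 60
    d = np.repeat(np.arange(m), n)
    x = rng.integers(0, 2, m * n).astype(float)
    v = rng.normal(0, 0.5, m)
    y = (rng.random(m * n) < expit(-2.0 + 0.5 * x + v[d])).astype(int)
    return pd.DataFrame({"district_id": d, "x": x, "y": y})
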