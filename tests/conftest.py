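import numpy as np
import pandas as pd
import pytest

import survstrat as ss


@pytest.fixture(scope="session")
def default_cohort():
    """One default-scenario synthetic cohort (n=108, 3 latent subgroups)."""
    return ss.generate_cohort(ss.default_simulation_config(seed=11))


@pytest.fixture(scope="session")
def small_pipeline_config():
    """Pipeline config with a reduced resample count for fast smoke tests."""
    return ss.PipelineConfig(seed=11, n_resamples=25)


@pytest.fixture
def toy_cohort():
    """Four uncensored patients, binary covariate; exact PL known in closed form."""
    return pd.DataFrame(
        {
            "patient_id": ["a", "b", "c", "d"],
            "time": [1.0, 2.0, 3.0, 4.0],
            "event": [1, 1, 1, 1],
            "x": [1.0, 0.0, 1.0, 0.0],
        }
    )


def random_survival_cohort(seed, n=60, p_censor=0.3, ties=False):
    """Small random survival dataset with two covariates."""
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    x2 = rng.binomial(1, 0.5, size=n).astype(float)
    lp = 0.5 * x1 - 0.3 * x2
    t = -np.log(rng.uniform(size=n)) / np.exp(lp) * 10
    if ties:
        t = np.ceil(t)
    c = rng.exponential(10 * (1 - p_censor) / max(p_censor, 1e-9), size=n) if p_censor else np.inf
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "time": np.maximum(time, 1e-9),
            "event": event,
            "x1": x1,
            "x2": x2,
        }
    )
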