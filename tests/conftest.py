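import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from optoclamp import ClampConfig, default_population, run_closed_loop

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_clamp_run():
    """One calibrated k=3 closed-loop run shared by read-only tests."""
    model = default_population(n_roi=1, seed=7)
    cfg = ClampConfig(k_sd=3.0, t_cl=266.0)
    return run_closed_loop(model, 0, cfg, seed=7), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
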