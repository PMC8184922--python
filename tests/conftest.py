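import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from rsrfit import ScenarioConfig, SRSeries, generate_replicate  # noqa: E402


@pytest.fixture
def toy_series() -> SRSeries:
    """Small deterministic hockey-stick-ish series (T=8)."""
    rng = np.random.default_rng(42)
    S = np.array([120.0, 380.0, 650.0, 220.0, 510.0, 800.0, 300.0, 450.0])
    R = 1.1 * np.minimum(S, 400.0) * np.exp(0.3 * rng.standard_normal(8))
    return SRSeries(np.arange(2000, 2008), S, R)


@pytest.fixture
def clean_replicate():
    """One clean autocorrelated replicate of the base scenario."""
    cfg = ScenarioConfig(name="clean", p=0.0, rho=0.8)
    return generate_replicate(cfg, 12345)


@pytest.fixture
def iid_replicate():
    """No outliers, no autocorrelation."""
    cfg = ScenarioConfig(name="iid", p=0.0, rho=0.0)
    return generate_replicate(cfg, 2021)
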