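import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from convclubs import (ClubSpec, DivergentSpec, FactorModelSpec, PanelData,
                       generate_panel)
from convclubs.simulate import study_scale_spec

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def small_log_panel() -> PanelData:
    """Hand-sized log-scale panel with known transition parameters."""
    return PanelData(values=[[2.0, 4.0], [6.0, 8.0]], ids=["a", "b"],
                     years=[2000, 2001], scale="log")


@pytest.fixture
def identical_panel() -> PanelData:
    """All units share one series: the exact-convergence edge case."""
    series = np.linspace(3.0, 4.0, 8)
    return PanelData(values=np.tile(series, (4, 1)),
                     ids=list("abcd"), years=list(range(2000, 2008)),
                     scale="log")


@pytest.fixture
def convergent_panel() -> PanelData:
    """Single planted club with tiny noise: clearly convergent."""
    spec = FactorModelSpec(n_periods=20, clubs=(ClubSpec(8, 1.0, 0.01),),
                           alpha=0.5, seed=7)
    panel, _ = generate_panel(spec)
    return panel


@pytest.fixture
def two_club_spec() -> FactorModelSpec:
    """Two well-separated clubs (gap = 8 within-club noise SDs)."""
    return FactorModelSpec(
        n_periods=20,
        clubs=(ClubSpec(6, 1.4, 0.05), ClubSpec(6, 1.0, 0.05)),
        alpha=0.5, seed=11)


@pytest.fixture
def study_scale_panel():
    """44 x 17 panel with 3 planted clubs (12/14/14) and 4 divergent units."""
    return generate_panel(study_scale_spec(seed=42))


def random_log_panel(rng: np.random.Generator, max_n: int = 20,
                     max_t: int = 30) -> PanelData:
    """An arbitrary positive log-scale panel for property checks."""
    n = int(rng.integers(2, max_n + 1))
    t = int(rng.integers(5, max_t + 1))
    values = rng.normal(3.0, 1.0, size=(n, t)).clip(min=0.1)
    return PanelData(values=values, ids=[f"u{i:03d}" for i in range(n)],
                     years=list(range(2000, 2000 + t)), scale="log")
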