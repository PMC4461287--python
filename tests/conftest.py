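import pytest
from hypothesis import HealthCheck, settings

import boolprune as bp

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_instance() -> bp.PlantedInstance:
    """Exhaustive-oracle tier planted benchmark (12 PKN edges)."""
    return bp.planted_small(seed=1)


@pytest.fixture(scope="session")
def toggle():
    """Mutual-inhibition toggle switch with complementary fixed points."""
    return bp.toggle_switch()


@pytest.fixture(scope="session")
def toy_model():
    return bp.toy_oscillator()


@pytest.fixture()
def fast_config() -> bp.OptimizationConfig:
    """Short loop for plumbing tests that do not probe convergence."""
    return bp.OptimizationConfig(max_iterations=10, seed=0)
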