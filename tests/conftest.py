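import pytest
from hypothesis import HealthCheck, settings

from screenkit import ScreenConfig, generate_screen

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def small_screen():
    """A 4-plate duplicate screen shared by read-only tests."""
    cfg = ScreenConfig(n_compounds=352 * 4, seed=42)
    wells, library, truth = generate_screen(cfg)
    return cfg, wells, library, truth
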