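import pytest
from hypothesis import HealthCheck, settings

from dormscreen.classifier import classify_panel
from dormscreen.synthetic import PanelConfig, generate_panel, simulate_panel_assays

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_config() -> PanelConfig:
    return PanelConfig()


@pytest.fixture(scope="session")
def default_panel(default_config):
    """The reference 189-variety synthetic panel (truths, trait table)."""
    return generate_panel(default_config)


@pytest.fixture(scope="session")
def panel_assays(default_panel, default_config):
    truths, _ = default_panel
    return simulate_panel_assays(truths, default_config)


@pytest.fixture(scope="session")
def panel_calls(panel_assays):
    return classify_panel(panel_assays)
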