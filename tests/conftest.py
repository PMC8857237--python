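from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from linafunnel.simulate import GeneratorConfig, gen_funnel_fixture

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

FIXTURES_DIR = Path(__file__).resolve().parents[1] / "fixtures"


@pytest.fixture(scope="session")
def in_paper_config() -> GeneratorConfig:
    """The replay configuration encoding the published funnel structure."""
    return GeneratorConfig.from_yaml(FIXTURES_DIR / "in_paper.yaml", seed=1)


@pytest.fixture(scope="session")
def in_paper_bundle(in_paper_config):
    """The full replay bundle, generated once per session (seed 1)."""
    return gen_funnel_fixture(in_paper_config)


@pytest.fixture(scope="session")
def small_bundle():
    """A desk-scale bundle under the default study conditions."""
    return gen_funnel_fixture(GeneratorConfig(seed=42))
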