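import pytest
from hypothesis import HealthCheck, settings

from comopath import SyntheticConfig, generate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_truth(tmp_path_factory):
    """One default-condition synthetic dataset shared across the session."""
    out = tmp_path_factory.mktemp("synthetic_default")
    return generate(SyntheticConfig(seed=11), out)
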