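import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def base_dir(tmp_path):
    """Output root for session directories."""
    out = tmp_path / "data"
    out.mkdir()
    return out
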