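import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def series():
    """The reconstructed 6a-6f compound series (deterministic)."""
    from qcpost.fixtures import builtin_series

    return builtin_series()
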