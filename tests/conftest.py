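import matplotlib
import pytest
from hypothesis import HealthCheck, settings

matplotlib.use("Agg")

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ph2adapt import DesignSpec  # noqa: E402


@pytest.fixture(scope="session")
def urothelial():
    """The urothelial-cancer worked example: 80% power at alpha = 0.1 for
    a 35% -> 50% response-rate improvement."""
    return DesignSpec(alpha=0.1, beta=0.2, pi_u=0.35, pi_a=0.5)


@pytest.fixture(scope="session")
def tiny_spec():
    """A permissive spec whose designs are small enough for brute force."""
    return DesignSpec(alpha=0.2, beta=0.3, pi_u=0.3, pi_a=0.7)
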