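import pytest
from hypothesis import HealthCheck, settings

from cprpose import Calibration, SyntheticSpec, generate_session

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def calibration():
    return Calibration(px_per_cm=10.0)


@pytest.fixture(scope="session")
def clean_session():
    """One noise-free 30-press phase: the standard detector fixture."""
    spec = SyntheticSpec(n_phases=1, presses_per_phase=30, noise_px_sd=0.0, seed=1)
    return generate_session(spec)


@pytest.fixture(scope="session")
def two_phase_session():
    """Two noise-free phases separated by a 5 s pause."""
    spec = SyntheticSpec(n_phases=2, presses_per_phase=30, pause_s=5.0, noise_px_sd=0.0, seed=2)
    return generate_session(spec)
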