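import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mindmodes.algebra import Basis, StateVector, normalize

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def basis4():
    return Basis(["w", "x", "y", "z"])


@pytest.fixture
def rng():
    return np.random.default_rng(20220927)


def random_state(basis: Basis, rng: np.random.Generator,
                 complex_phases: bool = True) -> StateVector:
    """A Haar-ish random normalized state (shared test helper)."""
    re = rng.normal(size=basis.dimension)
    im = rng.normal(size=basis.dimension) if complex_phases else 0.0
    return normalize(StateVector(basis, re + 1j * im))
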