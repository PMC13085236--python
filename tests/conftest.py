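import numpy as np
import pytest

from frdo.model_backend import build_ppp, generate_fixture
from frdo.drivers import minimize_ground_state
from frdo.orbital_space import OrbitalState


@pytest.fixture(scope="session")
def decoupled_spec():
    return generate_fixture(0, "decoupled")


@pytest.fixture(scope="session")
def decoupled_backend(decoupled_spec):
    return build_ppp(decoupled_spec)


@pytest.fixture(scope="session")
def decoupled_ground(decoupled_backend):
    report = minimize_ground_state(decoupled_backend)
    assert report.converged
    return report


@pytest.fixture(scope="session")
def collapse_spec():
    return generate_fixture(1, "collapse")


@pytest.fixture(scope="session")
def collapse_backend(collapse_spec):
    return build_ppp(collapse_spec)


def guess_state(backend) -> OrbitalState:
    """Orbital state at the backend's damped-SCF starting guess."""
    C, f = backend.sad_guess()
    return OrbitalState(C0=tuple(c.copy() for c in C),
                        C=tuple(c.copy() for c in C),
                        f=f, n_valence=backend.n_valence)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
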