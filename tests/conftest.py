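import numpy as np
import pytest

from aneucoil.rod import CoilSpec, NaturalShape, make_rod_state


@pytest.fixture(scope="session")
def coil_spec():
    """The baseline platinum coil used throughout the studies."""
    return CoilSpec(D1=0.05, D2=0.305, D3=2.0, alpha=0.1, length=50.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rod(rng, n, scale=0.3, step=0.5, angles=True):
    """A mildly wiggly open polyline rod with random frame angles."""
    pts = np.cumsum(rng.normal(0, scale, (n, 3)) + np.array([step, 0, 0]), axis=0)
    phi = rng.normal(0, 0.5, n - 1) if angles else None
    return make_rod_state(pts, edge_angles=phi)


def random_natural(rng, n, scale=0.3, step=0.5):
    pts = np.cumsum(rng.normal(0, scale, (n, 3)) + np.array([step, 0, 0]), axis=0)
    return NaturalShape.from_vertices(pts)


@pytest.fixture(scope="session")
def synthetic_domain():
    from aneucoil.geometry import make_synthetic_aneurysm

    return make_synthetic_aneurysm(dome_radius=2.5, neck_radius=1.0)
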