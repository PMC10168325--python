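import numpy as np
import pytest

from lumpsim import geometry as geo


@pytest.fixture(scope="session")
def coarse_human_mesh():
    spec = geo.GeometrySpec.human(h_cavity=1.2, h_far=3.0)
    return geo.build_human_geometry(spec)

@pytest.fixture(scope="session")
def coarse_porcine_mesh():
    spec = geo.GeometrySpec.porcine(h_cavity=0.35, h_far=3.5)
    return geo.build_porcine_geometry(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def unit_box_mesh(n):
    """Tet mesh of the unit cube with n cells per side."""
    ax = np.linspace(0.0, 1.0, n + 1)
    points, tets = geo._box_tets(ax, ax, ax)
    return points, tets
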