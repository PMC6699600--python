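import numpy as np
import pytest

from porescope.centerline import fit_centerline, radius_function
from porescope.fixtures import FixtureSpec, make_classification_pore, make_pore
from porescope.pathway import PathwayConfig, ProbeTrace, find_pathway


def make_straight_trace(z_lo: float = -2.0, z_hi: float = 2.0, step: float = 0.1,
                        radii=0.38) -> ProbeTrace:
    """Hand-built straight probe trace along +z with the origin at z=0."""
    z = np.arange(z_lo, z_hi + 1e-9, step)
    points = np.stack([np.zeros_like(z), np.zeros_like(z), z], axis=1)
    r = np.full(len(z), radii, dtype=float) if np.isscalar(radii) else np.asarray(radii, dtype=float)
    origin = int(np.argmin(np.abs(z)))
    return ProbeTrace(points=points, radii=r, origin_index=origin)


@pytest.fixture(scope="session")
def cylinder():
    return make_pore(FixtureSpec(shape="cylinder"))


@pytest.fixture(scope="session")
def hourglass():
    return make_pore(FixtureSpec(shape="hourglass"))


@pytest.fixture(scope="session")
def bent():
    return make_pore(FixtureSpec(shape="bent"))


@pytest.fixture(scope="session")
def classification_pore():
    return make_classification_pore()


def _analyze(frame, config=None):
    trace = find_pathway(frame, config or PathwayConfig())
    spline = fit_centerline(trace)
    radius = radius_function(spline, trace)
    return {"trace": trace, "spline": spline, "radius": radius}


@pytest.fixture(scope="session")
def cylinder_analysis(cylinder):
    return _analyze(cylinder[0])


@pytest.fixture(scope="session")
def hourglass_analysis(hourglass):
    return _analyze(hourglass[0])


@pytest.fixture(scope="session")
def bent_analysis(bent):
    return _analyze(bent[0])


@pytest.fixture(scope="session")
def classification_analysis(classification_pore):
    return _analyze(classification_pore[0])
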