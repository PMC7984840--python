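import numpy as np
import pytest

from segclock import GeometryParams
from segclock.engine import RunConfig
from segclock.mechanics import MechanicsParams

VA = 55.0 / 30.0


def junction_mechanics(geom: GeometryParams, **overrides) -> MechanicsParams:
    """Mechanics with the advection knot at the tube-tailbud junction."""
    xq = geom.Xc / geom.Lx
    vp = VA / (1.0 - xq)
    kw = dict(vp_early=vp, vp_late=vp, xq=xq, tg=float("inf"))
    kw.update(overrides)
    return MechanicsParams(**kw)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def geom():
    return GeometryParams()


@pytest.fixture
def small_config():
    """A small, fast tissue used by engine-level unit tests."""
    geom = GeometryParams(r0=15.0, L0=180.0)
    return RunConfig(
        geom=geom,
        mech=junction_mechanics(geom),
        duration=5.0,
        seed=7,
        relax_minutes=2.0,
    )
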