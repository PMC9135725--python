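import numpy as np
import pytest

from sigwhistle import synth
from sigwhistle.contours import WhistleContour
from sigwhistle.sigid import WhistleUnit


@pytest.fixture(scope="session")
def site_profiles():
    return synth.default_site_profiles()


@pytest.fixture(scope="session")
def small_study(site_profiles):
    return synth.make_repertoire(site_profiles, 3, seed=1)


def make_unit(t_start, duration=0.5, session_id="S1", f0=5000.0, f1=15000.0,
              n_samples=50, mirror=False):
    """A single-contour unit with a linear sweep shape at a given time."""
    t = t_start + np.linspace(0.0, duration, n_samples)
    f = np.linspace(f0, f1, n_samples)
    if mirror:
        f = f[::-1].copy()
    return WhistleUnit(session_id, (WhistleContour(session_id, t, f),))


def make_units(starts, duration=0.5, session_id="S1", **kw):
    return [make_unit(s, duration, session_id, **kw) for s in starts]
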