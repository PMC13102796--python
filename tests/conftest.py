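"""Shared fixtures and independent oracles for the test suite."""

import math

import pytest
from hypothesis import settings
from scipy.optimize import brentq

from fillfrac.geometry import ShellShape, ShellState, shell_from_am

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


def inflate_bisect(shape: ShellShape, am_state: ShellState, lam: float) -> ShellState:
    """Independent inflation oracle: solve wall-volume conservation for B
    by bracketed root-finding instead of the closed-form quadratic.

    The larger root (H <= 2B branch) lies in [P/4, P/2) where P = PMW/pi.
    """
    pmw = lam * am_state.pmw
    P = pmw / math.pi
    C = shape.volume_coeff

    def resid(b):
        return C * P * b * (P - 2.0 * b) - shape.v_m

    b = brentq(resid, P / 4.0, P / 2.0 * (1.0 - 1e-12), xtol=1e-14, rtol=1e-15)
    h = P - 2.0 * b
    return ShellState(
        b=b, a=shape.k * b, h=h, pmw=pmw, lvv=C * b**3, lam=lam
    )


@pytest.fixture
def hemisphere_heart():
    """Hemispherical shell (L=0, k=1) at the small end of the AM ranges."""
    return shell_from_am(lvid_am=2.6, h_am=1.0, k=1.0, L=0.0)


@pytest.fixture
def midrange_heart():
    """A mid-range truncated prolate heart."""
    return shell_from_am(lvid_am=3.6, h_am=1.5, k=1.5, L=0.2)
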