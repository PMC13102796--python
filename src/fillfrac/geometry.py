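"""Truncated prolate-ellipsoid shell model of the left ventricle.

The LV cavity is modelled as a prolate ellipsoid of revolution with minor
semi-axis ``B`` (half the internal diameter, LVID/2) and major semi-axis
``A = k*B``, truncated along the long axis: the shell extends a fraction
``L`` of ``A`` above the equator, so its total height is ``T = A*(1 + L)``.
``L = 0`` is a half shell, ``L = 1`` a complete ellipsoid.  The wall has
uniform thickness ``H`` added radially, and the mid-wall perimeter is the
equatorial circumference of the mid-wall surface,

    PMW = pi * (2*B + H).

A heart keeps its shape (``k``, ``L``) and its myocardial wall volume
``V_M`` fixed over the cardiac cycle (incompressible myocardium); states
differ only by the mid-wall stretch ``lambda = PMW / PMW_AM`` relative to
the fully contracted absolute-minimum (AM) state.  Because
``H + 2*B = PMW/pi`` is fixed by the stretch, wall-volume conservation is
a quadratic in ``B`` and inflation has a closed form.

All lengths are cm, all volumes mL (= cm^3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "GeometryError",
    "StretchUnattainableError",
    "ShellShape",
    "ShellState",
    "truncated_height",
    "cavity_volume",
    "wall_volume",
    "midwall_perimeter",
    "shell_from_am",
    "inflate_to_stretch",
    "trajectory",
]


class GeometryError(ValueError):
    """Invalid or unsupported shell geometry."""


class StretchUnattainableError(GeometryError):
    """No physical shell state exists at the requested mid-wall stretch."""


def _truncation_poly(L: float) -> float:
    # volume factor of the truncation: 1 + L + L^2 - L^3
    return 1.0 + L + L * L - L * L * L


def _check_L(L: float) -> None:
    if not 0.0 <= L <= 1.0:
        raise GeometryError(f"truncation ratio L must be in [0, 1], got {L}")


@dataclass(frozen=True)
class ShellShape:
    """Per-heart constants: truncation ``L``, height:width ratio ``k = A/B``,
    and myocardial wall volume ``v_m`` (mL)."""

    L: float
    k: float
    v_m: float

    def __post_init__(self) -> None:
        _check_L(self.L)
        if self.k < 1.0:
            raise GeometryError(f"height:width ratio k must be >= 1, got {self.k}")
        if self.v_m <= 0.0:
            raise GeometryError(f"wall volume v_m must be positive, got {self.v_m}")

    @property
    def volume_coeff(self) -> float:
        """C such that LVV = C * B**3 for this shape (A = k*B)."""
        return (2.0 / 3.0) * math.pi * self.k * _truncation_poly(self.L)


@dataclass(frozen=True)
class ShellState:
    """One cardiac state of a shell.

    ``b``/``a`` are the cavity minor/major semi-axes (cm), ``h`` the wall
    thickness (cm), ``pmw`` the mid-wall perimeter (cm), ``lvv`` the cavity
    volume (mL) and ``lam`` the mid-wall stretch relative to the AM state
    (``lam = 1`` exactly at AM).
    """

    b: float
    a: float
    h: float
    pmw: float
    lvv: float
    lam: float

    @property
    def lvid(self) -> float:
        """Internal diameter, 2*B (cm)."""
        return 2.0 * self.b


def truncated_height(a: float, L: float) -> float:
    """Total long-axis height T = A*(1 + L) of the truncated shell."""
    if a <= 0.0:
        raise GeometryError(f"major semi-axis must be positive, got {a}")
    _check_L(L)
    return a * (1.0 + L)


def cavity_volume(a: float, b: float, L: float) -> float:
    """Cavity volume (2/3)*pi*A*B^2*(1 + L + L^2 - L^3) of the truncated
    prolate ellipsoid."""
    if a <= 0.0 or b <= 0.0:
        raise GeometryError(f"semi-axes must be positive, got A={a}, B={b}")
    _check_L(L)
    return (2.0 / 3.0) * math.pi * a * b * b * _truncation_poly(L)


def wall_volume(a: float, b: float, h: float, L: float) -> float:
    """Myocardial volume of a shell of uniform radial thickness H.

    Equals ``cavity_volume(a, b + h, L) - cavity_volume(a, b, L)``: the
    thickness is added radially only, the major semi-axis of the outer
    surface staying at A.
    """
    if a <= 0.0 or b <= 0.0 or h < 0.0:
        raise GeometryError(f"need A, B > 0 and H >= 0, got A={a}, B={b}, H={h}")
    _check_L(L)
    return (2.0 / 3.0) * math.pi * a * h * _truncation_poly(L) * (h + 2.0 * b)


def midwall_perimeter(b: float, h: float) -> float:
    """Mid-wall perimeter PMW = pi*(2*B + H)."""
    if b <= 0.0 or h <= 0.0:
        raise GeometryError(f"need B, H > 0, got B={b}, H={h}")
    return math.pi * (2.0 * b + h)


def shell_from_am(
    lvid_am: float, h_am: float, k: float, L: float
) -> tuple[ShellShape, ShellState]:
    """Build a heart from its fully contracted (AM) dimensions.

    Returns the constant shape (with ``v_m`` fixed by the AM wall volume)
    and the AM state itself (``lam = 1``).  The AM cavity volume is the
    heart's true dead-space volume V_W.
    """
    if lvid_am <= 0.0 or h_am <= 0.0:
        raise GeometryError("AM diameter and thickness must be positive")
    b = 0.5 * lvid_am
    if h_am >= 2.0 * b:
        raise GeometryError(
            f"wall thickness H={h_am} >= internal diameter {lvid_am}: "
            "root selection would be ambiguous (unsupported geometry)"
        )
    a = k * b
    shape = ShellShape(L=L, k=k, v_m=wall_volume(a, b, h_am, L))
    state = ShellState(
        b=b,
        a=a,
        h=h_am,
        pmw=midwall_perimeter(b, h_am),
        lvv=cavity_volume(a, b, L),
        lam=1.0,
    )
    return shape, state


def _solve_inflation(pmw, shape: ShellShape):
    """Closed-form shell state at mid-wall perimeter ``pmw`` (scalar or array).

    With P = PMW/pi and C = (2/3)*pi*k*(1+L+L^2-L^3), conservation of
    V_M = C*B*H*(H + 2B) collapses under H = P - 2B to the quadratic
    C*P*B*(P - 2B) = V_M; the root with H <= 2B is
    B = (P + sqrt(P^2 - 8*V_M/(C*P))) / 4.

    Returns (B, H, LVV).
    """
    P = np.asarray(pmw, dtype=float) / math.pi
    C = shape.volume_coeff
    disc = P * P - 8.0 * shape.v_m / (C * P)
    if np.any(disc < 0.0):
        raise StretchUnattainableError(
            "no shell state exists at the requested perimeter "
            "(wall volume exceeds what the perimeter can enclose)"
        )
    b = 0.25 * (P + np.sqrt(disc))
    h = P - 2.0 * b
    lvv = C * b * b * b
    return b, h, lvv


def inflate_to_stretch(
    shape: ShellShape, am_state: ShellState, lambda_target: float
) -> ShellState:
    """Inflate the shell from its AM state to a prescribed mid-wall stretch.

    The returned state has ``pmw = lambda_target * am_state.pmw`` exactly,
    conserves the myocardial volume ``shape.v_m``, and keeps the shape
    (``k``, ``L``) constant.
    """
    if lambda_target < 1.0:
        raise GeometryError(f"stretch must be >= 1, got {lambda_target}")
    if lambda_target == 1.0:
        return am_state
    pmw = lambda_target * am_state.pmw
    b, h, lvv = _solve_inflation(pmw, shape)
    return ShellState(
        b=float(b), a=shape.k * float(b), h=float(h), pmw=pmw,
        lvv=float(lvv), lam=lambda_target,
    )


def trajectory(
    shape: ShellShape, am_state: ShellState, lambda_grid: Sequence[float]
) -> list[ShellState]:
    """States of one heart along a sorted grid of stretches (>= 1).

    Supports linearity diagnostics of LVV against PMW^3 and plot-ready
    trajectory export.
    """
    grid = list(lambda_grid)
    if any(g < 1.0 for g in grid):
        raise GeometryError("all grid stretches must be >= 1")
    if grid != sorted(grid):
        raise GeometryError("stretch grid must be sorted ascending")
    return [inflate_to_stretch(shape, am_state, lam) for lam in grid]
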