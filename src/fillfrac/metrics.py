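"""Preload-recruitable-stroke-work (PRSW) derived preload metrics.

Under PRSW, stroke work is linear in preload, SW = M_W * (EDV - V_W),
with slope M_W (a contractility index, work per volume) and volume-axis
intercept V_W (the dead-space volume).  Writing SW = MAP * SV and dividing
by EDV gives the three-factor ejection-fraction decomposition

    EF = FF * M_W / MAP,

where FF = (EDV - AMV)/EDV is the filling fraction: the preload factor and
the physiologic ceiling on EF (EF <= FF whenever M_W <= MAP in common
units).  M_W is conventionally reported in g/cm^2 and MAP in mmHg; the two
are the same physical unit, related by 1 mmHg = 1.35951 g/cm^2 (mercury
density 13.5951 g/cm^3 over a 0.1 cm column).  Pressures here carry an
explicit unit tag and never convert silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "MMHG",
    "G_PER_CM2",
    "G_PER_CM2_PER_MMHG",
    "UnitError",
    "Pressure",
    "convert_pressure",
    "stroke_work",
    "filling_fraction",
    "ef_decomposition",
    "mw_single_beat",
    "PreloadReport",
    "takeuchi_fixture",
    "takeuchi_summary",
]

MMHG = "mmHg"
G_PER_CM2 = "g/cm2"
#: 1 mmHg in g/cm^2 (mercury density 13.5951 g/cm^3 x 0.1 cm)
G_PER_CM2_PER_MMHG = 1.35951

_UNITS = {MMHG, G_PER_CM2}


class UnitError(ValueError):
    """Pressure-unit mismatch or unknown unit."""


@dataclass(frozen=True)
class Pressure:
    """A pressure (or work-per-volume) value with an explicit unit tag."""

    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in _UNITS:
            raise UnitError(f"unknown pressure unit {self.unit!r}; use {_UNITS}")

    def to(self, unit: str) -> "Pressure":
        return convert_pressure(self, unit)


def convert_pressure(p: Pressure, to_unit: str) -> Pressure:
    """Convert between mmHg and g/cm^2; roundtrip-exact to 1e-12."""
    if to_unit not in _UNITS:
        raise UnitError(f"unknown pressure unit {to_unit!r}; use {_UNITS}")
    if p.unit == to_unit:
        return p
    if p.unit == MMHG:  # -> g/cm2
        return Pressure(p.value * G_PER_CM2_PER_MMHG, to_unit)
    return Pressure(p.value / G_PER_CM2_PER_MMHG, to_unit)


def stroke_work(
    map_mmhg: float,
    sv: float | None = None,
    *,
    co: float | None = None,
    hr: float | None = None,
) -> float:
    """Stroke work MAP*SV in mmHg*mL.

    Equivalently CO*MAP/HR when cardiac output (mL/min) and heart rate
    (min^-1) are given instead of stroke volume.
    """
    if map_mmhg <= 0.0:
        raise ValueError(f"MAP must be positive, got {map_mmhg}")
    if sv is None:
        if co is None or hr is None:
            raise ValueError("give sv, or both co and hr")
        sv = co / hr
    if sv < 0.0:
        raise ValueError(f"stroke volume must be >= 0, got {sv}")
    return map_mmhg * sv


def filling_fraction(edv: float, amv: float) -> float:
    """Filling fraction FF = (EDV - AMV)/EDV.

    Dimensionless; BSA-indexed volumes give the identical result.  Values
    outside [0, 1] (amv < 0 or amv > edv) are returned raw -- the caller
    decides how to flag them.
    """
    if edv <= 0.0:
        raise ValueError(f"EDV must be positive, got {edv}")
    return (edv - amv) / edv


def ef_decomposition(ff: float, m_w: Pressure, map_pressure: Pressure) -> float:
    """EF = FF * M_W / MAP; both pressures must carry the same unit."""
    if m_w.unit != map_pressure.unit:
        raise UnitError(
            f"M_W in {m_w.unit!r} but MAP in {map_pressure.unit!r}: "
            "convert explicitly before combining"
        )
    if map_pressure.value <= 0.0:
        raise ValueError("MAP must be positive")
    return ff * m_w.value / map_pressure.value


def mw_single_beat(ef: float, ff: float, map_mmhg: float) -> Pressure:
    """Single-beat contractility M_W = EF*MAP/FF, in mmHg.

    Use ``.to(G_PER_CM2)`` for the conventional reporting unit.
    """
    if ff <= 0.0:
        raise ValueError("filling fraction must be positive to invert for M_W")
    return Pressure(ef * map_mmhg / ff, MMHG)


@dataclass(frozen=True)
class PreloadReport:
    """Per-beat preload metrics: fill volume (mL), filling fraction,
    ejection fraction, stroke work (mmHg*mL), contractility M_W and the
    afterload MAP."""

    fv: float
    ff: float
    ef: float
    sw_mmhg_ml: float | None
    m_w: Pressure | None
    afterload_map_mmhg: float | None


# Published group means (control EF > 0.5 vs heart-failure EF < 0.5):
# BSA-indexed dead-space volume and EDV (mL/m^2) and mean EF.
_TAKEUCHI_ROWS = [
    # group, vw_bsa, edv_bsa, ef
    ("group1_control", 19.1, 95.1, 0.66),
    ("group2_hfref", 59.3, 127.5, 0.40),
]


def takeuchi_fixture() -> pd.DataFrame:
    """Embedded two-group worked example (published group means).

    Columns: vw_bsa_ml_m2, edv_bsa_ml_m2, ef, plus the derived ff and the
    ff - ef gap in percentage points.  BSA indexing cancels in FF.
    """
    df = pd.DataFrame(
        _TAKEUCHI_ROWS, columns=["group", "vw_bsa_ml_m2", "edv_bsa_ml_m2", "ef"]
    ).set_index("group")
    df["ff"] = [
        filling_fraction(e, v) for e, v in zip(df.edv_bsa_ml_m2, df.vw_bsa_ml_m2)
    ]
    df["ff_ef_gap_pp"] = (df.ff - df.ef) * 100.0
    return df


def takeuchi_summary() -> dict[str, float]:
    """Cross-group headline numbers of the worked example.

    Ratios are expressed as percentages of the control value (e.g. a
    dead-space ratio of 310 means group 2 is 3.10x group 1); the FF
    reduction is relative to the control FF, in percent; gaps are FF - EF
    in percentage points.
    """
    df = takeuchi_fixture()
    g1, g2 = df.loc["group1_control"], df.loc["group2_hfref"]
    return {
        "ff_group1": g1.ff,
        "ff_group2": g2.ff,
        "vw_ratio_pct": 100.0 * g2.vw_bsa_ml_m2 / g1.vw_bsa_ml_m2,
        "edv_ratio_pct": 100.0 * g2.edv_bsa_ml_m2 / g1.edv_bsa_ml_m2,
        "ff_relative_reduction_pct": 100.0 * (g1.ff - g2.ff) / g1.ff,
        "ff_ef_gap_pp_group1": g1.ff_ef_gap_pp,
        "ff_ef_gap_pp_group2": g2.ff_ef_gap_pp,
    }
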