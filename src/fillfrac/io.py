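"""Tabular input/output and run configuration.

Beat tables are CSV with a header row, one row per beat:

    id, lvid_ed_cm, h_ed_cm, lvid_es_cm, h_es_cm, edv_ml, esv_ml,
    ess_g_cm2, rr_s, map_mmhg[, vcfc_s1]

``map_mmhg`` may be blank (contractility M_W is then not reported for the
row); ``vcfc_s1`` is an optional override of the computed V_CFC.  Rows
violating a physical invariant are rejected individually with a reason;
valid rows are still processed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .single_beat import C_1_DEFAULT, M_N_DEFAULT, BeatError, EchoBeat
from .metrics import G_PER_CM2_PER_MMHG

__all__ = [
    "SchemaError",
    "RowError",
    "RunConfig",
    "read_beats",
    "BEAT_COLUMNS",
]

BEAT_COLUMNS = [
    "id",
    "lvid_ed_cm",
    "h_ed_cm",
    "lvid_es_cm",
    "h_es_cm",
    "edv_ml",
    "esv_ml",
    "ess_g_cm2",
    "rr_s",
    "map_mmhg",
]
_OPTIONAL_COLUMNS = ["vcfc_s1"]


class SchemaError(ValueError):
    """Input table is missing a required column."""


@dataclass(frozen=True)
class RowError:
    """A rejected input row: its position, id (if readable) and reason."""

    row: int
    beat_id: str
    reason: str


@dataclass(frozen=True)
class RunConfig:
    """Configurable constants of the estimator and simulator.

    ``m_n``: normal-contractility stress-stretch slope, g/cm^2.
    ``c_1``: slope of the contractility-gain relation.
    ``pressure_conversion``: g/cm^2 per mmHg.
    ``precision``: significant digits in CSV output.
    ``seed``: RNG seed for simulation commands.
    ``ranges``: sampling-plan interval overrides, name -> [lo, hi].
    """

    m_n: float = M_N_DEFAULT
    c_1: float = C_1_DEFAULT
    pressure_conversion: float = G_PER_CM2_PER_MMHG
    precision: int = 6
    seed: int = 42
    ranges: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("m_n", "c_1", "pressure_conversion"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")
        if self.precision < 1:
            raise ValueError("precision must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def _is_blank(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def read_beats(path: str | Path) -> tuple[list[tuple[str, EchoBeat]], list[RowError]]:
    """Read and validate a beat table.

    Returns ``(beats, errors)`` where ``beats`` pairs each row's id with
    its validated :class:`EchoBeat` and ``errors`` lists rejected rows
    with 1-based data-row numbers.  A missing required column raises
    :class:`SchemaError` naming the column.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in BEAT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    has_vcfc = "vcfc_s1" in df.columns
    beats: list[tuple[str, EchoBeat]] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        beat_id = str(getattr(row, "id", f"row{i}"))
        try:
            mapv = getattr(row, "map_mmhg")
            vcfcv = getattr(row, "vcfc_s1") if has_vcfc else None
            beat = EchoBeat(
                lvid_ed=float(row.lvid_ed_cm),
                h_ed=float(row.h_ed_cm),
                lvid_es=float(row.lvid_es_cm),
                h_es=float(row.h_es_cm),
                edv=float(row.edv_ml),
                esv=float(row.esv_ml),
                ess=float(row.ess_g_cm2),
                rr=float(row.rr_s),
                map_mmhg=None if _is_blank(mapv) else float(mapv),
                vcfc_override=None if _is_blank(vcfcv) else float(vcfcv),
            )
        except (BeatError, TypeError, ValueError) as exc:
            errors.append(RowError(row=i, beat_id=beat_id, reason=str(exc)))
            continue
        beats.append((beat_id, beat))
    return beats, errors


def format_sig(value: float | None, precision: int) -> str:
    """Format to ``precision`` significant digits; blank for missing."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return f"{value:.{precision}g}"
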