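"""Single-beat estimator of the LV dead-space (absolute minimum) volume.

The chain runs entirely from one beat's echo-derived measurements:

1. V_CFC, the rate-corrected velocity of circumferential fiber shortening,
   from the mid-wall perimeters at ED/ES and the RR interval;
2. a contractility Z-score Z_C from the V_CFC vs. end-systolic wall stress
   (ESS) population relation;
3. a multiplicative contractility gain G_C = C1*Z + sqrt((C1*Z)^2 + 1);
4. the end-systolic mid-wall stretch lambda_ES = 1 + ESS/(G_C * M_N) from
   the linear myocyte stress-stretch law (x-intercept at stretch 1), and
   hence PMW_AM = PMW_ES / lambda_ES;
5. a two-point cubic law LVV = a*PMW^3 - b fitted through the ED and ES
   states, evaluated at PMW_AM to give AMV.

ESS is consumed in g/cm^2; PMW from clinical measurements is
pi*(LVID + H) since LVID = 2B.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "BeatError",
    "DegenerateFitError",
    "EchoBeat",
    "ContractilityScore",
    "CubicFit",
    "AmvEstimate",
    "NEGATIVE_AMV",
    "AMV_ABOVE_ESV",
    "M_N_DEFAULT",
    "C_1_DEFAULT",
    "vcfc",
    "z_score",
    "gain",
    "lambda_es",
    "pmw_am",
    "fit_ab",
    "amv",
    "estimate_amv_single_beat",
]

#: slope of the contractility-gain relation (population-level estimate)
C_1_DEFAULT = 0.2
#: normal-contractility slope of the ESS vs. (lambda_ES - 1) law, g/cm^2
M_N_DEFAULT = 500.0

# V_CFC vs. ESS population line: V_CFC = 1.23 - 0.0044*ESS (mean normal),
# vertical SD 0.06 s^-1.
_ZC_ESS_SLOPE = 0.0044  # s^-1 cm^2 / g
_ZC_INTERCEPT = 1.23  # s^-1
_ZC_SD = 0.06  # s^-1

#: diagnostic flags (reported, never clamped)
NEGATIVE_AMV = "NEGATIVE_AMV"
AMV_ABOVE_ESV = "AMV_ABOVE_ESV"


class BeatError(ValueError):
    """Beat measurements violate a physical invariant."""


class DegenerateFitError(BeatError):
    """ED and ES perimeters too close to fit the cubic law."""


@dataclass(frozen=True)
class EchoBeat:
    """One beat's clinical measurements.

    Lengths in cm, volumes in mL, ESS in g/cm^2, RR in s, MAP in mmHg.
    ``map_mmhg`` is optional (needed for contractility M_W, not for AMV);
    ``vcfc_override`` substitutes a literature V_CFC for the one computed
    from perimeters and RR.
    """

    lvid_ed: float
    h_ed: float
    lvid_es: float
    h_es: float
    edv: float
    esv: float
    ess: float
    rr: float
    map_mmhg: float | None = None
    vcfc_override: float | None = None

    def __post_init__(self) -> None:
        if not self.edv > self.esv > 0.0:
            raise BeatError(f"need EDV > ESV > 0, got EDV={self.edv}, ESV={self.esv}")
        if self.ess < 0.0:
            raise BeatError(f"ESS must be >= 0, got {self.ess}")
        if self.rr <= 0.0:
            raise BeatError(f"RR interval must be positive, got {self.rr}")
        for name in ("lvid_ed", "h_ed", "lvid_es", "h_es"):
            if getattr(self, name) <= 0.0:
                raise BeatError(f"{name} must be positive")
        if not self.pmw_ed > self.pmw_es:
            raise BeatError(
                f"PMW_ED={self.pmw_ed:.4f} must exceed PMW_ES={self.pmw_es:.4f}"
            )

    @property
    def pmw_ed(self) -> float:
        """End-diastolic mid-wall perimeter pi*(LVID_ED + H_ED), cm."""
        return math.pi * (self.lvid_ed + self.h_ed)

    @property
    def pmw_es(self) -> float:
        """End-systolic mid-wall perimeter pi*(LVID_ES + H_ES), cm."""
        return math.pi * (self.lvid_es + self.h_es)


@dataclass(frozen=True)
class ContractilityScore:
    """Contractility Z-score and the derived gain (g_c = 1 at z_c = 0)."""

    z_c: float
    g_c: float
    c_1: float = C_1_DEFAULT


@dataclass(frozen=True)
class CubicFit:
    """Coefficients of LVV = a*PMW^3 - b.

    ``a`` (mL/cm^3) captures shape and axial-to-hoop motion; ``b`` (mL) is
    the volume of muscle within the mid-wall shell.
    """

    a: float
    b: float


@dataclass(frozen=True)
class AmvEstimate:
    """Full single-beat estimator output, intermediates kept for audit."""

    z_c: float
    g_c: float
    lambda_es: float
    pmw_am: float
    fit: CubicFit
    amv: float
    flags: frozenset[str] = field(default_factory=frozenset)


def vcfc(pmw_ed: float, pmw_es: float, rr: float) -> float:
    """Rate-corrected velocity of circumferential fiber shortening, s^-1.

    Fractional mid-wall shortening (PMW_ED - PMW_ES)/PMW_ED divided by the
    cube root of the RR interval.
    """
    if not pmw_ed >= pmw_es > 0.0:
        raise BeatError(f"need PMW_ED >= PMW_ES > 0, got {pmw_ed}, {pmw_es}")
    if rr <= 0.0:
        raise BeatError(f"RR must be positive, got {rr}")
    return (pmw_ed - pmw_es) / pmw_ed / rr ** (1.0 / 3.0)


def z_score(vcfc_value: float, ess: float) -> float:
    """Contractility Z-score from the V_CFC vs. ESS population relation.

    Vertical displacement from the mean-normal line
    V_CFC = 1.23 - 0.0044*ESS, in units of its vertical SD (0.06 s^-1).
    """
    if ess < 0.0:
        raise BeatError(f"ESS must be >= 0, got {ess}")
    return (vcfc_value + _ZC_ESS_SLOPE * ess - _ZC_INTERCEPT) / _ZC_SD


def gain(z_c: float, c_1: float = C_1_DEFAULT) -> float:
    """Contractility gain G_C = C1*Z + sqrt((C1*Z)^2 + 1).

    Always positive, strictly increasing in ``z_c``, equal to 1 at normal
    contractility (z_c = 0), and reciprocal-symmetric:
    gain(z)*gain(-z) = 1.
    """
    if c_1 <= 0.0:
        raise BeatError(f"c_1 must be positive, got {c_1}")
    x = c_1 * z_c
    return x + math.sqrt(x * x + 1.0)


def lambda_es(ess: float, g_c: float, m_n: float = M_N_DEFAULT) -> float:
    """End-systolic mid-wall stretch from the linear stress-stretch law,
    lambda_ES = 1 + ESS/(G_C * M_N).  Always >= 1."""
    if ess < 0.0:
        raise BeatError(f"ESS must be >= 0, got {ess}")
    if g_c <= 0.0 or m_n <= 0.0:
        raise BeatError("gain and normal slope must be positive")
    return 1.0 + ess / (g_c * m_n)


def pmw_am(pmw_es: float, ess: float, g_c: float, m_n: float = M_N_DEFAULT) -> float:
    """Mid-wall perimeter of the fully contracted state,
    PMW_AM = PMW_ES / lambda_ES.  Always <= PMW_ES."""
    if pmw_es <= 0.0:
        raise BeatError(f"PMW_ES must be positive, got {pmw_es}")
    return pmw_es / lambda_es(ess, g_c, m_n)


def fit_ab(edv: float, esv: float, pmw_ed: float, pmw_es: float) -> CubicFit:
    """Two-point fit of LVV = a*PMW^3 - b through the ED and ES states.

    a = (EDV - ESV) / (PMW_ED^3 - PMW_ES^3); b follows so that both states
    are reproduced exactly.
    """
    if not (pmw_ed > 0.0 and pmw_es > 0.0):
        raise BeatError("perimeters must be positive")
    if not edv > esv:
        raise BeatError(f"need EDV > ESV, got {edv}, {esv}")
    c_ed = pmw_ed ** 3
    c_es = pmw_es ** 3
    denom = c_ed - c_es
    if abs(denom) < 1e-9 * max(c_ed, c_es):
        raise DegenerateFitError(
            "ED and ES perimeters coincide to relative 1e-9: cubic fit is degenerate"
        )
    a = (edv - esv) / denom
    b = -(esv * c_ed - edv * c_es) / denom
    return CubicFit(a=a, b=b)


def amv(fit: CubicFit, pmw_am_value: float) -> float:
    """Absolute minimum volume AMV = a*PMW_AM^3 - b, mL.

    May be negative for pathological inputs; returned raw (callers flag).
    """
    if pmw_am_value <= 0.0:
        raise BeatError(f"PMW_AM must be positive, got {pmw_am_value}")
    return fit.a * pmw_am_value ** 3 - fit.b


def estimate_amv_single_beat(
    beat: EchoBeat, c_1: float = C_1_DEFAULT, m_n: float = M_N_DEFAULT
) -> AmvEstimate:
    """Run the full single-beat chain on one beat.

    Computes PMW_ED/ES from LVID and H, V_CFC (or uses the override), the
    contractility score and gain, lambda_ES and PMW_AM, the two-point
    cubic fit, and AMV.  Unphysiologic AMV values (negative, or at/above
    ESV) are flagged, never clamped.
    """
    p_ed, p_es = beat.pmw_ed, beat.pmw_es
    v = beat.vcfc_override if beat.vcfc_override is not None else vcfc(
        p_ed, p_es, beat.rr
    )
    z = z_score(v, beat.ess)
    g = gain(z, c_1)
    lam = lambda_es(beat.ess, g, m_n)
    p_am = p_es / lam
    fit = fit_ab(beat.edv, beat.esv, p_ed, p_es)
    amv_hat = amv(fit, p_am)
    flags = set()
    if amv_hat < 0.0:
        flags.add(NEGATIVE_AMV)
    if amv_hat > beat.esv:
        flags.add(AMV_ABOVE_ESV)
    return AmvEstimate(
        z_c=z, g_c=g, lambda_es=lam, pmw_am=p_am, fit=fit,
        amv=amv_hat, flags=frozenset(flags),
    )
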