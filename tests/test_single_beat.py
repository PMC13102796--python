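"""Single-beat estimator chain: V_CFC, Z-score, gain, stretch, cubic fit, AMV."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fillfrac.geometry import inflate_to_stretch, shell_from_am
from fillfrac.single_beat import (
    AMV_ABOVE_ESV,
    NEGATIVE_AMV,
    BeatError,
    CubicFit,
    DegenerateFitError,
    EchoBeat,
    amv,
    estimate_amv_single_beat,
    fit_ab,
    gain,
    lambda_es,
    pmw_am,
    vcfc,
    z_score,
)


def beat_from_heart(shape, am, es, ed, g_c=1.0, m_n=500.0, map_mmhg=None):
    """Synthesize an echo beat from a simulated heart with an ESS that is
    exactly consistent with the stress-stretch law at gain ``g_c``, and a
    V_CFC override that makes the estimator recover that same gain."""
    ess = g_c * m_n * (es.lam - 1.0)
    z = (g_c - 1.0 / g_c) / (2.0 * 0.2)  # invert gain: z = (g - 1/g)/(2*c1)
    vcfc_override = 0.06 * z + 1.23 - 0.0044 * ess
    return EchoBeat(
        lvid_ed=2.0 * ed.b, h_ed=ed.h, lvid_es=2.0 * es.b, h_es=es.h,
        edv=ed.lvv, esv=es.lvv, ess=ess, rr=1.0,
        map_mmhg=map_mmhg, vcfc_override=vcfc_override,
    )


class TestVcfc:
    @pytest.mark.parametrize(
        "p_ed, p_es, rr, expected",
        [
            (13.0, 11.0, 1.0, 2.0 / 13.0),
            (13.0, 13.0, 1.0, 0.0),
            (13.0, 11.0, 0.729, 2.0 / 13.0 / 0.9),
        ],
    )
    def test_values(self, p_ed, p_es, rr, expected):
        assert vcfc(p_ed, p_es, rr) == pytest.approx(expected, rel=1e-9)

    def test_reversed_perimeters_rejected(self):
        with pytest.raises(BeatError):
            vcfc(11.0, 13.0, 1.0)


class TestZScore:
    @pytest.mark.parametrize(
        "v, ess, expected",
        [
            (0.966, 60.0, 0.0),   # on the mean-normal line
            (1.026, 60.0, 1.0),   # one vertical SD above it
            (1.23, 0.0, 0.0),     # intercept of the line
        ],
    )
    def test_values(self, v, ess, expected):
        assert z_score(v, ess) == pytest.approx(expected, abs=1e-9)


class TestGain:
    def test_normal_contractility_gives_unity(self):
        assert gain(0.0) == 1.0

    def test_direct_value(self):
        assert gain(2.0, 0.2) == pytest.approx(0.4 + math.sqrt(1.16), rel=1e-12)

    @given(z=st.floats(-5.0, 5.0))
    def test_reciprocal_symmetry(self, z):
        assert gain(z) * gain(-z) == pytest.approx(1.0, rel=1e-12)

    @given(z=st.floats(-5.0, 5.0))
    def test_positive_and_increasing(self, z):
        assert gain(z) > 0.0
        assert gain(z + 0.01) > gain(z)


class TestLambdaEs:
    @pytest.mark.parametrize(
        "ess, g_c, expected",
        [(60.0, 1.0, 1.12), (0.0, 1.0, 1.0), (60.0, 2.0, 1.06)],
    )
    def test_values(self, ess, g_c, expected):
        assert lambda_es(ess, g_c) == pytest.approx(expected, rel=1e-12)


class TestPmwAm:
    def test_normal_heart(self):
        assert pmw_am(11.2, 60.0, 1.0) == pytest.approx(10.0, rel=1e-12)

    def test_zero_stress_identity(self):
        assert pmw_am(11.2, 0.0, 1.0) == 11.2

    @given(ess=st.floats(1.0, 200.0), d=st.floats(1.0, 50.0))
    def test_monotone_decreasing_in_stress(self, ess, d):
        assert pmw_am(11.2, ess + d, 1.0) < pmw_am(11.2, ess, 1.0)


class TestFitAb:
    def test_worked_example(self):
        fit = fit_ab(120.0, 50.0, 12.0, 10.0)
        assert fit.a == pytest.approx(70.0 / 728.0, rel=1e-12)
        assert fit.b == pytest.approx(33600.0 / 728.0, rel=1e-12)
        assert fit.a * 1000.0 - fit.b == pytest.approx(50.0, rel=1e-12)

    def test_thin_hemisphere_recovers_closed_form(self):
        """States of a thin hemispherical shell recover the half-sphere
        cubic coefficient a = 1/(12*pi^2), within 0.2% of the reported
        0.00845."""
        shape, am = shell_from_am(3.0, 0.02, k=1.0, L=0.0)
        es = inflate_to_stretch(shape, am, 1.12)
        ed = inflate_to_stretch(shape, am, 1.30)
        fit = fit_ab(ed.lvv, es.lvv, ed.pmw, es.pmw)
        assert fit.a == pytest.approx(1.0 / (12.0 * math.pi**2), rel=1e-3)
        assert fit.a == pytest.approx(0.00845, rel=2e-3)

    @given(
        lvid=st.floats(2.6, 4.6), h=st.floats(1.0, 2.0),
        k=st.floats(1.0, 2.0), L=st.floats(0.0, 0.375),
        lam_es=st.floats(1.06, 1.18), lam_ed=st.floats(1.24, 1.36),
    )
    def test_interpolation_exactness(self, lvid, h, k, L, lam_es, lam_ed):
        shape, am = shell_from_am(lvid, h, k, L)
        es = inflate_to_stretch(shape, am, lam_es)
        ed = inflate_to_stretch(shape, am, lam_ed)
        fit = fit_ab(ed.lvv, es.lvv, ed.pmw, es.pmw)
        assert fit.a * ed.pmw**3 - fit.b == pytest.approx(ed.lvv, rel=1e-9)
        assert fit.a * es.pmw**3 - fit.b == pytest.approx(es.lvv, rel=1e-9)
        assert fit.a > 0.0

    def test_degenerate_perimeters_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_ab(120.0, 50.0, 10.0, 10.0 * (1.0 - 1e-12))


class TestAmv:
    def test_worked_example(self):
        fit = CubicFit(a=70.0 / 728.0, b=33600.0 / 728.0)
        assert amv(fit, 9.0) == pytest.approx(23.942, abs=5e-4)

    def test_pass_through_at_es(self):
        fit = fit_ab(120.0, 50.0, 12.0, 10.0)
        assert amv(fit, 10.0) == pytest.approx(50.0, rel=1e-12)


class TestEstimateChain:
    def test_stress_pathway_inverts_exactly(self, midrange_heart):
        shape, am = midrange_heart
        es = inflate_to_stretch(shape, am, 1.12)
        ed = inflate_to_stretch(shape, am, 1.30)
        for g_c in (0.5, 1.0, 1.8):
            beat = beat_from_heart(shape, am, es, ed, g_c=g_c)
            est = estimate_amv_single_beat(beat)
            assert est.g_c == pytest.approx(g_c, rel=1e-9)
            assert est.pmw_am == pytest.approx(am.pmw, rel=1e-9)

    def test_zero_stress_gives_amv_equal_esv(self):
        beat = EchoBeat(
            lvid_ed=5.0, h_ed=1.0, lvid_es=4.0, h_es=1.4,
            edv=120.0, esv=50.0, ess=0.0, rr=0.8,
        )
        est = estimate_amv_single_beat(beat)
        assert est.lambda_es == 1.0
        assert est.amv == pytest.approx(beat.esv, rel=1e-12)

    def test_simulated_heart_beat_is_unflagged(self, midrange_heart):
        shape, am = midrange_heart
        es = inflate_to_stretch(shape, am, 1.12)
        ed = inflate_to_stretch(shape, am, 1.30)
        est = estimate_amv_single_beat(beat_from_heart(shape, am, es, ed))
        assert est.flags == frozenset()
        assert 0.0 < est.amv < es.lvv
        # and the estimate lands near the true dead-space volume
        assert est.amv == pytest.approx(am.lvv, rel=0.15)

    def test_amv_never_exceeds_esv_for_nonnegative_stress(self, midrange_heart):
        shape, am = midrange_heart
        es = inflate_to_stretch(shape, am, 1.12)
        ed = inflate_to_stretch(shape, am, 1.30)
        for ess in (0.0, 20.0, 60.0, 150.0):
            beat = EchoBeat(
                lvid_ed=2 * ed.b, h_ed=ed.h, lvid_es=2 * es.b, h_es=es.h,
                edv=ed.lvv, esv=es.lvv, ess=ess, rr=1.0,
            )
            est = estimate_amv_single_beat(beat)
            assert est.amv <= beat.esv + 1e-12

    def test_chain_monotone_in_stress_at_fixed_gain(self, midrange_heart):
        """With geometry and contractility gain fixed, higher end-systolic
        stress means a smaller estimated dead-space volume.  (The override
        keeps the beat on the mean-normal line so the inferred gain stays
        at 1; fed through the Z-score, a higher ESS would otherwise also
        raise the inferred contractility.)"""
        shape, am = midrange_heart
        es = inflate_to_stretch(shape, am, 1.12)
        ed = inflate_to_stretch(shape, am, 1.30)
        amvs = []
        for ess in (10.0, 40.0, 80.0, 140.0):
            beat = EchoBeat(
                lvid_ed=2 * ed.b, h_ed=ed.h, lvid_es=2 * es.b, h_es=es.h,
                edv=ed.lvv, esv=es.lvv, ess=ess, rr=1.0,
                vcfc_override=1.23 - 0.0044 * ess,
            )
            est = estimate_amv_single_beat(beat)
            assert est.g_c == pytest.approx(1.0, rel=1e-12)
            amvs.append(est.amv)
        assert all(x > y for x, y in zip(amvs, amvs[1:]))

    def test_negative_amv_flagged_not_clamped(self):
        """A huge stress pushes PMW_AM far below ES; AMV goes negative and
        is reported raw with a flag."""
        beat = EchoBeat(
            lvid_ed=5.0, h_ed=1.0, lvid_es=4.0, h_es=1.4,
            edv=120.0, esv=50.0, ess=200.0, rr=0.8, vcfc_override=0.2,
        )
        est = estimate_amv_single_beat(beat)
        assert est.amv < 0.0
        assert NEGATIVE_AMV in est.flags


class TestEchoBeat:
    def test_invariants_enforced(self):
        with pytest.raises(BeatError):
            EchoBeat(5.0, 1.0, 4.0, 1.4, edv=50.0, esv=120.0, ess=60.0, rr=0.8)
        with pytest.raises(BeatError):
            EchoBeat(4.0, 1.0, 5.0, 1.4, edv=120.0, esv=50.0, ess=60.0, rr=0.8)
        with pytest.raises(BeatError):
            EchoBeat(5.0, 1.0, 4.0, 1.4, edv=120.0, esv=50.0, ess=-1.0, rr=0.8)

    def test_perimeters_from_diameter_and_thickness(self):
        beat = EchoBeat(5.0, 1.0, 4.0, 1.4, edv=120.0, esv=50.0, ess=60.0, rr=0.8)
        assert beat.pmw_ed == pytest.approx(6.0 * math.pi, rel=1e-12)
        assert beat.pmw_es == pytest.approx(5.4 * math.pi, rel=1e-12)
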