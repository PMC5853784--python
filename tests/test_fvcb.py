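"""FvCB forward model, A-Ci inversion, and temperature normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from leafspec import fvcb
from leafspec.fvcb import (
    ACiCurve,
    FvCBError,
    FitWarning,
    GENERIC_C3_KINETICS as KIN,
    PhotoTraits,
    arrhenius_factor,
    fit_aci,
    fvcb_assimilation,
    normalize_vcmax25,
    simulate_aci,
    vcmax_at_temperature,
)


def scalar_fvcb(ci, vcmax, j, rd, tleaf, kin=KIN, o=210.0):
    """Independent scalar re-coding of the two limitation equations."""
    import math

    f = lambda e: math.exp(e * 1e3 * (tleaf - 25.0) / (8.314 * 298.15 * (tleaf + 273.15)))
    kc, ko, gs = kin.Kc25 * f(kin.E_Kc), kin.Ko25 * f(kin.E_Ko), kin.GammaStar25 * f(kin.E_GammaStar)
    ac = vcmax * (ci - gs) / (ci + kc * (1 + o / ko))
    aj = j * (ci - gs) / (4 * ci + 8 * gs)
    return min(ac, aj) - rd


class TestForwardModel:
    def test_compensation_point_gives_minus_rd(self):
        gs = KIN.GammaStar(25.0)
        assert fvcb_assimilation(gs, 100, 150, 1.0) == pytest.approx(-1.0, abs=1e-12)

    def test_high_ci_limits(self):
        # gross rates: Ac -> Vcmax, Aj -> J/4 as Ci -> infinity
        a = fvcb_assimilation(1e9, 100, 150, 0.0)
        assert a == pytest.approx(min(100, 150 / 4), rel=1e-6)

    def test_matches_independent_scalar_evaluation(self):
        ci_ladder = [60, 120, 250, 400, 700, 1100, 1500]
        for tleaf in (25.0, 32.0):
            for ci in ci_ladder:
                expect = scalar_fvcb(ci, 100, 150, 1.0, tleaf)
                got = fvcb_assimilation(ci, 100, 150, 1.0, tleaf)
                assert got == pytest.approx(expect, rel=1e-12)

    def test_nondecreasing_in_ci_and_continuous(self):
        ci = np.linspace(50, 1500, 400)
        a = fvcb_assimilation(ci, 120, 170, 1.0)
        assert np.all(np.diff(a) > -1e-9)
        # continuity at the regime switch: no step where Ac crosses Aj
        from scipy.optimize import brentq

        gs = KIN.GammaStar(25.0)
        km = KIN.Kc(25.0) * (1 + 210.0 / KIN.Ko(25.0))
        cross = brentq(
            lambda c: 120 * (c - gs) / (c + km) - 170 * (c - gs) / (4 * c + 8 * gs), 100, 1500
        )
        lo = fvcb_assimilation(cross - 1e-6, 120, 170, 1.0)
        hi = fvcb_assimilation(cross + 1e-6, 120, 170, 1.0)
        assert hi - lo == pytest.approx(0.0, abs=1e-4)

    def test_smoothing_theta_below_hard_minimum(self):
        ci = np.linspace(50, 1500, 50)
        hard = fvcb_assimilation(ci, 120, 170, 1.0)
        smooth = fvcb_assimilation(ci, 120, 170, 1.0, smoothing_theta=0.9)
        assert np.all(smooth <= hard + 1e-9)

    def test_domain_errors(self):
        with pytest.raises(FvCBError):
            fvcb_assimilation(-5.0, 100, 150, 1.0)
        with pytest.raises(FvCBError):
            fvcb_assimilation(300.0, -1, 150, 1.0)


class TestTemperatureNormalization:
    def test_identity_at_25(self):
        assert normalize_vcmax25(150.0, 25.0) == 150.0
        assert arrhenius_factor(25.0, 65.0) == 1.0

    def test_round_trip(self):
        v25 = normalize_vcmax25(150.0, 30.0)
        back = vcmax_at_temperature(v25, 30.0)
        assert back == pytest.approx(150.0, rel=1e-12)

    def test_scalar_oracle_at_30C(self):
        # independent evaluation of the Arrhenius factor for E = 65 kJ/mol
        import math

        factor = math.exp(65e3 * 5.0 / (8.314 * 298.15 * 303.15))
        assert normalize_vcmax25(150.0, 30.0, 65.0) == pytest.approx(150.0 / factor, rel=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(st.floats(25.1, 45.0), st.floats(20.0, 120.0))
    def test_normalization_shrinks_above_25(self, tleaf, e_v):
        assert normalize_vcmax25(100.0, tleaf, e_v) <= 100.0

    def test_tleaf_out_of_range(self):
        with pytest.raises(FvCBError):
            normalize_vcmax25(100.0, 60.0)

    def test_kinetics_evaluate_to_25C_values_exactly(self):
        assert KIN.Kc(25.0) == KIN.Kc25
        assert KIN.Ko(25.0) == KIN.Ko25
        assert KIN.GammaStar(25.0) == KIN.GammaStar25


class TestSimulateAci:
    def test_noise_free_points_on_model(self):
        photo = PhotoTraits(Vcmax=100, J=150, Rd=1.0, Tleaf=25)
        curve = simulate_aci(photo, fvcb.DEFAULT_CI_LEVELS, 0.0)
        expect = fvcb_assimilation(curve.ci, 100, 150, 1.0)
        assert np.allclose(curve.a, expect)

    def test_seed_determinism(self):
        photo = PhotoTraits(Vcmax=100, J=150, Rd=1.0, Tleaf=25)
        c1 = simulate_aci(photo, fvcb.DEFAULT_CI_LEVELS, 0.5, seed=9)
        c2 = simulate_aci(photo, fvcb.DEFAULT_CI_LEVELS, 0.5, seed=9)
        assert np.array_equal(c1.a, c2.a)

    def test_residual_sd_matches_noise_sd(self):
        photo = PhotoTraits(Vcmax=100, J=150, Rd=1.0, Tleaf=25)
        ci = np.linspace(60, 1500, 1000)
        curve = simulate_aci(photo, ci, 0.5, seed=4)
        resid = curve.a - fvcb_assimilation(ci, 100, 150, 1.0)
        assert np.std(resid) == pytest.approx(0.5, rel=0.10)


class TestCurveInvariants:
    def test_too_few_points(self):
        with pytest.raises(FvCBError, match=">=5"):
            ACiCurve(ci=np.array([100.0, 300, 700, 900]), a=np.zeros(4))

    def test_duplicate_ci(self):
        with pytest.raises(FvCBError, match="distinct"):
            ACiCurve(ci=np.array([100.0, 100, 300, 700, 900]), a=np.zeros(5))


class TestFitAci:
    @pytest.mark.parametrize("vcmax", [50.0, 150.0, 300.0])
    @pytest.mark.parametrize("rd", [0.5, 2.0])
    def test_noise_free_recovery_grid(self, vcmax, rd):
        """Noise-free identifiability across the parameter grid
        (J = 1.4 Vcmax): recovery within 0.5% relative error."""
        j = 1.4 * vcmax
        photo = PhotoTraits(Vcmax=vcmax, J=j, Rd=rd, Tleaf=25)
        curve = simulate_aci(photo, fvcb.DEFAULT_CI_LEVELS, 0.0)
        fit = fit_aci(curve)
        assert fit.Vcmax == pytest.approx(vcmax, rel=5e-3)
        assert fit.J == pytest.approx(j, rel=5e-3)
        assert fit.Rd == pytest.approx(rd, abs=0.05)
        assert fit.Vcmax25 == pytest.approx(vcmax, rel=5e-3)  # Tleaf = 25

    def test_limitation_labels_cover_both_regimes(self):
        photo = PhotoTraits(Vcmax=120, J=180, Rd=1.0, Tleaf=25)
        fit = fit_aci(simulate_aci(photo, fvcb.DEFAULT_CI_LEVELS, 0.0))
        assert fit.n_rubisco >= 1 and fit.n_rubp >= 1
        assert fit.limitation[0] == "Rubisco" and fit.limitation[-1] == "RuBP"

    def test_missing_high_ci_regime_warns(self):
        photo = PhotoTraits(Vcmax=120, J=180, Rd=1.0, Tleaf=25)
        curve = simulate_aci(photo, np.array([50.0, 80, 110, 150, 190]), 0.0)
        with pytest.warns(FitWarning, match="J is not estimable"):
            fit_aci(curve)

    def test_fixed_rd(self):
        photo = PhotoTraits(Vcmax=120, J=180, Rd=1.5, Tleaf=25)
        curve = simulate_aci(photo, fvcb.DEFAULT_CI_LEVELS, 0.0)
        fit = fit_aci(curve, fix_rd=1.5)
        assert fit.Rd == 1.5
        assert fit.Vcmax == pytest.approx(120, rel=5e-3)

    def test_recovery_at_off_reference_temperature(self):
        v25 = 150.0
        tleaf = 31.5
        vc = vcmax_at_temperature(v25, tleaf)
        photo = PhotoTraits(Vcmax=vc, J=1.6 * v25, Rd=1.0, Tleaf=tleaf)
        fit = fit_aci(simulate_aci(photo, fvcb.DEFAULT_CI_LEVELS, 0.0))
        assert fit.Vcmax == pytest.approx(vc, rel=5e-3)
        assert fit.Vcmax25 == pytest.approx(v25, rel=5e-3)
        assert fit.Vcmax25 < fit.Vcmax  # monotone normalization above 25 C
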