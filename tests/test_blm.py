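"""Unit and property tests for the biotic ligand model core."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from asblm.blm import (
    ECEstimate,
    ExtrapolatedBLM,
    PsiSlopeFit,
    SensitivityRecord,
    ec50_blm,
    environmental_modulator,
    fit_psi0_slope,
    inherent_sensitivity,
    normalized_ec50,
    predict_ec50_site,
    psi0_adjust,
    within_order_of_magnitude,
)
from asblm.constants import DEFAULT_BLM_CONSTANTS as C
from asblm.speciation import MediumComposition, speciate_medium
from conftest import random_medium


class TestEnvironmentalModulator:
    def test_zero_phosphate_closed_form(self):
        # EM = 1 / (10^3.067 * {H+}/10^-6.76 + 10^4.802) at pH 7, no P
        spec = speciate_medium(MediumComposition(
            label="noP", pH=7.0, totals={"Na": 1e-3, "Cl": 1e-3}))
        expected = 1.0 / (10 ** 3.067 * 1e-7 / 10 ** -6.76 + 10 ** 4.802)
        assert environmental_modulator(spec) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.561e-5, rel=1e-3)

    def test_monotone_in_phosphate(self):
        ems = []
        for p_mM in (0.0, 0.05, 0.2, 1.0, 5.0):
            m = MediumComposition(
                label=f"P{p_mM}", pH=7.0,
                totals={"P_total": p_mM * 1e-3}).with_charge_balance()
            ems.append(environmental_modulator(speciate_medium(m)))
        assert np.all(np.diff(ems) > 0)

    def test_acid_shifts_modulator_down(self):
        # More H+ pushes arsenate toward H2AsO4- which binds via the
        # K_XH2AsO4 {H+}/K_As term, enlarging the denominator.
        em_7 = environmental_modulator(speciate_medium(
            MediumComposition(label="a", pH=7.0).with_charge_balance()))
        em_5 = environmental_modulator(speciate_medium(
            MediumComposition(label="b", pH=5.0).with_charge_balance()))
        assert em_5 < em_7


class TestEc50Blm:
    def test_half_occupancy_equals_em(self, background_spec):
        est = ec50_blm(0.5, background_spec)
        assert est.value == pytest.approx(
            environmental_modulator(background_spec), rel=1e-12)
        assert est.basis == "blm"

    def test_monotone_in_f(self, background_spec):
        values = [ec50_blm(f, background_spec).value
                  for f in (0.05, 0.3, 0.6, 0.9, 0.99)]
        assert np.all(np.diff(values) > 0)

    @pytest.mark.parametrize("bad_f", [0.0, 1.0, -0.2, 1.5])
    def test_rejects_f_outside_unit_interval(self, bad_f, background_spec):
        with pytest.raises(ValueError):
            ec50_blm(bad_f, background_spec)

    def test_calibration_inverse(self, background_spec):
        # f = 0.626 in the background medium recovers ~45 uM: the inverse
        # of the calibration path (IS x EM with IS = 0.626/0.374).
        est = ec50_blm(0.626, background_spec)
        em = environmental_modulator(background_spec)
        assert est.value == pytest.approx(0.626 / 0.374 * em, rel=1e-12)
        assert est.value == pytest.approx(45.1e-6, rel=0.05)

    @given(f=st.floats(0.01, 0.99), seed=st.integers(0, 2_000))
    @settings(max_examples=25, deadline=None)
    def test_identity_with_is_times_em(self, f, seed):
        # f/(1-f) x EM computed directly == IS x EM via the
        # sensitivity-record round trip, to machine precision.
        spec = speciate_medium(random_medium(np.random.default_rng(seed)))
        direct = ec50_blm(f, spec).value
        sens = SensitivityRecord.from_f(f)
        via_registry = predict_ec50_site(
            sens, environmental_modulator(spec)).value
        assert direct == pytest.approx(via_registry, rel=1e-14)


class TestInherentSensitivity:
    def test_unit_sensitivity(self):
        rec = inherent_sensitivity(2.7e-5, 2.7e-5)
        assert rec.IS == pytest.approx(1.0)
        assert rec.f_mix50 == pytest.approx(0.5)

    def test_barley_calibration_with_printed_em(self):
        rec = inherent_sensitivity(45.1e-6, 2.70e-5)
        assert rec.IS == pytest.approx(1.675, rel=0.005)
        assert rec.f_mix50 == pytest.approx(0.626, abs=0.001)

    def test_fischeri_f_round_trip(self):
        # registry f = 0.616 -> IS -> f reproduces itself exactly
        IS = 0.616 / (1 - 0.616)
        rec = inherent_sensitivity(IS * 1.0, 1.0)
        assert rec.f_mix50 == pytest.approx(0.616, rel=1e-12)

    @given(f=st.floats(0.001, 0.999))
    @settings(max_examples=50, deadline=None)
    def test_f_round_trip_identity(self, f):
        sens = SensitivityRecord.from_f(f)
        back = inherent_sensitivity(sens.IS * 3.3e-5, 3.3e-5)
        assert back.f_mix50 == pytest.approx(f, rel=1e-9)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            inherent_sensitivity(0.0, 1e-5)


class TestPsi0Adjust:
    FIT = PsiSlopeFit("H. vulgare", -0.615, 45.1, 0.771)

    def test_no_shift_no_change(self):
        est = ECEstimate(45.1e-6, basis="blm")
        out = psi0_adjust(est, self.FIT, -53.8, -53.8)
        assert out.value == pytest.approx(est.value)
        assert out.basis == "blm+psi0"

    def test_barley_arithmetic(self):
        # 45.1 uM at -53.8 mV moved to -3.3 mV: 45.1 - 0.615*50.5 = 14.04 uM
        out = psi0_adjust(ECEstimate(45.1e-6), self.FIT, -3.3, -53.8)
        assert out.value * 1e6 == pytest.approx(45.1 - 0.615 * 50.5, rel=1e-12)

    def test_zero_slope_is_identity(self):
        fit = PsiSlopeFit("flat", 0.0, 45.1, 0.0)
        out = psi0_adjust(ECEstimate(45.1e-6), fit, 40.0, -53.8)
        assert out.value == pytest.approx(45.1e-6)

    def test_affine_path_independence(self):
        one_step = psi0_adjust(ECEstimate(45.1e-6), self.FIT, -3.3, -53.8)
        half = psi0_adjust(ECEstimate(45.1e-6), self.FIT, -28.0, -53.8)
        two_step = psi0_adjust(half, self.FIT, -3.3, -28.0)
        assert two_step.value == pytest.approx(one_step.value, rel=1e-12)

    def test_floor_warns(self):
        with pytest.warns(UserWarning, match="floor"):
            out = psi0_adjust(ECEstimate(5e-6), self.FIT, 10.0, -53.8)
        assert out.value == pytest.approx(0.01 * 5e-6)

    def test_no_floor_raises(self):
        with pytest.raises(ValueError, match="psi0 adjustment"):
            psi0_adjust(ECEstimate(5e-6), self.FIT, 10.0, -53.8,
                        floor_fraction=None)


class TestNormalizedEc50:
    FIT = PsiSlopeFit("H. vulgare", -0.615, 12.0, 0.771)

    def test_intercept_reference_point(self):
        assert normalized_ec50(ECEstimate(12.0e-6), self.FIT) == pytest.approx(1.0)

    def test_scale_free(self):
        for k in (0.5, 2.0, 10.0):
            fit = PsiSlopeFit("s", -0.615 * k, 12.0 * k, 0.771)
            assert normalized_ec50(ECEstimate(k * 12.0e-6), fit) == pytest.approx(1.0)

    def test_normalized_slope_consistency(self):
        # On the fitted line EC50(psi) = intercept + slope*psi, the
        # normalized value is 1 + (slope/intercept)*psi; with the published
        # H. vulgare fit the common normalized slope is about -0.055 /mV.
        slope, r2 = -0.615, 0.771
        intercept = 45.1 - slope * (-53.8)  # line through the 0.2 mM anchor
        fit = PsiSlopeFit("H. vulgare", slope, intercept, r2)
        ec50_at = ECEstimate((intercept + slope * -53.8) * 1e-6)
        norm = normalized_ec50(ec50_at, fit)
        assert norm == pytest.approx(1 + slope / intercept * -53.8, rel=1e-12)
        assert slope / intercept == pytest.approx(-0.055, abs=0.015)

    def test_rejects_nonpositive_intercept(self):
        with pytest.raises(ValueError, match="intercept"):
            normalized_ec50(ECEstimate(1e-5), PsiSlopeFit("s", -1.0, 0.0, 1.0))


class TestFitPsi0Slope:
    def test_collinear_points_exact(self):
        pts = [(-50.0, 40.0), (-30.0, 28.0), (-10.0, 16.0), (0.0, 10.0)]
        fit = fit_psi0_slope(pts)
        assert fit.slope == pytest.approx(-0.6, rel=1e-12)
        assert fit.intercept == pytest.approx(10.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_rejects_fewer_than_three(self):
        with pytest.raises(ValueError, match="3"):
            fit_psi0_slope([(-50.0, 40.0), (-10.0, 16.0)])

    def test_rejects_degenerate_psi(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_psi0_slope([(-5.0, 1.0), (-5.0, 2.0), (-5.0, 3.0)])

    def test_two_point_anchor_slope(self):
        # The printed ladder endpoints alone give (45.1-15.0)/(-53.8+3.3)
        # = -0.596 uM/mV, consistent in sign and size with the published
        # full-ladder slope of -0.615.
        two_point = (45.1 - 15.0) / (-53.8 - (-3.3))
        assert two_point == pytest.approx(-0.596, abs=0.001)
        assert abs(two_point - (-0.615)) < 0.05

    def test_noise_recovery_within_se(self):
        # 95% t-interval on the OLS slope covers the generating slope in
        # about 95% of replicates; demand at least 90%.
        from scipy import stats as sps

        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 200
        x = np.linspace(-55, -3, 6)
        tcrit = sps.t.ppf(0.975, df=x.size - 2)
        for _ in range(n_rep):
            y = 12.0 - 0.6 * x + rng.normal(0, 2.0, x.size)
            fit = fit_psi0_slope(list(zip(x, y)))
            resid = y - (fit.intercept + fit.slope * x)
            se = np.sqrt(resid.var(ddof=2) / ((x - x.mean()) ** 2).sum())
            hits += abs(fit.slope - (-0.6)) < tcrit * se
        assert hits / n_rep >= 0.90


class TestExtrapolatedBLM:
    def test_sklearn_param_interface(self):
        model = ExtrapolatedBLM(psi_slope=-0.615, floor_fraction=0.02)
        params = model.get_params()
        assert params["psi_slope"] == -0.615
        cloned = clone(model)
        assert cloned.get_params()["floor_fraction"] == 0.02

    def test_unfitted_predict_raises(self, background_spec):
        with pytest.raises(RuntimeError, match="not fitted"):
            ExtrapolatedBLM().predict([background_spec])

    def test_fit_predict_matches_manual_path(self, background_spec):
        model = ExtrapolatedBLM().fit(background_spec, 45.1e-6)
        spec20 = speciate_medium(MediumComposition.background_plant(20.0))
        pred = model.predict([background_spec, spec20])
        em_ref = environmental_modulator(background_spec)
        sens = inherent_sensitivity(45.1e-6, em_ref)
        assert pred[0] == pytest.approx(45.1e-6, rel=1e-12)  # self-prediction
        assert pred[1] == pytest.approx(
            predict_ec50_site(sens, environmental_modulator(spec20)).value,
            rel=1e-12)

    def test_psi0_correction_applied(self, background_spec):
        model = ExtrapolatedBLM(psi_slope=-0.615)
        model.fit(background_spec, 45.1e-6, psi0_ref_mV=-53.8)
        spec20 = speciate_medium(MediumComposition.background_plant(20.0))
        with_psi = model.predict_estimates([spec20], psi0_mV=[-3.3])[0]
        without = predict_ec50_site(model.sensitivity_,
                                    environmental_modulator(spec20))
        assert with_psi.basis == "blm+psi0"
        shift_uM = -0.615 * (-3.3 - (-53.8))
        assert with_psi.value * 1e6 == pytest.approx(
            without.value * 1e6 + shift_uM, rel=1e-10)


def test_order_of_magnitude_band():
    assert within_order_of_magnitude(14.0e-6, 15.0e-6)
    assert within_order_of_magnitude(1.6e-6, 15.0e-6)
    assert not within_order_of_magnitude(1.4e-6, 15.0e-6)
    with pytest.raises(ValueError):
        within_order_of_magnitude(-1.0, 1.0)
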