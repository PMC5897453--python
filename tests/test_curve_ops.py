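"""Tests of baseline correction, contact detection and the Sneddon fit."""

import numpy as np
import pytest
from sklearn.base import clone

from myoelast import (AcquisitionConfig, FitConfig, ForceCurve, SneddonModel,
                      analyze_curve, baseline_correct,
                      calibrate_spring_constant_thermal, detect_contact_point,
                      fit_sneddon, simulate_curve, to_force_indentation)
from myoelast.curve_ops import ContactNotFoundError
from myoelast.sneddon import BOLTZMANN_J_PER_K, cone_prefactor_pN_per_nm2


def _flat_curve(n=256, k=30.0, deflection=None, z0=0.0):
    z = z0 + np.arange(n, dtype=float)
    d = np.zeros(n) if deflection is None else deflection
    return ForceCurve(z, d, k)


class TestBaseline:
    def test_removes_its_own_linear_trend(self):
        z = np.arange(300, dtype=float)
        d = 2.0 + 0.01 * z
        corrected, sd = baseline_correct(ForceCurve(z, d, 30.0), 0.5)
        assert np.allclose(corrected.deflection_nm[:150], 0.0, atol=1e-10)
        assert sd == pytest.approx(0.0, abs=1e-10)

    def test_identity_on_zero_baseline(self):
        curve = _flat_curve()
        corrected, _ = baseline_correct(curve, 0.3)
        assert np.allclose(corrected.deflection_nm, 0.0, atol=1e-12)

    def test_recovers_injected_noise_sd_under_tilt(self):
        cfg = AcquisitionConfig(noise_sd_nm=0.3, baseline_tilt_nm_per_um=0.05)
        curve = simulate_curve(1000.0, 1200.0, cfg, seed=7)
        _, sd = baseline_correct(curve, 0.15)
        assert sd == pytest.approx(0.3, rel=0.2)

    def test_too_few_baseline_points_raises(self):
        with pytest.raises(ValueError):
            baseline_correct(_flat_curve(n=32), 0.1)


class TestContactDetection:
    def test_noiseless_contact_within_one_sample(self, noiseless_config):
        curve = simulate_curve(1000.0, 1200.0, noiseless_config, seed=0)
        corrected, sd = baseline_correct(curve, 0.15)
        z0, _ = detect_contact_point(corrected, "threshold", sd)
        dz = np.diff(curve.z_nm).max()
        assert abs(z0 - 1200.0) <= dz

    @pytest.mark.parametrize("method", ["threshold", "ratio_of_variances"])
    def test_all_zero_deflection_is_no_contact(self, method):
        with pytest.raises(ContactNotFoundError):
            detect_contact_point(_flat_curve(), method, 0.0)

    def test_methods_agree_on_step(self, rng):
        n, jump_at = 400, 250
        d = rng.normal(0.0, 0.3, n)
        d[jump_at:] += 10.0
        curve = _flat_curve(n=n, deflection=d)
        z0_thr, i_thr = detect_contact_point(curve, "threshold", 0.3)
        z0_rov, i_rov = detect_contact_point(curve, "ratio_of_variances", 0.3)
        assert abs(i_thr - i_rov) <= 2
        assert abs(i_thr - jump_at) <= 2


class TestForceIndentation:
    def test_direct_substitution(self):
        """F = k (d - d0), delta = (z - z0) - (d - d0) for a single sample."""
        z = np.linspace(0.0, 120.0, 61)  # includes z - z0 = 100 at z0 = 0
        d = np.zeros_like(z)
        d[-11] = 0.28135  # the sample at z = 100
        curve = ForceCurve(z, d, 30.0)
        delta, force = to_force_indentation(curve, 0.0, 0.0)
        i = np.argmax(force)
        assert force[i] == pytest.approx(30.0 * 0.28135, rel=1e-12)  # 8.44 pN
        assert delta[i] == pytest.approx(100.0 - 0.28135, rel=1e-12)  # 99.72

    def test_contact_origin_maps_to_zero(self):
        curve = _flat_curve()
        delta, force = to_force_indentation(curve, float(curve.z_nm[0]), 0.0)
        assert delta[0] == 0.0 and force[0] == 0.0

    def test_rigid_limit_gives_zero_indentation(self):
        z = np.arange(64, dtype=float)
        curve = ForceCurve(z, z - z[0], 30.0)  # d - d0 == z - z0
        delta, _ = to_force_indentation(curve, 0.0, 0.0)
        assert np.allclose(delta, 0.0)

    def test_contact_outside_range_raises(self):
        with pytest.raises(ValueError):
            to_force_indentation(_flat_curve(), -100.0, 0.0)


class TestSneddonFit:
    def test_closed_form_inversion_is_exact(self):
        delta = np.linspace(1.0, 300.0, 100)
        c = cone_prefactor_pN_per_nm2(1000.0)
        fit = fit_sneddon(delta, c * delta ** 2)
        assert fit.status == "ok"
        assert fit.youngs_modulus_Pa == pytest.approx(1000.0, rel=1e-12)

    def test_zero_force_flags_poor_fit(self):
        delta = np.linspace(1.0, 300.0, 64)
        fit = fit_sneddon(delta, np.zeros_like(delta))
        assert fit.status == "poor_fit"
        assert not np.isfinite(fit.youngs_modulus_Pa)

    def test_too_few_points_flags_low_indentation(self):
        fit = fit_sneddon(np.array([1.0, 2.0, 3.0]), np.array([1.0, 4.0, 9.0]))
        assert fit.status == "low_indentation"

    @pytest.mark.parametrize("E_Pa", [100.0, 500.0, 1000.0, 2000.0, 5000.0,
                                      100000.0])
    def test_noiseless_roundtrip(self, noiseless_config, E_Pa):
        """simulate -> detect -> fit recovers E to < 0.1% without noise."""
        curve = simulate_curve(E_Pa, 1200.0, noiseless_config, seed=1)
        fit = analyze_curve(curve)
        assert fit.status == "ok"
        assert fit.youngs_modulus_Pa == pytest.approx(E_Pa, rel=1e-3)

    def test_subsampling_invariance(self, noiseless_config):
        curve = simulate_curve(1000.0, 1200.0, noiseless_config, seed=1)
        half = ForceCurve(curve.z_nm[::2], curve.deflection_nm[::2],
                          curve.spring_constant_pN_per_nm)
        e_full = analyze_curve(curve).youngs_modulus_Pa
        e_half = analyze_curve(half).youngs_modulus_Pa
        assert e_half == pytest.approx(e_full, rel=5e-3)

    def test_modulus_monotone_in_generative_modulus(self, noiseless_config):
        estimates = [analyze_curve(
            simulate_curve(E, 1200.0, noiseless_config, seed=1)
        ).youngs_modulus_Pa for E in [100.0, 300.0, 900.0, 2700.0, 8100.0]]
        assert np.all(np.diff(estimates) > 0)

    def test_estimator_api_round_trips(self):
        model = SneddonModel(refine_contact=True, refine_span_nm=500.0)
        params = model.get_params()
        assert params["refine_span_nm"] == 500.0
        cloned = clone(model)
        delta = np.linspace(1.0, 200.0, 64)
        c = cone_prefactor_pN_per_nm2(720.0)
        cloned.fit(delta, c * delta ** 2)
        assert cloned.youngs_modulus_Pa_ == pytest.approx(720.0, rel=1e-6)
        pred = cloned.predict(delta)
        assert np.allclose(pred, c * (delta - cloned.contact_offset_nm_) ** 2,
                           rtol=1e-9)


class TestThermalCalibration:
    def test_equipartition_worked_example(self):
        """<d^2> = 1.404e-19 m^2 at 305.15 K gives k close to 30 pN/nm."""
        var_nm2 = 1.404e-19 / 1e-18
        record = np.array([np.sqrt(var_nm2), -np.sqrt(var_nm2)] * 600)
        record = record - record.mean()
        expected = BOLTZMANN_J_PER_K * 305.15 / 1.404e-19 * 1000.0
        result = calibrate_spring_constant_thermal(record, 305.15)
        # the two-point record has exactly the target variance up to ddof
        assert result.spring_constant_pN_per_nm == pytest.approx(
            expected, rel=2e-3)
        assert expected == pytest.approx(30.0, rel=1e-2)

    def test_inverse_proportional_to_variance(self, rng):
        base = rng.normal(0.0, 0.4, 4000)
        k1 = calibrate_spring_constant_thermal(base, 300.0)
        k2 = calibrate_spring_constant_thermal(base * np.sqrt(2.0), 300.0)
        assert k2.spring_constant_pN_per_nm == pytest.approx(
            k1.spring_constant_pN_per_nm / 2.0, rel=1e-9)

    def test_sampling_recovery_within_three_se(self, rng):
        var = 0.1404
        record = rng.normal(0.0, np.sqrt(var), 20_000)
        k_true = BOLTZMANN_J_PER_K * 305.15 / (var * 1e-18) * 1000.0
        k_est = calibrate_spring_constant_thermal(
            record, 305.15).spring_constant_pN_per_nm
        se = k_true * np.sqrt(2.0 / record.size)
        assert abs(k_est - k_true) < 3 * se

    def test_degenerate_records_rejected(self):
        with pytest.raises(ValueError):
            calibrate_spring_constant_thermal(np.zeros(2000), 300.0)
        with pytest.raises(ValueError):
            calibrate_spring_constant_thermal(np.random.default_rng(0)
                                              .normal(0, 1, 100), 300.0)
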