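"""Tests of the phantom generator and the force-curve forward model."""

import numpy as np
import pytest
from scipy.optimize import brentq

from myoelast import (AcquisitionConfig, make_phantom, simulate_curve,
                      simulate_map)
from myoelast.sneddon import (cone_prefactor_pN_per_nm2,
                              indentation_from_separation_nm,
                              sneddon_force_pN)
from myoelast.synthetic import (GroupSpec, SimulationError, sample_diameters_um,
                                sample_mixture)


class TestForwardModel:
    def test_worked_example_against_numeric_root(self):
        """delta(z) at E = 1 kPa, k = 30 pN/nm, 100 nm past contact must
        match an independent brentq solution of s = delta + c*delta^2/k."""
        E, k, s = 1000.0, 30.0, 100.0
        c = cone_prefactor_pN_per_nm2(E)
        delta_ref = brentq(lambda d: d + c * d * d / k - s, 0.0, s)
        delta = indentation_from_separation_nm(s, E, k)
        assert delta == pytest.approx(delta_ref, rel=1e-12)
        assert delta == pytest.approx(99.7186, abs=1e-3)
        assert c * delta ** 2 == pytest.approx(8.4406, abs=1e-3)

    @pytest.mark.parametrize("E_Pa", [100.0, 1000.0, 100000.0])
    def test_forward_inverse_consistency(self, E_Pa):
        """delta + F(delta)/k reproduces the separation to 1e-9 relative."""
        k = 30.0
        s = np.linspace(0.1, 2500.0, 200)
        delta = indentation_from_separation_nm(s, E_Pa, k)
        force = sneddon_force_pN(delta, E_Pa)
        assert np.allclose(delta + force / k, s, rtol=1e-9)

    def test_force_linear_in_modulus(self):
        delta = np.array([5.0, 20.0, 80.0])
        assert np.allclose(sneddon_force_pN(delta, 2000.0),
                           2.0 * sneddon_force_pN(delta, 1000.0))


class TestSimulateCurve:
    def test_precontact_deflection_is_zero(self, noiseless_config):
        curve = simulate_curve(1000.0, 1200.0, noiseless_config, seed=0)
        pre = curve.z_nm < 1200.0
        assert np.all(curve.deflection_nm[pre] == 0.0)

    def test_trigger_respected(self, noisy_config):
        curve = simulate_curve(800.0, 1200.0, noisy_config, seed=4)
        force = sneddon_force_pN(
            indentation_from_separation_nm(
                np.clip(curve.z_nm - 1200.0, 0, None), 800.0, 30.0), 800.0)
        dz = np.diff(curve.z_nm).max()
        increment = np.diff(force).max()
        assert force.max() <= noisy_config.trigger_force_pN + increment + 1e-9
        assert dz > 0

    def test_trigger_unreachable_raises(self):
        cfg = AcquisitionConfig(ramp_length_nm=500.0, samples_per_curve=64,
                                noise_sd_nm=0.0)
        with pytest.raises(SimulationError):
            simulate_curve(100.0, 400.0, cfg, seed=0)

    def test_rejects_nonpositive_modulus(self, noiseless_config):
        with pytest.raises(ValueError):
            simulate_curve(-5.0, 1200.0, noiseless_config)


class TestPhantom:
    def test_mixture_sample_mean_matches_closed_form(self, rng):
        """Empirical mixture moments converge to the closed-form values."""
        w1, mu1, s1, mu2, s2 = 0.5, 557.0, 80.0, 1200.0, 150.0
        n = 100_000
        vals = sample_mixture((w1, mu1, s1, mu2, s2), n, rng)
        mean_true = w1 * mu1 + (1 - w1) * mu2  # 878.5
        var_true = (w1 * (s1 ** 2 + mu1 ** 2)
                    + (1 - w1) * (s2 ** 2 + mu2 ** 2) - mean_true ** 2)
        se_mean = np.sqrt(var_true / n)
        assert abs(vals.mean() - mean_true) < 3 * se_mean
        # variance check, allowing 3 SE of the sample variance
        se_var = var_true * np.sqrt(2.0 / n)
        assert abs(vals.var() - var_true) < 4 * se_var

    def test_degenerate_mixture_gives_two_values(self, small_config, rng):
        vals = sample_mixture((0.4, 500.0, 0.0, 900.0, 0.0), 500, rng)
        assert set(np.unique(vals)) == {500.0, 900.0}

    def test_tube_apex_equals_radius(self, small_config):
        # center the tube on a pixel center so the profile apex is sampled
        ph = make_phantom(small_config, tube_radius_um=4.0, tube_center_um=3.5)
        assert ph.height_field_nm.max() == pytest.approx(4000.0, abs=1e-9)

    def test_cell_and_substrate_partition(self, small_config):
        ph = make_phantom(small_config, tube_radius_um=2.0)
        assert np.all(ph.modulus_field_Pa[~ph.cell_mask] == 1.0e5)
        assert np.all(ph.modulus_field_Pa > 0)

    @pytest.mark.parametrize("kwargs", [
        {"tube_radius_um": -1.0},
        {"mixture": (1.5, 500.0, 50.0, 900.0, 50.0)},
        {"mixture": (0.5, 900.0, 50.0, 500.0, 50.0)},
    ])
    def test_rejects_bad_geometry_or_mixture(self, small_config, kwargs):
        with pytest.raises(ValueError):
            make_phantom(small_config, **kwargs)


class TestSimulateMap:
    def test_grid_size_and_determinism(self, small_config):
        ph = make_phantom(small_config, tube_radius_um=2.0, seed=1)
        vol1, truth = simulate_map(ph, small_config, seed=5)
        vol2, _ = simulate_map(ph, small_config, seed=5)
        assert vol1.shape == (8, 10)
        assert sum(1 for _ in vol1.iter_pixels()) == 80
        for (i, j, c1), (_, _, c2) in zip(vol1.iter_pixels(),
                                          vol2.iter_pixels()):
            assert np.array_equal(c1.z_nm, c2.z_nm)
            assert np.array_equal(c1.deflection_nm, c2.deflection_nm)
        assert truth.true_modulus_Pa.shape == (8, 10)

    def test_flat_phantom_contacts_align(self):
        cfg = AcquisitionConfig(grid_rows=2, grid_cols=8, samples_per_curve=256,
                                noise_sd_nm=0.0, scan_width_um=8.0,
                                scan_height_um=2.0)
        ph = make_phantom(cfg, tube_radius_um=0.01, mixture=(0.5, 900.0, 10.0,
                                                             1100.0, 10.0))
        assert not ph.cell_mask.any()  # all substrate: flat at height 0
        vol, _ = simulate_map(ph, cfg, seed=2)
        first_contact = [c.z_nm[np.argmax(c.deflection_nm > 0)]
                         for _, _, c in vol.iter_pixels()]
        assert np.ptp(first_contact) < 1e-9


class TestCohortSpecs:
    def test_diameter_generator_self_consistency(self, rng):
        spec = GroupSpec("WT", 5)
        d = sample_diameters_um(spec, 4000, rng)
        se = spec.diameter_sd_um / np.sqrt(d.size)
        # truncation at 1.7 um shifts the mean by well under 1 SE at n=4000
        assert abs(d.mean() - 5.19) < 3 * se + 0.01
        assert d.min() >= spec.diameter_floor_um

    def test_zero_maps_rejected(self):
        with pytest.raises(ValueError):
            GroupSpec("WT", 0)
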