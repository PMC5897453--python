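"""Tests of map assembly, QC masking, ROI statistics and export."""

import numpy as np
import pandas as pd
import pytest
import tifffile

from myoelast import (AcquisitionConfig, ElasticityMap, ForceCurve,
                      RegionOfInterest, exclude_maps, export_maps,
                      make_phantom, process_volume, roi_statistics,
                      simulate_map)
from myoelast.forcemap import MapError, TopographyMap


def _flat_map(E_Pa=1000.0, noise=0.0, seed=0):
    cfg = AcquisitionConfig(grid_rows=4, grid_cols=8, scan_width_um=8.0,
                            scan_height_um=4.0, samples_per_curve=512,
                            noise_sd_nm=noise, seed=seed)
    lo = max(E_Pa - 1.0, 1.0)
    ph = make_phantom(cfg, tube_radius_um=0.01,
                      mixture=(0.5, lo, 0.0, E_Pa + 1.0, 0.0),
                      substrate_modulus_Pa=E_Pa)
    vol, truth = simulate_map(ph, cfg, seed=seed)
    return cfg, vol, truth


class TestProcessVolume:
    def test_flat_noiseless_map_is_uniform(self):
        _, vol, _ = _flat_map(1000.0)
        topo, emap, table = process_volume(vol)
        assert np.all(emap.qc_mask == "ok")
        assert np.allclose(emap.values, 1000.0, rtol=1e-3)
        assert np.nanmax(np.abs(topo.values - np.nanmean(topo.values))) < 1.0

    def test_half_cylinder_topography_recovered(self, small_config):
        ph = make_phantom(small_config, tube_radius_um=2.0, tube_center_um=3.5,
                          mixture=(0.5, 557.0, 80.0, 1200.0, 150.0), seed=2)
        vol, _ = simulate_map(ph, small_config, seed=2)
        topo, _, _ = process_volume(vol)
        # noiseless: re-zeroed apex matches the tube height to ~1 nm
        assert np.nanmax(topo.values) == pytest.approx(
            ph.height_field_nm.max(), abs=1.0)

    def test_flat_noisy_topography_rmse(self):
        """Contact-height noise on the stiff flat substrate stays within
        ~2 nm RMSE at the default sample density and 0.3 nm deflection
        noise (the physics floor for the contact position is ~1 nm)."""
        cfg = AcquisitionConfig(grid_rows=4, grid_cols=8, scan_width_um=8.0,
                                scan_height_um=4.0, noise_sd_nm=0.3, seed=6)
        ph = make_phantom(cfg, tube_radius_um=0.01,
                          substrate_modulus_Pa=1.0e5)
        vol, _ = simulate_map(ph, cfg, seed=6)
        topo, _, _ = process_volume(vol)
        resid = topo.values - np.nanmean(topo.values)
        assert np.sqrt(np.nanmean(resid ** 2)) < 2.0

    def test_dead_pixel_is_isolated(self):
        _, vol, _ = _flat_map(1000.0)
        dead = vol[1, 3]
        vol.curves[1][3] = ForceCurve(dead.z_nm, np.zeros_like(dead.z_nm),
                                      dead.spring_constant_pN_per_nm)
        topo, emap, table = process_volume(vol)
        assert emap.qc_mask[1, 3] == "no_contact"
        mask = np.ones(emap.values.shape, bool)
        mask[1, 3] = False
        assert np.all(emap.qc_mask[mask] == "ok")

    def test_pixel_conservation(self, small_config):
        ph = make_phantom(small_config, tube_radius_um=2.0, seed=3)
        vol, _ = simulate_map(ph, small_config, seed=3)
        _, emap, table = process_volume(vol)
        counts = table["status"].value_counts()
        assert counts.sum() == np.prod(vol.shape)
        assert (emap.qc_mask == "ok").sum() == counts.get("ok", 0)

    def test_substrate_pixels_hit_modulus_ceiling(self):
        # 200 kPa substrate exceeds the default 100 kPa ceiling
        cfg = AcquisitionConfig(grid_rows=4, grid_cols=8, scan_width_um=8.0,
                                scan_height_um=4.0, samples_per_curve=512,
                                noise_sd_nm=0.0)
        ph = make_phantom(cfg, tube_radius_um=0.01,
                          substrate_modulus_Pa=2.0e5)
        vol, _ = simulate_map(ph, cfg, seed=1)
        _, emap, _ = process_volume(vol)
        assert np.all(emap.qc_mask == "excluded")
        assert not np.isfinite(emap.values).any()


class TestRoi:
    def _uniform_emap(self, values):
        values = np.asarray(values, float)
        qc = np.full(values.shape, "ok", dtype=object).astype(str)
        return ElasticityMap(values, qc, (0.4, 0.8), "Pa")

    def test_constant_region(self):
        emap = self._uniform_emap(np.full((4, 4), 720.0))
        mean, sem, n = roi_statistics(
            emap, RegionOfInterest.from_rect("body", 0, 0, 4, 4))
        assert mean == 720.0 and sem == 0.0 and n == 16

    def test_hand_computed_sem(self):
        emap = self._uniform_emap(
            np.array([[600.0, 700.0], [800.0, 900.0]]))
        mean, sem, n = roi_statistics(
            emap, RegionOfInterest.from_rect("body", 0, 0, 2, 2))
        assert mean == pytest.approx(750.0)
        assert sem == pytest.approx(np.std([600, 700, 800, 900], ddof=1) / 2.0)
        assert sem == pytest.approx(64.55, abs=0.01)

    def test_fully_masked_roi_raises(self):
        emap = self._uniform_emap(np.full((2, 2), 500.0))
        emap.qc_mask[:1, :] = "poor_fit"
        with pytest.raises(MapError):
            roi_statistics(emap, RegionOfInterest.from_rect("p", 0, 0, 1, 2))

    def test_empty_roi_rejected(self):
        with pytest.raises(MapError):
            RegionOfInterest("empty", np.empty((0, 2)))


class TestExclusion:
    def test_exclusion_bookkeeping(self):
        ids = [f"m{i:02d}" for i in range(16)]
        kept, audit = exclude_maps(ids, [("m03", "shape change"),
                                         ("m07", "detached")])
        assert len(kept) == 14
        assert audit["excluded"].sum() == 2
        assert set(audit["map_id"]) == set(ids)

    def test_empty_exclusion_is_identity(self):
        kept, audit = exclude_maps(["a", "b"], [])
        assert kept == ["a", "b"]
        assert not audit["excluded"].any()

    def test_duplicate_collapses_unknown_raises(self):
        kept, _ = exclude_maps(["a", "b"], [("a", "r"), ("a", "r2")])
        assert kept == ["b"]
        with pytest.raises(KeyError):
            exclude_maps(["a"], [("zzz", "r")])
        with pytest.raises(ValueError):
            exclude_maps(["a"], [("a", "")])


class TestExport:
    def test_csv_round_trip_and_tiff_shape(self, tmp_path, rng):
        values = rng.uniform(100.0, 9000.0, (5, 7))
        qc = np.full(values.shape, "ok", dtype=object).astype(str)
        topo = TopographyMap(rng.uniform(0, 2000, (5, 7)), qc, (0.4, 0.8), "nm")
        emap = ElasticityMap(values, qc, (0.4, 0.8), "Pa")
        paths = export_maps(topo, emap, tmp_path, basename="t")
        back = np.loadtxt(paths["elasticity_csv"], delimiter=",")
        assert np.array_equal(back, values)
        tif = tifffile.imread(paths["elasticity_tiff"])
        assert tif.shape == (5, 7)
        # TIFF keeps unclamped data even above the 5 kPa display scale
        assert tif.max() == np.float32(values.max())
        assert paths["surface_png"].exists()
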