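"""En-face maps, circular ROIs and lesion volume aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mpsf
from mpsf.enface import (EnfaceMap, ShapeError, drusen_thickness_map,
                         hrf_roi_volume, roi_mask, roi_mean_thickness,
                         roi_volume)


def uniform_map(geometry, value=0.0):
    return EnfaceMap(np.full(geometry.shape, float(value)), geometry)


class TestDrusenThickness:
    def test_identical_surfaces_give_zero(self, geometry):
        s = np.full(geometry.shape, 300.0)
        m = drusen_thickness_map(s, s, geometry)
        assert (m.values == 0).all()

    def test_constant_separation(self, geometry):
        rpe = np.full(geometry.shape, 250.0)
        bm = np.full(geometry.shape, 300.0)
        m = drusen_thickness_map(rpe, bm, geometry)
        assert (m.values == 50.0).all()

    def test_crossing_surfaces_clamp_to_zero(self, geometry):
        rpe = np.full(geometry.shape, 310.0)  # segmented below BM: artefact
        bm = np.full(geometry.shape, 300.0)
        bm[10, 10] = 320.0
        m = drusen_thickness_map(rpe, bm, geometry)
        assert m.values[10, 10] == 10.0
        assert m.values[0, 0] == 0.0
        assert (m.values >= 0).all()

    def test_shape_mismatch(self, geometry):
        with pytest.raises(ShapeError):
            drusen_thickness_map(np.zeros((10, 10)), np.zeros((10, 10)),
                                 geometry)


def brute_force_mask_cells(centre, radius_um, geometry):
    """Exhaustive scan of every raster cell."""
    cx, cy = centre
    dx = geometry.ascan_spacing_mm * 1000
    dy = geometry.bscan_spacing_mm * 1000
    cells = set()
    for j in range(geometry.n_bscan):
        for i in range(geometry.n_ascan):
            if ((i - cx) * dx) ** 2 + ((j - cy) * dy) ** 2 <= radius_um**2:
                cells.add((j, i))
    return cells


class TestRoiMask:
    def test_tiny_radius_single_cell(self, geometry):
        cfg = mpsf.QuantConfig(roi_diameter_um=2.0)  # radius < ascan spacing
        mask = roi_mask((100.0, 50.0), cfg, geometry)
        assert mask.n_cells == 1
        assert (mask.rows[0], mask.cols[0]) == (50, 100)

    def test_matches_exhaustive_oracle(self, geometry, quant):
        for centre in [(512.3, 48.7), (100.0, 10.0), (1000.9, 90.2)]:
            mask = roi_mask(centre, quant, geometry)
            got = set(zip(mask.rows.tolist(), mask.cols.tolist()))
            assert got == brute_force_mask_cells(centre, 120.0, geometry)

    def test_reflection_symmetry_about_raster_midline(self, geometry, quant):
        cy = (geometry.n_bscan - 1) / 2.0
        up = roi_mask((512.0, cy + 10.25), quant, geometry)
        dn = roi_mask((512.0, cy - 10.25), quant, geometry)
        reflected = sorted(zip((geometry.n_bscan - 1) - up.rows, up.cols))
        assert reflected == sorted(zip(dn.rows, dn.cols))

    def test_out_of_raster_centre_gives_flagged_empty_mask(self, geometry, quant):
        mask = roi_mask((-5.0, 0.0), quant, geometry)
        assert mask.n_cells == 0 and mask.out_of_raster


class TestRoiVolume:
    def test_single_cell_of_one_millimetre(self, geometry):
        # 1 mm thickness over one unit pixel = the unit pixel area in mm^3
        cfg = mpsf.QuantConfig(roi_diameter_um=2.0)
        mask = roi_mask((100.0, 50.0), cfg, geometry)
        m = uniform_map(geometry, 1000.0)
        assert roi_volume(m, mask) == pytest.approx(geometry.pixel_area_mm2,
                                                    rel=1e-12)

    def test_uniform_thickness_brute_force(self, geometry, quant):
        mask = roi_mask((512.0, 48.0), quant, geometry)
        m = uniform_map(geometry, 100.0)
        expected = mask.n_cells * 0.1 * geometry.pixel_area_mm2
        assert roi_volume(m, mask) == pytest.approx(expected, rel=1e-12)

    def test_zero_map(self, geometry, quant):
        mask = roi_mask((512.0, 48.0), quant, geometry)
        assert roi_volume(uniform_map(geometry), mask) == 0.0

    def test_equals_bruteforce_accumulation_on_random_map(self, geometry,
                                                          quant, rng):
        m = EnfaceMap(rng.uniform(0, 200, geometry.shape), geometry)
        mask = roi_mask((300.6, 40.2), quant, geometry)
        acc = 0.0
        for j, i in zip(mask.rows, mask.cols):
            acc += m.values[j, i] / 1000.0 * geometry.pixel_area_mm2
        assert roi_volume(m, mask) == pytest.approx(acc, rel=1e-12)

    def test_additive_over_mask_partition(self, geometry, quant, rng):
        m = EnfaceMap(rng.uniform(0, 200, geometry.shape), geometry)
        mask = roi_mask((512.0, 48.0), quant, geometry)
        half = mask.n_cells // 2
        import dataclasses
        a = dataclasses.replace(mask, rows=mask.rows[:half], cols=mask.cols[:half])
        b = dataclasses.replace(mask, rows=mask.rows[half:], cols=mask.cols[half:])
        assert roi_volume(m, mask) == pytest.approx(
            roi_volume(m, a) + roi_volume(m, b), rel=1e-12)

    def test_monotone_in_thickness(self, geometry, quant, rng):
        base = rng.uniform(0, 100, geometry.shape)
        lo = EnfaceMap(base, geometry)
        hi = EnfaceMap(base + rng.uniform(0, 50, geometry.shape), geometry)
        mask = roi_mask((512.0, 48.0), quant, geometry)
        assert roi_volume(hi, mask) >= roi_volume(lo, mask)


class TestMeanThickness:
    def test_uniform(self, geometry, quant):
        mask = roi_mask((512.0, 48.0), quant, geometry)
        assert roi_mean_thickness(uniform_map(geometry, 50.0), mask) == 50.0

    def test_zeros_count_toward_mean(self, geometry, quant):
        mask = roi_mask((512.0, 48.0), quant, geometry)
        vals = np.zeros(geometry.shape)
        half = mask.n_cells // 2
        vals[mask.rows[:half], mask.cols[:half]] = 100.0
        m = EnfaceMap(vals, geometry)
        assert roi_mean_thickness(m, mask) == pytest.approx(100.0 * half
                                                            / mask.n_cells)

    def test_algebraic_identity_with_volume(self, geometry, quant, rng):
        m = EnfaceMap(rng.uniform(0, 150, geometry.shape), geometry)
        mask = roi_mask((700.4, 60.1), quant, geometry)
        vol = roi_volume(m, mask)
        mean_um = roi_mean_thickness(m, mask)
        assert mean_um == pytest.approx(
            vol / (mask.n_cells * geometry.pixel_area_mm2) * 1000, rel=1e-9)

    def test_empty_mask_is_nan(self, geometry, quant):
        mask = roi_mask((-1.0, 0.0), quant, geometry)
        assert np.isnan(roi_mean_thickness(uniform_map(geometry), mask))


class TestHrfFloor:
    def _map_with_volume(self, geometry, mask, volume_mm3):
        vals = np.zeros(geometry.shape)
        per_cell_um = volume_mm3 / (mask.n_cells * geometry.pixel_area_mm2) * 1000
        vals[mask.rows, mask.cols] = per_cell_um
        return EnfaceMap(vals, geometry)

    def test_below_floor_set_to_zero(self, geometry, quant):
        mask = roi_mask((512.0, 48.0), quant, geometry)
        m = self._map_with_volume(geometry, mask, 5.9e-5)
        assert hrf_roi_volume(m, mask, quant) == 0.0

    def test_observed_minimum_passes_unchanged(self, geometry, quant):
        mask = roi_mask((512.0, 48.0), quant, geometry)
        m = self._map_with_volume(geometry, mask, 6.09e-5)
        assert hrf_roi_volume(m, mask, quant) == pytest.approx(6.09e-5,
                                                               rel=1e-9)

    def test_zero_stays_zero(self, geometry, quant):
        mask = roi_mask((512.0, 48.0), quant, geometry)
        assert hrf_roi_volume(uniform_map(geometry), mask, quant) == 0.0

    @settings(derandomize=True, max_examples=100)
    @given(raw=st.floats(0, 3e-4))
    def test_never_returns_values_inside_floor_gap(self, raw):
        geometry = mpsf.ScanGeometry()
        quant = mpsf.QuantConfig()
        mask = roi_mask((512.0, 48.0), quant, geometry)
        m = self._map_with_volume(geometry, mask, raw)
        out = hrf_roi_volume(m, mask, quant)
        assert out == 0.0 or out >= quant.hrf_min_volume_mm3
        # idempotence: feeding the floored value back changes nothing
        m2 = self._map_with_volume(geometry, mask, out)
        assert hrf_roi_volume(m2, mask, quant) == pytest.approx(out, rel=1e-9)


class TestExtractSpotFeatures:
    def test_zero_maps_give_zero_volumes(self, geometry, grid, quant):
        import pandas as pd
        from mpsf.grid import deg_to_px
        x, y, ok = deg_to_px(np.array(grid.x_deg), np.array(grid.y_deg),
                             geometry.centre_px, geometry)
        mapped = pd.DataFrame({"spot_id": grid.spot_ids, "x_px": x, "y_px": y,
                               "in_raster": ok})
        feats = mpsf.extract_spot_features(uniform_map(geometry),
                                           uniform_map(geometry), mapped, quant)
        assert len(feats) == 45
        assert (feats["drusen_vol_e3mm3"] == 0).all()
        assert not feats["drusen_present"].any()
        assert not feats["hrf_present"].any()

    def test_negative_map_rejected(self, geometry):
        with pytest.raises(ValueError):
            EnfaceMap(np.full(geometry.shape, -1.0), geometry)

    def test_tiff_round_trip(self, geometry, tmp_path, rng):
        m = EnfaceMap(rng.uniform(0, 100, geometry.shape).astype(np.float32)
                      .astype(float), geometry)
        p = tmp_path / "map.tiff"
        m.to_tiff(p)
        back = EnfaceMap.from_tiff(p, geometry)
        np.testing.assert_allclose(back.values, m.values, rtol=1e-6)
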