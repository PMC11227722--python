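"""Covariate derivation: binning, focal mode, patches, windows, terrain."""

import numpy as np
import pytest

from fisherhab import landscape as ls


class TestCategorizeCanopy:
    def test_quartile_bin_edges(self):
        vals = np.array([0.0, 25.0, 25.1, 50.0, 50.1, 75.0, 75.1, 76.0, 100.0])
        out = ls.categorize_canopy(vals)
        assert out.tolist() == [1, 1, 2, 2, 3, 3, 4, 4, 4]

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            ls.categorize_canopy(np.array([50.0, 101.0]))
        with pytest.raises(ValueError):
            ls.categorize_canopy(np.array([-0.5]))


class TestFocalMode:
    def test_uniform_raster_unchanged(self):
        r = np.full((6, 6), 4, dtype=np.int8)
        assert np.array_equal(ls.focal_mode(r), r)

    def test_isolated_cell_removed(self):
        r = np.full((5, 5), 4, dtype=np.int8)
        r[2, 2] = 1
        assert ls.focal_mode(r, passes=1)[2, 2] == 4

    def test_tie_keeps_center(self):
        r = np.array([[4, 4, 4], [1, 2, 1], [1, 4, 1]], dtype=np.int8)
        # window counts: four 4s, four 1s, one 2 -> tie between 1 and 4
        assert ls.focal_mode(r, passes=1)[1, 1] == 2

    @pytest.mark.parametrize("window", [0, 2, 4])
    def test_bad_window_error(self, window):
        with pytest.raises(ValueError):
            ls.focal_mode(np.ones((3, 3), dtype=int), window=window)

    def test_converges_within_twenty_passes(self, rng):
        """Repeated smoothing reaches a fixed point or 2-cycle on any input."""
        for _ in range(5):
            r = rng.integers(1, 5, (12, 12)).astype(np.int8)
            seen = [r]
            for _ in range(20):
                seen.append(ls.focal_mode(seen[-1], passes=1))
                if np.array_equal(seen[-1], seen[-2]) or (
                        len(seen) > 2 and np.array_equal(seen[-1], seen[-3])):
                    break
            else:
                pytest.fail("focal mode did not settle within 20 passes")


class TestDelineatePatches:
    def test_minimum_mapping_unit_is_strict(self):
        cat = np.full((20, 20), 4, dtype=np.int8)
        cat[:4, :10] = 1  # 40 cells = 0.40 ha at 10 m: retained
        keep = ls.delineate_patches(cat, 10.0)
        assert set(keep.table["category"]) == {"sparse", "dense"}
        assert keep.table["area_ha"].min() == pytest.approx(0.40)

        cat[0, 9] = 4  # 39 cells = 0.39 ha: merged away
        gone = ls.delineate_patches(cat, 10.0)
        assert set(gone.table["category"]) == {"dense"}
        assert len(gone.table) == 1

    def test_single_class_spans_extent(self):
        cat = np.full((8, 8), 2, dtype=np.int8)
        ps = ls.delineate_patches(cat, 10.0)
        assert len(ps.table) == 1
        assert ps.table["area_ha"].iloc[0] == pytest.approx(0.64)
        assert len(ps.boundary_segments) == 0

    def test_every_cell_assigned_and_min_area_enforced(self, rng):
        canopy = rng.uniform(0, 100, (40, 40))
        ps = ls.delineate_patches(ls.focal_mode(ls.categorize_canopy(canopy)),
                                  10.0)
        assert (ps.labels > 0).all()
        if len(ps.table) > 1:
            assert ps.table["area_ha"].min() >= 0.4 - 1e-9

    def test_empty_raster_error(self):
        with pytest.raises(ValueError):
            ls.delineate_patches(np.empty((0, 0), dtype=np.int8), 10.0)


class TestEdgeDensity:
    def _island(self):
        cat = np.full((50, 50), 4, dtype=np.int8)
        cat[20:30, 20:30] = 1  # 100 x 100 m patch
        return ls.delineate_patches(cat, 10.0)

    def test_isolated_patch_closed_form(self):
        ed = ls.edge_density(self._island(), 400.0)
        expected = 400.0 / (np.pi * 400.0 ** 2) * 1000.0  # m/m^2 -> km/km^2
        assert ed[25, 25] == pytest.approx(expected, rel=1e-9)

    def test_single_patch_is_zero_everywhere(self):
        ps = ls.delineate_patches(np.full((30, 30), 3, dtype=np.int8), 10.0)
        assert np.all(ls.edge_density(ps, 100.0) == 0)

    def test_disjoint_boundaries_add(self):
        cat = np.full((60, 60), 4, dtype=np.int8)
        cat[10:20, 10:20] = 1
        one = ls.edge_density(ls.delineate_patches(cat, 10.0), 500.0)[30, 30]
        cat[40:50, 40:50] = 1
        two = ls.edge_density(ls.delineate_patches(cat, 10.0), 500.0)[30, 30]
        assert two == pytest.approx(2 * one, rel=1e-9)

    def test_radius_below_resolution_error(self):
        with pytest.raises(ValueError):
            ls.edge_density(self._island(), 5.0)


class TestDistanceToEdge:
    def test_patch_center_and_boundary(self):
        cat = np.full((50, 50), 4, dtype=np.int8)
        cat[20:30, 20:30] = 1  # x, y in [200, 300)
        ps = ls.delineate_patches(cat, 10.0)
        d = ls.distance_to_edge(ps, [(250.0, 250.0), (200.0, 250.0)])
        assert d[0] == pytest.approx(50.0)
        assert d[1] == pytest.approx(0.0, abs=1e-12)

    def test_outside_extent_error(self):
        ps = ls.delineate_patches(np.full((5, 5), 1, dtype=np.int8), 10.0)
        with pytest.raises(ValueError, match="outside"):
            ls.distance_to_edge(ps, [(60.0, 10.0)])


class TestNeighborhoodMeanAndTPI:
    def test_constant_raster(self):
        r = np.full((15, 15), 7.5)
        assert np.allclose(ls.neighborhood_mean(r, 40.0, 10.0), 7.5)
        assert np.allclose(ls.tpi(r, 40.0, 10.0), 0.0)

    def test_small_radius_returns_own_value(self, rng):
        r = rng.uniform(0, 100, (10, 10))
        assert np.array_equal(ls.neighborhood_mean(r, 4.0, 10.0), r)

    def test_checkerboard_mean_near_half(self):
        cb = (np.indices((40, 40)).sum(axis=0) % 2).astype(float)
        nm = ls.neighborhood_mean(cb, 150.0, 10.0)
        assert abs(nm[20, 20] - 0.5) < 0.01

    def test_tpi_spike_and_antisymmetry(self, rng):
        e = np.zeros((9, 9))
        e[4, 4] = 10.0
        t = ls.tpi(e, 20.0, 10.0)
        assert t[4, 4] == pytest.approx(10.0)
        r = rng.uniform(0, 100, (12, 12))
        assert np.allclose(ls.tpi(-r, 30.0, 10.0), -ls.tpi(r, 30.0, 10.0))

    def test_nan_cells_ignored(self):
        r = np.full((7, 7), 4.0)
        r[3, 3] = np.nan
        nm = ls.neighborhood_mean(r, 15.0, 10.0)
        assert nm[3, 4] == pytest.approx(4.0)


class TestSlopeAspect:
    def test_flat_raster(self):
        s, a = ls.slope_linear_aspect(np.full((8, 8), 100.0), 10.0)
        assert np.all(s == 0)
        assert np.all(a == 0.5)

    def test_inclined_plane_interior_slope(self):
        x = np.arange(30) * 10.0
        plane = np.tile(0.1 * x, (30, 1))
        s, _ = ls.slope_linear_aspect(plane, 10.0)
        assert s[15, 15] == pytest.approx(np.degrees(np.arctan(0.1)))

    def test_descent_at_fold_bearing_maps_to_zero(self):
        # elevation dropping toward compass bearing 30 deg (the fold angle)
        xs = np.arange(20) * 10.0
        X, Y = np.meshgrid(xs, xs)
        elev = -(np.sin(np.radians(30)) * X + np.cos(np.radians(30)) * Y) * 0.1
        _, idx = ls.slope_linear_aspect(elev, 10.0)
        assert idx[10, 10] == pytest.approx(0.0, abs=1e-9)


class TestExtractCovariates:
    def test_uniform_landscape_means_equal_constant(self, small_landscape):
        import dataclasses
        flat = dataclasses.replace(
            small_landscape, canopy=np.full(small_landscape.shape, 80.0),
            elevation=np.full(small_landscape.shape, 1000.0))
        eng = ls.CovariateEngine(flat, scales=(100.0, 400.0))
        row = eng.extract([(700.0, 700.0)]).iloc[0]
        assert row["canopy_100"] == pytest.approx(80.0)
        assert row["canopy_400"] == pytest.approx(80.0)
        assert row["patch_category"] == "dense"
        veg_codes = flat.veg_codes
        props = [row[f"prop_veg{c}_100"] for c in veg_codes]
        assert sum(props) == pytest.approx(1.0)

    def test_row_matches_single_point_recomputation(self, small_landscape):
        eng = ls.CovariateEngine(small_landscape, scales=(100.0,))
        pt = (612.0, 733.0)
        row = eng.extract([pt]).iloc[0]
        i, j = small_landscape.cell_of(*pt)
        assert row["canopy_100"] == pytest.approx(
            ls.neighborhood_mean(small_landscape.canopy, 100.0, 10.0)[i, j])
        assert row["tpi_100"] == pytest.approx(
            ls.tpi(small_landscape.elevation, 100.0, 10.0)[i, j])
        assert row["dist_to_edge"] == pytest.approx(
            float(ls.distance_to_edge(eng.patches, [pt])[0]))
        assert row["patch_size_ha"] == pytest.approx(
            eng.patches.table.set_index("patch_id").loc[
                eng.patches.labels[i, j], "area_ha"])

    def test_outside_point_warns_and_is_nan(self, small_landscape):
        eng = ls.CovariateEngine(small_landscape, scales=(100.0,))
        with pytest.warns(UserWarning, match="outside"):
            out = eng.extract([(700.0, 700.0), (1e6, 1e6)])
        assert np.isnan(out["canopy_100"].iloc[1])
        assert not np.isnan(out["canopy_100"].iloc[0])

    def test_disturbed_points_dropped(self, small_landscape):
        eng = ls.CovariateEngine(small_landscape, scales=(100.0,))
        mask = np.zeros(small_landscape.shape, dtype=bool)
        i, j = small_landscape.cell_of(700.0, 700.0)
        mask[i, j] = True
        out = eng.extract([(700.0, 700.0), (200.0, 200.0)],
                          disturbed_mask=mask)
        assert len(out) == 1


def test_landscape_tiff_roundtrip(tmp_path, small_landscape):
    ls.write_landscape(small_landscape, str(tmp_path / "l"))
    back = ls.read_landscape(str(tmp_path / "l"))
    assert np.allclose(back.canopy, small_landscape.canopy, atol=1e-4)
    assert np.array_equal(back.vegclass, small_landscape.vegclass)
    assert back.resolution == small_landscape.resolution
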