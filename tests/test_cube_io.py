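"""Raster containers, TIFF roundtrips, compositing, masks, zonal stats."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from vegdyn import AnnualCube, GridTransform, ZoneMask
from vegdyn.io import (
    build_valid_mask,
    composite_growing_season,
    read_annual_cube,
    read_cube,
    write_annual_cube,
    write_single_band,
    zonal_summary,
)


class TestAnnualCube:
    def test_years_layer_mismatch_rejected(self):
        with pytest.raises(ValueError, match="years"):
            AnnualCube(np.zeros((3, 2, 2)), [2000, 2001])

    def test_non_consecutive_years_rejected(self):
        with pytest.raises(ValueError, match="consecutive"):
            AnnualCube(np.zeros((3, 2, 2)), [2000, 2002, 2003])

    def test_series_extraction(self):
        vals = np.arange(12, dtype=float).reshape(3, 2, 2)
        cube = AnnualCube(vals, [2000, 2001, 2002])
        assert cube.series(1, 0).tolist() == [2.0, 6.0, 10.0]


class TestRoundtrip:
    def test_write_read_identity(self, tmp_path):
        rng = np.random.default_rng(1)
        cube = AnnualCube(
            rng.uniform(0, 1, (3, 4, 4)),
            [2000, 2001, 2002],
            GridTransform(500.0, 0, 100.0, 0, -500.0, 4000.0),
        )
        path = tmp_path / "cube.tif"
        write_annual_cube(path, cube)
        back = read_cube(path)
        np.testing.assert_allclose(back.values, cube.values)
        assert back.years == cube.years
        assert back.transform == cube.transform
        assert not back.nodata_mask.any()

    def test_single_band_roundtrip_preserves_nan(self, tmp_path):
        layer = np.array([[0.5, np.nan], [0.2, 0.9]])
        path = tmp_path / "layer.tif"
        write_single_band(path, layer)
        back = read_cube(path)
        assert back.nodata_mask[0, 1]
        np.testing.assert_allclose(back.values[0][~back.nodata_mask],
                                   layer[~np.isnan(layer)])


class TestReadAnnualCube:
    def _write_year(self, path, data, transform=GridTransform()):
        write_single_band(path, data, transform)

    def test_per_year_files_assemble(self, tmp_path):
        for k in range(3):
            self._write_year(tmp_path / f"y{k}.tif", np.full((4, 4), 0.1 * (k + 1)))
        cube = read_annual_cube(
            [tmp_path / f"y{k}.tif" for k in range(3)], [2000, 2001, 2002]
        )
        assert cube.n_years == 3
        np.testing.assert_allclose(cube.values[2], 0.3)

    def test_shape_mismatch_names_offender(self, tmp_path):
        self._write_year(tmp_path / "a.tif", np.zeros((4, 4)))
        self._write_year(tmp_path / "b.tif", np.zeros((5, 4)))
        with pytest.raises(ValueError, match="b.tif"):
            read_annual_cube([tmp_path / "a.tif", tmp_path / "b.tif"], [2000, 2001])

    def test_paths_years_length_mismatch(self, tmp_path):
        self._write_year(tmp_path / "a.tif", np.zeros((2, 2)))
        with pytest.raises(ValueError, match="paths"):
            read_annual_cube([tmp_path / "a.tif"], [2000, 2001])

    def test_nodata_in_one_year_masks_pixel_everywhere(self, tmp_path):
        for k in range(3):
            data = np.full((3, 3), 0.5)
            if k == 1:
                data[2, 2] = np.nan
            self._write_year(tmp_path / f"y{k}.tif", data)
        cube = read_annual_cube(
            [tmp_path / f"y{k}.tif" for k in range(3)], [2000, 2001, 2002]
        )
        assert int(cube.nodata_mask.sum()) == 1
        assert cube.nodata_mask[2, 2]
        assert np.isnan(cube.values[:, 2, 2]).all()


class TestCompositeGrowingSeason:
    def test_mean_of_constant_layers(self):
        layers = [(dt.date(2000, m, 15), np.full((2, 2), 0.5)) for m in (4, 7, 10)]
        cube = composite_growing_season(layers)
        np.testing.assert_allclose(cube.values, 0.5)
        assert cube.years == [2000]

    def test_march_layer_excluded(self):
        layers = [
            (dt.date(2000, 3, 25), np.full((2, 2), 0.0)),
            (dt.date(2000, 4, 10), np.full((2, 2), 0.6)),
        ]
        cube = composite_growing_season(layers)
        np.testing.assert_allclose(cube.values[0], 0.6)

    def test_arithmetic_mean(self):
        layers = [
            (dt.date(2001, 5, 1), np.full((1, 1), 0.2)),
            (dt.date(2001, 6, 1), np.full((1, 1), 0.4)),
            (dt.date(2001, 9, 30), np.full((1, 1), 0.6)),
        ]
        cube = composite_growing_season(layers)
        np.testing.assert_allclose(cube.values[0, 0, 0], 0.4)

    def test_order_invariance(self, rng):
        layers = [
            (dt.date(2000 + y, m, 10), rng.uniform(0, 1, (3, 3)))
            for y in range(2) for m in (4, 6, 8, 10)
        ]
        fwd = composite_growing_season(layers)
        rev = composite_growing_season(layers[::-1])
        np.testing.assert_array_equal(fwd.values, rev.values)

    def test_gap_year_is_hard_error(self):
        layers = [
            (dt.date(2000, 6, 1), np.zeros((1, 1))),
            (dt.date(2002, 6, 1), np.zeros((1, 1))),
        ]
        with pytest.raises(ValueError, match="2001"):
            composite_growing_season(layers)

    def test_window_boundary_dates_included(self):
        layers = [
            (dt.date(2000, 4, 1), np.full((1, 1), 0.2)),
            (dt.date(2000, 10, 31), np.full((1, 1), 0.4)),
            (dt.date(2000, 11, 1), np.full((1, 1), 0.9)),
        ]
        cube = composite_growing_season(layers)
        np.testing.assert_allclose(cube.values[0, 0, 0], 0.3)


class TestValidMask:
    def test_threshold_is_inclusive(self):
        vals = np.stack([np.array([[0.05, 0.10], [0.15, 0.5]])] * 4)
        cube = AnnualCube(vals, [2000, 2001, 2002, 2003])
        mask = build_valid_mask(cube)
        assert mask.tolist() == [[False, True], [True, True]]

    def test_all_above_threshold_all_valid(self):
        cube = AnnualCube(np.full((4, 2, 2), 0.4), [2000, 2001, 2002, 2003])
        assert build_valid_mask(cube).all()

    def test_empty_valid_set_warns(self):
        cube = AnnualCube(np.full((4, 2, 2), 0.01), [2000, 2001, 2002, 2003])
        with pytest.warns(UserWarning, match="empty"):
            mask = build_valid_mask(cube)
        assert not mask.any()

    def test_period_mean_rule_keeps_dipping_pixel(self):
        # one low year does not invalidate a pixel under the period-mean rule
        vals = np.full((4, 1, 1), 0.3)
        vals[0] = 0.05
        cube = AnnualCube(vals, [2000, 2001, 2002, 2003])
        assert build_valid_mask(cube, rule="period_mean").all()
        with pytest.warns(UserWarning, match="empty"):
            assert not build_valid_mask(cube, rule="per_year").any()


class TestZonalSummary:
    zones = ZoneMask(np.array([[0, 0], [0, 0]]), {0: "GTGP"})

    def test_mean(self):
        layer = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = zonal_summary(layer, self.zones, "mean")
        assert out.loc[0, "mean"] == pytest.approx(2.5)

    def test_class_fractions(self):
        layer = np.array([["improve", "improve"], ["stable", "improve"]], dtype=object)
        zones = ZoneMask(np.array([[0, 0], [0, 1]]), {0: "GRP", 1: "NPA"})
        out = zonal_summary(layer, zones, "class_fraction")
        grp = out[out.zone == "GRP"].iloc[0]
        assert grp["frac_improve"] == pytest.approx(2 / 3)
        assert grp["frac_stable"] == pytest.approx(1 / 3)

    def test_fractions_sum_to_one(self, rng):
        layer = rng.integers(0, 4, (10, 10)).astype(object)
        zones = ZoneMask(rng.integers(0, 3, (10, 10)), {0: "a", 1: "b", 2: "c"})
        out = zonal_summary(layer, zones, "class_fraction")
        frac_cols = [c for c in out.columns if c.startswith("frac_")]
        sums = out[frac_cols].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_histogram_hand_count(self):
        layer = np.array([[10.0, 30.0], [50.0, 90.0]])
        out = zonal_summary(layer, self.zones, "histogram", bins=[0, 20, 40, 60, 80, 100])
        counts = [out.loc[0, c] for c in out.columns if c.startswith("bin_")]
        assert counts == [1, 1, 1, 0, 1]

    def test_empty_zone_yields_null_row(self):
        layer = np.array([[1.0, 2.0], [3.0, 4.0]])
        zones = ZoneMask(np.array([[0, 0], [0, 0]]), {0: "a", 1: "ghost"})
        out = zonal_summary(layer, zones, "mean")
        assert np.isnan(out[out.zone == "ghost"].iloc[0]["mean"])

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ValueError, match="statistic"):
            zonal_summary(np.zeros((2, 2)), self.zones, "median")

    def test_legend_must_cover_labels(self):
        with pytest.raises(ValueError, match="legend"):
            ZoneMask(np.array([[0, 1]]), {0: "only"})
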