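"""Buffer statistics and the named feature table."""

import numpy as np
import pandas as pd
import pytest

from lurpm.features import (
    BufferSpec,
    FeatureTable,
    build_feature_table,
    categorical_buffer_stats,
    continuous_buffer_stats,
    feature_column_names,
)
from lurpm.grids import Grid


def grid_of(values, res=10.0):
    return Grid(values=np.asarray(values, dtype=float), x0=0.0, y0=0.0,
                resolution=res)


class TestContinuousBufferStats:
    def test_constant_raster(self):
        g = grid_of(np.full((20, 20), 5.5))
        assert continuous_buffer_stats(g, (100, 100), 30.0) == (5.5, 5.5, 5.5)

    def test_tiny_radius_hits_single_cell(self):
        values = np.arange(400.0).reshape(20, 20)
        g = grid_of(values)
        # center of cell (3, 4): x = 45, y = 35
        stats = continuous_buffer_stats(g, (45.0, 35.0), 4.0)
        assert stats == (values[3, 4], values[3, 4], values[3, 4])

    def test_matches_exhaustive_scan(self, rng):
        g = grid_of(rng.normal(size=(30, 30)))
        xs, ys = g.cell_centers()
        X, Y = np.meshgrid(xs, ys)
        for _ in range(20):
            cx, cy = rng.uniform(20, 280, size=2)
            r = rng.uniform(6.0, 120.0)
            mask = (X - cx) ** 2 + (Y - cy) ** 2 <= r**2
            vals = g.values[mask]
            got = continuous_buffer_stats(g, (cx, cy), r)
            if len(vals) == 0:
                assert np.isnan(got[0])
            else:
                assert got == pytest.approx((vals.max(), vals.min(), vals.mean()))

    def test_center_outside_extent_rejected(self):
        with pytest.raises(ValueError):
            continuous_buffer_stats(grid_of(np.zeros((20, 20))), (1e4, 0), 10.0)


class TestCategoricalBufferStats:
    def test_majority_and_minority(self):
        g = grid_of([[1.0, 1.0], [2.0, 1.0]], res=10.0)
        cmax, cmin = categorical_buffer_stats(g, (10.0, 10.0), 20.0)
        assert (cmax, cmin) == (1.0, 2.0)

    def test_single_code(self):
        g = grid_of(np.full((10, 10), 3.0))
        assert categorical_buffer_stats(g, (50, 50), 25.0) == (3.0, 3.0)

    def test_frequency_tie_breaks_to_smallest_code(self):
        g = grid_of([[4.0, 2.0], [2.0, 4.0]], res=10.0)
        cmax, cmin = categorical_buffer_stats(g, (10.0, 10.0), 20.0)
        assert cmax == 2.0 and cmin == 2.0


class TestBuildFeatureTable:
    def make_layers(self, rng, n_cont=1, n_cat=1, shape=(40, 40)):
        layers = {}
        for i in range(n_cont):
            layers[f"C{i}"] = ("continuous", grid_of(rng.normal(size=shape)))
        for i in range(n_cat):
            layers[f"K{i}"] = (
                "categorical",
                grid_of(rng.integers(1, 4, size=shape).astype(float)),
            )
        return layers

    def test_column_count_four_continuous_five_categorical(self, rng):
        layers = self.make_layers(rng, n_cont=4, n_cat=5)
        pts = pd.DataFrame({"x": [200.0], "y": [200.0]})
        table = build_feature_table(pts, layers, BufferSpec(), target=None)
        # 3 stats x 4 layers x 10 radii + 2 stats x 5 layers x 10 radii
        assert len(table.feature_names) == 220

    def test_naming_convention(self, rng):
        layers = {"X": ("continuous", grid_of(rng.normal(size=(40, 40))))}
        pts = pd.DataFrame({"x": [200.0], "y": [200.0]})
        table = build_feature_table(pts, layers, BufferSpec(radii=(25.0,)),
                                    target=None)
        assert table.feature_names == ["X_max_25", "X_min_25", "X_mean_25"]

    def test_traffic_volume_column_name(self):
        names = feature_column_names([("DTV", "continuous")], BufferSpec())
        assert "DTV_min_750" in names

    def test_column_order_layer_then_stat_then_radius(self):
        names = feature_column_names(
            [("A", "continuous"), ("K", "categorical")], BufferSpec(radii=(25.0, 50.0))
        )
        assert names == [
            "A_max_25", "A_max_50", "A_min_25", "A_min_50",
            "A_mean_25", "A_mean_50",
            "K_cat_max_25", "K_cat_max_50", "K_cat_min_25", "K_cat_min_50",
        ]

    def test_rows_with_missing_predictors_dropped(self, rng):
        values = rng.normal(size=(40, 40))
        values[:10, :10] = np.nan  # no-data corner
        layers = {"X": ("continuous", grid_of(values))}
        pts = pd.DataFrame({"x": [50.0, 300.0], "y": [50.0, 300.0]})
        table = build_feature_table(pts, layers, BufferSpec(radii=(25.0,)),
                                    target=None)
        assert len(table) == 1 and table.data["x"].iloc[0] == 300.0

    def test_resolution_guard(self, rng):
        layers = {"X": ("continuous", grid_of(rng.normal(size=(40, 40)), res=20.0))}
        pts = pd.DataFrame({"x": [400.0], "y": [400.0]})
        with pytest.raises(ValueError, match="resolution"):
            build_feature_table(pts, layers, BufferSpec(radii=(25.0,)), target=None)

    def test_matches_single_point_api(self, rng):
        """The table path and the per-point statistics agree exactly."""
        layers = self.make_layers(rng, n_cont=1, n_cat=1)
        pts = pd.DataFrame({"x": rng.uniform(100, 300, 5),
                            "y": rng.uniform(100, 300, 5)})
        spec = BufferSpec(radii=(25.0, 75.0))
        table = build_feature_table(pts, layers, spec, target=None)
        for k in range(len(table)):
            c = (table.data["x"].iloc[k], table.data["y"].iloc[k])
            for r in spec.radii:
                mx, mn, me = continuous_buffer_stats(layers["C0"][1], c, r)
                assert table.data[f"C0_max_{r:g}"].iloc[k] == mx
                assert table.data[f"C0_mean_{r:g}"].iloc[k] == pytest.approx(me)
                cmax, cmin = categorical_buffer_stats(layers["K0"][1], c, r)
                assert table.data[f"K0_cat_max_{r:g}"].iloc[k] == cmax
                assert table.data[f"K0_cat_min_{r:g}"].iloc[k] == cmin

    def test_station_and_route_rows_share_code_path(self, small_scene):
        from lurpm.workflow import route_feature_table, station_feature_table

        route_table = route_feature_table(small_scene)
        station_table = station_feature_table(small_scene)
        assert route_table.feature_names == station_table.feature_names
        assert route_table.codebook == station_table.codebook

    def test_csv_roundtrip(self, rng, tmp_path):
        layers = self.make_layers(rng)
        pts = pd.DataFrame({"x": [200.0, 250.0], "y": [200.0, 250.0]})
        table = build_feature_table(pts, layers, BufferSpec(radii=(25.0, 50.0)),
                                    target=None)
        table.to_csv(tmp_path / "t.csv")
        back = FeatureTable.from_csv(tmp_path / "t.csv")
        pd.testing.assert_frame_equal(table.data, back.data)
        assert back.feature_names == table.feature_names
        assert back.codebook == table.codebook


class TestBufferSpec:
    def test_default_radii(self):
        assert BufferSpec().radii == (25.0, 50.0, 75.0, 100.0, 150.0, 200.0,
                                      250.0, 500.0, 750.0, 1000.0)

    @pytest.mark.parametrize("radii", [(), (0.0, 10.0), (50.0, 25.0)])
    def test_invalid_radii_rejected(self, radii):
        with pytest.raises(ValueError):
            BufferSpec(radii=radii)


class TestGrid:
    def test_csv_roundtrip(self, rng, tmp_path):
        g = grid_of(rng.normal(size=(12, 15)))
        g.to_csv(tmp_path / "g.csv")
        back = Grid.from_csv(tmp_path / "g.csv")
        assert np.allclose(back.values, g.values)
        assert back.resolution == g.resolution

    def test_value_at_nearest_cell(self):
        g = grid_of(np.arange(9.0).reshape(3, 3))
        assert g.value_at(15.0, 25.0) == 7.0  # col 1, row 2

    def test_outside_lookup_rejected(self):
        g = grid_of(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            g.value_at(-1.0, 0.0)
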