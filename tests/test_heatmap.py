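import numpy as np
import pandas as pd
import pytest

from egretwatch import behavior, heatmap
from egretwatch.heatmap import (
    CellGrid,
    assign_counts,
    counts_over_time,
    period_heatmap,
    render,
    spatial_smooth,
    temporal_smooth,
)


def records_at(points, species="great_egret", t="2019-09-23 06:00"):
    return pd.DataFrame(
        [
            {"timestamp": pd.Timestamp(t), "species": species,
             "x_min": x - 10.0, "y_min": y - 10.0,
             "x_max": x + 10.0, "y_max": y + 10.0, "score": 0.9}
            for x, y in points
        ]
    )


class TestCellGrid:
    def test_tiling_with_partial_cells(self):
        grid = CellGrid(2139, 1281, 200)
        assert (grid.n_rows, grid.n_cols) == (7, 11)
        # last row/col are partial; their centres sit inside the frame
        assert grid.centers_y[-1] == pytest.approx((1200 + 1281) / 2)
        assert grid.centers_x[-1] == pytest.approx((2000 + 2139) / 2)

    def test_distance_matrix_symmetric_zero_diag(self):
        grid = CellGrid(800, 600, 200)
        d = grid.distance_matrix()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)

    def test_neighbour_distance(self):
        grid = CellGrid(800, 800, 200)
        d = grid.distance_matrix()
        # horizontally adjacent full cells are one cell side apart
        assert d[0, 1] == pytest.approx(200.0)


class TestAssignCounts:
    def test_single_bird_in_cell(self):
        grid = CellGrid(800, 800, 200)
        c = assign_counts(records_at([(500, 700)]), grid)
        assert c[3, 2] == 1
        assert c.sum() == 1

    def test_boundary_goes_to_lower_index_side(self):
        grid = CellGrid(800, 800, 200)
        c = assign_counts(records_at([(200.0, 100.0)]), grid)
        # x == 200 lies in the half-open cell [200, 400)
        assert c[0, 1] == 1

    def test_conservation(self, two_day_stream):
        _, records, _ = two_day_stream
        grid = CellGrid(2139, 1281)
        frame = records[records["timestamp"] == records["timestamp"].iloc[0]]
        c = assign_counts(frame, grid, "great_egret")
        assert c.sum() == (frame["species"] == "great_egret").sum()


class TestSpatialSmooth:
    def test_beta_zero_gives_total_everywhere(self):
        grid = CellGrid(800, 600, 200)
        c = np.zeros((grid.n_rows, grid.n_cols))
        c[1, 2], c[0, 0] = 3, 2
        x = spatial_smooth(c, grid, beta=0.0)
        assert np.allclose(x, 5.0)

    def test_neighbour_closed_form(self):
        grid = CellGrid(800, 600, 200)
        c = np.zeros((grid.n_rows, grid.n_cols))
        c[1, 1] = 4.0
        x = spatial_smooth(c, grid, beta=0.01)
        # horizontally adjacent cell at d = 200 px: 4 * e^{-2}
        assert x[1, 2] == pytest.approx(4.0 * np.exp(-2.0), rel=1e-12)

    def test_large_beta_recovers_raw_counts(self, rng):
        grid = CellGrid(800, 600, 200)
        c = rng.integers(0, 5, (grid.n_rows, grid.n_cols)).astype(float)
        x = spatial_smooth(c, grid, beta=10.0)
        assert np.allclose(x, c, atol=1e-12)

    def test_double_loop_oracle_8x8(self, rng):
        grid = CellGrid(1600, 1600, 200)
        assert (grid.n_rows, grid.n_cols) == (8, 8)
        c = rng.poisson(1.0, (8, 8)).astype(float)
        beta = 0.007
        x = spatial_smooth(c, grid, beta)
        d = grid.distance_matrix().reshape(8, 8, 8, 8)
        oracle = np.zeros((8, 8))
        for i in range(8):
            for j in range(8):
                acc = 0.0
                for k in range(8):
                    for l in range(8):
                        dist = np.hypot(
                            grid.centers_y[i] - grid.centers_y[k],
                            grid.centers_x[j] - grid.centers_x[l],
                        )
                        acc += np.exp(-beta * dist) * c[k, l]
                oracle[i, j] = acc
        assert np.abs(x - oracle).max() <= 1e-10

    def test_mass_inflation_identity(self, rng):
        grid = CellGrid(600, 600, 200)
        c = rng.integers(0, 4, (3, 3)).astype(float)
        beta = 0.004
        x = spatial_smooth(c, grid, beta)
        kernel = np.exp(-beta * grid.distance_matrix())
        expected_total = (kernel.sum(axis=0) * c.ravel()).sum()
        assert x.sum() == pytest.approx(expected_total, rel=1e-12)

    def test_field_dominates_own_count(self, rng):
        grid = CellGrid(600, 600, 200)
        c = rng.integers(0, 4, (3, 3)).astype(float)
        x = spatial_smooth(c, grid, beta=0.01)
        assert (x >= c - 1e-12).all()

    def test_negative_beta_rejected(self):
        grid = CellGrid(600, 600, 200)
        with pytest.raises(ValueError):
            spatial_smooth(np.zeros((3, 3)), grid, beta=-0.1)


class TestTemporalSmooth:
    def test_lambda_one_is_identity(self, rng):
        x = rng.random((5, 3, 3))
        assert np.array_equal(temporal_smooth(x, 1.0), x)

    def test_lambda_zero_freezes_s0(self, rng):
        x = rng.random((5, 3, 3))
        s0 = np.full((3, 3), 0.7)
        out = temporal_smooth(x, 0.0, s0=s0)
        assert np.allclose(out, 0.7)

    def test_constant_fixed_point(self):
        x = np.full((6, 2, 2), 3.0)
        assert np.allclose(temporal_smooth(x, 0.3), 3.0)

    def test_bounded_by_running_extremes(self, rng):
        x = rng.random((20, 4, 4))
        out = temporal_smooth(x, 0.25)
        run_min = np.minimum.accumulate(x, axis=0)
        run_max = np.maximum.accumulate(x, axis=0)
        assert (out >= run_min - 1e-12).all()
        assert (out <= run_max + 1e-12).all()

    def test_lambda_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            temporal_smooth(np.zeros((2, 1, 1)), 1.5)


class TestPeriodHeatmap:
    def test_constant_field_mean(self):
        s = np.full((4, 2, 2), 2.5)
        assert np.allclose(period_heatmap(s), 2.5)

    def test_empty_period_rejected(self):
        s = np.zeros((3, 2, 2))
        times = pd.date_range("2019-09-23", periods=3, freq="1h")
        with pytest.raises(ValueError):
            period_heatmap(s, times, start="2020-01-01", end="2020-01-02")

    def test_hotspot_recovery(self, two_day_stream):
        config, records, ledger = two_day_stream
        grid = CellGrid(config.frame_width, config.frame_height)
        stack, times = counts_over_time(records, grid, "great_egret")
        x = spatial_smooth(stack, grid, beta=0.05)
        s = temporal_smooth(x, 0.1)
        mean_field = period_heatmap(s, times)
        col_mass = mean_field.sum(axis=0)
        top2 = set(np.argsort(col_mass)[-2:])
        planted = {
            int(m * config.frame_width // grid.cell_size)
            for m, _, _ in ledger["hotspots_x"]
        }
        assert top2 == planted


class TestStratification:
    def test_great_row_span_contains_little(self, two_day_stream):
        config, records, _ = two_day_stream
        grid = CellGrid(config.frame_width, config.frame_height)
        spans = {}
        for sp in ("great_egret", "little_egret"):
            stack, _ = counts_over_time(records, grid, sp)
            total = stack.sum(axis=0)
            rows = np.nonzero(total.sum(axis=1) > 0)[0]
            spans[sp] = (rows.min(), rows.max())
        g, l = spans["great_egret"], spans["little_egret"]
        assert g[0] <= l[0] and g[1] >= l[1]
        assert g != l  # strict containment


class TestRender:
    def test_all_zero_is_blank_background(self):
        z = np.zeros((3, 3))
        bg = np.full((60, 60, 3), 120, dtype=np.uint8)
        out = render(z, z, bg)
        assert np.array_equal(out, bg)

    def test_species_colour_channels(self):
        g = np.zeros((2, 2)); g[0, 0] = 1.0
        l = np.zeros((2, 2)); l[1, 1] = 1.0
        bg = np.full((40, 40, 3), 255, dtype=np.uint8)
        out = render(g, l, bg)
        assert out[5, 5, 0] > out[5, 5, 2]      # great hotspot is red
        assert out[35, 35, 2] > out[35, 35, 0]  # little hotspot is blue
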