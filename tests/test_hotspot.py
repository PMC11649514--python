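"""Heatmap tallies and the fixed-area, minimum-count hotspot search."""

import numpy as np
import pandas as pd
import pytest

import ki67hotspot as k
from ki67hotspot.errors import NoHotspotError
from ki67hotspot.hotspot import SearchParams, brute_force_hotspot


def _cells(x, y, positive):
    return pd.DataFrame({"x_um": np.asarray(x, float),
                         "y_um": np.asarray(y, float),
                         "ki67_class": np.where(positive, "positive", "negative")})


def _cluster(cx, cy, n, ratio, seed=0, spread=300.0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(cx - spread, cx + spread, n)
    y = rng.uniform(cy - spread, cy + spread, n)
    n_pos = int(round(ratio * n))
    pos = np.zeros(n, bool)
    pos[:n_pos] = True
    return _cells(x, y, pos)


def _exact_ratio_cluster(cx, cy, n, ratio, seed=0, spread=300.0, group=10):
    """Cluster whose every sub-window has exactly the nominal ratio: cells
    come in co-located groups of ``group`` with a fixed positive count, so
    no window boundary can separate a group."""
    assert n % group == 0 and abs(ratio * group - round(ratio * group)) < 1e-9
    rng = np.random.default_rng(seed)
    gx = rng.uniform(cx - spread, cx + spread, n // group)
    gy = rng.uniform(cy - spread, cy + spread, n // group)
    x = np.repeat(gx, group)
    y = np.repeat(gy, group)
    pos = np.tile(np.arange(group) < round(ratio * group), n // group)
    return _cells(x, y, pos)


class TestHeatmap:
    def test_single_positive_cell(self):
        grid = k.build_heatmap(_cells([75], [125], [True]), extent_um=(200, 200),
                               params=SearchParams(heatmap_bin_um=50))
        assert grid.total[2, 1] == 1 and grid.positive[2, 1] == 1
        assert grid.ratio[2, 1] == 1.0
        undefined = np.isnan(grid.ratio)
        assert undefined.sum() == grid.ratio.size - 1

    def test_all_positive_ratios_are_one(self):
        rng = np.random.default_rng(0)
        cells = _cells(rng.uniform(0, 500, 300), rng.uniform(0, 500, 300),
                       np.ones(300, bool))
        grid = k.build_heatmap(cells, extent_um=(500, 500))
        nonempty = grid.total > 0
        assert np.all(grid.ratio[nonempty] == 1.0)
        assert grid.total.sum() == 300

    def test_tallies_match_direct_count(self):
        rng = np.random.default_rng(1)
        cells = _cells(rng.uniform(0, 1000, 500), rng.uniform(0, 1000, 500),
                       rng.random(500) < 0.4)
        b = 50.0
        grid = k.build_heatmap(cells, extent_um=(1000, 1000),
                               params=SearchParams(heatmap_bin_um=b))
        for _, row in cells.iterrows():
            ix, iy = int(row.x_um // b), int(row.y_um // b)
            assert grid.total[iy, ix] >= 1
        # brute-force per-bin tally
        total = np.zeros_like(grid.total)
        positive = np.zeros_like(grid.positive)
        for _, row in cells.iterrows():
            ix, iy = int(row.x_um // b), int(row.y_um // b)
            total[iy, ix] += 1
            positive[iy, ix] += row.ki67_class == "positive"
        assert np.array_equal(total, grid.total)
        assert np.array_equal(positive, grid.positive)


class TestComputePi:
    @pytest.mark.parametrize("p,n,expected", [(0, 500, 0.0), (500, 500, 100.0),
                                              (250, 500, 50.0), (1, 3, 33.3)])
    def test_values(self, p, n, expected):
        assert k.compute_pi(p, n) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            k.compute_pi(0, 0)


class TestFindHotspot:
    def test_single_eligible_cluster(self):
        cells = _exact_ratio_cluster(500, 500, 600, 0.5, seed=2)
        hs = k.find_hotspot(cells, extent_um=(2000, 2000))
        assert hs.n_cells == 600
        assert hs.pi_percent == 50.0

    def test_higher_ratio_cluster_wins(self):
        a = _exact_ratio_cluster(400, 400, 600, 0.8, seed=3)
        b = _exact_ratio_cluster(1600, 1600, 600, 0.6, seed=4)
        hs = k.find_hotspot(pd.concat([a, b], ignore_index=True),
                            extent_um=(2200, 2200))
        cx, cy = hs.center_um
        assert np.hypot(cx - 400, cy - 400) < 300
        assert hs.pi_percent == 80.0

    def test_minimum_count_beats_purity(self):
        """A 499-cell pure cluster loses to an eligible 600-cell cluster."""
        pure = _cluster(400, 400, 499, 1.0, seed=5)
        big = _exact_ratio_cluster(1600, 1600, 600, 0.5, seed=6)
        hs = k.find_hotspot(pd.concat([pure, big], ignore_index=True),
                            extent_um=(2200, 2200))
        assert hs.n_cells == 600
        assert hs.pi_percent == 50.0

    def test_no_eligible_window_raises(self):
        cells = _cluster(500, 500, 100, 0.5, seed=7)
        with pytest.raises(NoHotspotError):
            k.find_hotspot(cells, extent_um=(2000, 2000))

    def test_equals_brute_force_on_random_instances(self):
        rng = np.random.default_rng(8)
        params = SearchParams(stride_um=50.0)
        for _ in range(30):
            n = int(rng.integers(600, 1500))
            cells = _cells(rng.uniform(0, 1000, n), rng.uniform(0, 1000, n),
                           rng.random(n) < rng.uniform(0.1, 0.9))
            try:
                fast = k.find_hotspot(cells, params=params, extent_um=(1000, 1000))
                fast_key = (fast.origin_um, fast.n_cells, fast.n_positive,
                            fast.pi_percent)
            except NoHotspotError:
                fast_key = None
            try:
                slow = brute_force_hotspot(cells, params=params,
                                           extent_um=(1000, 1000))
                slow_key = (slow.origin_um, slow.n_cells, slow.n_positive,
                            slow.pi_percent)
            except NoHotspotError:
                slow_key = None
            assert fast_key == slow_key

    def test_maximality_over_sampled_candidates(self):
        rng = np.random.default_rng(9)
        cells = _cells(rng.uniform(0, 2000, 6000), rng.uniform(0, 2000, 6000),
                       rng.random(6000) < 0.3)
        params = SearchParams()
        hs = k.find_hotspot(cells, params=params, extent_um=(2000, 2000))
        side = params.window_side_um
        x = cells["x_um"].to_numpy()
        y = cells["y_um"].to_numpy()
        pos = cells["ki67_class"].to_numpy() == "positive"
        for _ in range(50):
            x0 = rng.integers(0, int((2000 - side) / 25)) * 25.0
            y0 = rng.integers(0, int((2000 - side) / 25)) * 25.0
            sel = (x >= x0) & (x < x0 + side) & (y >= y0) & (y < y0 + side)
            n = sel.sum()
            if n >= params.min_cells:
                assert hs.n_positive * n >= pos[sel].sum() * hs.n_cells

    def test_dense_uniform_hotspot_at_least_global_pi(self):
        rng = np.random.default_rng(10)
        n = 20000
        cells = _cells(rng.uniform(0, 2000, n), rng.uniform(0, 2000, n),
                       rng.random(n) < 0.35)
        hs = k.find_hotspot(cells, extent_um=(2000, 2000))
        global_pi = 100 * (cells["ki67_class"] == "positive").mean()
        assert hs.pi_percent >= global_pi

    def test_sparse_margin_selected_near_minimum_count(self):
        """A sparse high-ratio margin wins with barely over 500 cells."""
        rng = np.random.default_rng(11)
        dense = _cluster(600, 1000, 8000, 0.3, seed=12, spread=550)
        n_margin = 520
        margin = _cells(rng.uniform(1500, 2000, n_margin),
                        rng.uniform(700, 1300, n_margin),
                        rng.random(n_margin) < 0.9)
        hs = k.find_hotspot(pd.concat([dense, margin], ignore_index=True),
                            extent_um=(2200, 2000))
        assert hs.n_cells <= 1.1 * 500
        assert hs.origin_um[0] >= 1200

    def test_tie_break_prefers_more_cells_then_topmost(self):
        # two windows, identical ratio 1.0; the larger cluster must win
        a = _cluster(400, 400, 550, 1.0, seed=13)
        b = _cluster(1600, 400, 700, 1.0, seed=14)
        hs = k.find_hotspot(pd.concat([a, b], ignore_index=True),
                            extent_um=(2200, 1200))
        assert hs.n_cells >= 700


class TestBruteForce:
    def test_no_eligible_window_same_error(self):
        cells = _cluster(500, 500, 50, 0.5, seed=15)
        with pytest.raises(NoHotspotError):
            brute_force_hotspot(cells, extent_um=(1000, 1000))

    def test_single_window_degenerate_slide(self):
        cells = _cluster(380, 380, 600, 0.5, seed=16, spread=200)
        params = SearchParams(stride_um=707.0)
        hs = brute_force_hotspot(cells, params=params, extent_um=(760, 760))
        assert hs.origin_um == (0.0, 0.0)
        assert hs.n_cells == 600
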