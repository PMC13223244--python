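"""Viewpoint sampling, line of sight, visual exposure, Rule-3 share."""

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from conftest import make_grid
from viewshed_oracle import exposure_oracle, line_of_sight_oracle
from urban330.rule3 import (
    ViewshedConfig,
    compute_visual_exposure,
    line_of_sight,
    rule3_compliance,
    rule3_population_share,
    sample_viewpoints,
)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs", [{"min_spacing_d_m": -5}, {"radius_r_m": 0}, {"tree_threshold": 0}]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ViewshedConfig(**kwargs)


class TestSampling:
    def test_single_cell_admits_one_point(self):
        cfg = ViewshedConfig(min_spacing_d_m=500, seed=3, max_sample_attempts=200)
        pts = sample_viewpoints(box(0, 0, 100, 100), cfg)
        assert pts.count == 1

    def test_deterministic_under_seed(self):
        cfg = ViewshedConfig(min_spacing_d_m=100, seed=11, max_sample_attempts=300)
        b = box(0, 0, 1000, 1000)
        a = sample_viewpoints(b, cfg)
        c = sample_viewpoints(b, cfg)
        assert np.array_equal(a.points, c.points)
        d = sample_viewpoints(b, ViewshedConfig(min_spacing_d_m=100, seed=12, max_sample_attempts=300))
        assert not np.array_equal(a.points, d.points)

    def test_pairwise_spacing_and_containment(self):
        cfg = ViewshedConfig(min_spacing_d_m=100, seed=0, max_sample_attempts=1000)
        b = box(0, 0, 1000, 1000)
        pts = sample_viewpoints(b, cfg).points
        assert len(pts) > 10
        diff = pts[:, None, :] - pts[None, :, :]
        dist = np.hypot(diff[..., 0], diff[..., 1])
        np.fill_diagonal(dist, np.inf)
        assert dist.min() >= 100.0
        assert (pts >= 0).all() and (pts <= 1000).all()

    def test_degenerate_boundary_rejected(self):
        with pytest.raises(ValueError, match="zero area"):
            sample_viewpoints(Polygon(), ViewshedConfig())


class TestLineOfSight:
    def test_flat_terrain_always_visible(self, flat_grid):
        cfg = ViewshedConfig(radius_r_m=250)
        assert line_of_sight(flat_grid, (50, 50), (250, 150), cfg)

    def test_intermediate_building_blocks(self):
        # 30 m obstacle between observer and target, eye line at 1.6 m
        h = np.zeros((1, 3))
        h[0, 1] = 30.0
        grid = make_grid(h)
        cfg = ViewshedConfig(radius_r_m=250)
        assert not line_of_sight(grid, (50, 50), (250, 50), cfg)

    def test_own_cell_obstacle_excluded(self):
        # a 50 m building in the target's own cell cannot hide the target
        h = np.zeros((1, 2))
        h[0, 1] = 50.0
        grid = make_grid(h)
        cfg = ViewshedConfig(radius_r_m=250)
        assert line_of_sight(grid, (50, 50), (150, 50), cfg)
        # and symmetrically for the observer's cell
        h2 = np.zeros((1, 2))
        h2[0, 0] = 50.0
        assert line_of_sight(make_grid(h2), (50, 50), (150, 50), cfg)

    def test_tie_blocks(self):
        # obstacle exactly at the sight-line height -> blocked
        h = np.zeros((1, 3))
        h[0, 1] = 1.6
        grid = make_grid(h)
        assert not line_of_sight(grid, (50, 50), (250, 50), ViewshedConfig(radius_r_m=250))
        h[0, 1] = 1.5999
        assert line_of_sight(make_grid(h), (50, 50), (250, 50), ViewshedConfig(radius_r_m=250))

    def test_out_of_grid_and_out_of_radius_rejected(self, flat_grid):
        cfg = ViewshedConfig(radius_r_m=100)
        with pytest.raises(ValueError, match="within the height grid"):
            line_of_sight(flat_grid, (-10, 50), (50, 50), cfg)
        with pytest.raises(ValueError, match="radius"):
            line_of_sight(flat_grid, (50, 50), (450, 50), cfg)


class TestExposure:
    def test_empty_point_set_gives_zero(self, flat_grid):
        cfg = ViewshedConfig()
        from urban330.rule3 import ObservationPointSet

        pts = ObservationPointSet(points=np.empty((0, 2)), config=cfg)
        out = compute_visual_exposure(flat_grid, pts, cfg)
        assert (out.exposure.values == 0).all()
        assert not out.visible_mask.any()

    def test_flat_grid_disk_membership(self, flat_grid):
        from urban330.rule3 import ObservationPointSet

        cfg = ViewshedConfig(radius_r_m=100)
        p = (450.0, 450.0)
        pts = ObservationPointSet(points=np.array([p]), config=cfg)
        out = compute_visual_exposure(flat_grid, pts, cfg)
        X, Y = flat_grid.cell_centers()
        expected = (X - p[0]) ** 2 + (Y - p[1]) ** 2 <= 100.0**2
        assert np.array_equal(out.visible_mask, expected)

    def test_additive_in_points(self):
        from urban330.rule3 import ObservationPointSet

        rng = np.random.default_rng(5)
        grid = make_grid(rng.uniform(0, 20, size=(8, 8)) * (rng.random((8, 8)) < 0.3))
        cfg = ViewshedConfig(radius_r_m=250)
        p1, p2 = (150.0, 350.0), (420.0, 430.0)
        both = compute_visual_exposure(
            grid, ObservationPointSet(np.array([p1, p2]), cfg), cfg
        )
        one = compute_visual_exposure(grid, ObservationPointSet(np.array([p1]), cfg), cfg)
        two = compute_visual_exposure(grid, ObservationPointSet(np.array([p2]), cfg), cfg)
        assert np.array_equal(both.exposure.values, one.exposure.values + two.exposure.values)

    def test_matches_exact_oracle_on_random_grids(self):
        from urban330.rule3 import ObservationPointSet

        rng = np.random.default_rng(42)
        for _ in range(8):
            h = rng.uniform(0, 25, size=(12, 12)) * (rng.random((12, 12)) < 0.4)
            grid = make_grid(h)
            cfg = ViewshedConfig(radius_r_m=400)
            pts = rng.uniform(50, 1150, size=(3, 2))
            mine = compute_visual_exposure(grid, ObservationPointSet(pts, cfg), cfg)
            ref = exposure_oracle(grid, pts, 400.0, 1.6, 1.6)
            assert np.array_equal(mine.exposure.values, ref)

    def test_single_los_matches_oracle(self):
        rng = np.random.default_rng(9)
        cfg = ViewshedConfig(radius_r_m=600)
        for _ in range(200):
            h = rng.uniform(0, 10, size=(6, 6)) * (rng.random((6, 6)) < 0.5)
            grid = make_grid(h)
            a = rng.uniform(0, 600, size=2)
            b = rng.uniform(0, 600, size=2)
            if np.hypot(*(a - b)) > 600:
                continue
            assert line_of_sight(grid, tuple(a), tuple(b), cfg) == line_of_sight_oracle(
                grid, tuple(a), tuple(b), 1.6, 1.6
            )

    def test_visible_mask_monotone_in_radius(self):
        from urban330.rule3 import ObservationPointSet

        rng = np.random.default_rng(3)
        grid = make_grid(rng.uniform(0, 15, size=(10, 10)) * (rng.random((10, 10)) < 0.3))
        pts = rng.uniform(100, 900, size=(4, 2))
        small = compute_visual_exposure(
            grid, ObservationPointSet(pts, ViewshedConfig(radius_r_m=100)), ViewshedConfig(radius_r_m=100)
        )
        big = compute_visual_exposure(
            grid, ObservationPointSet(pts, ViewshedConfig(radius_r_m=250)), ViewshedConfig(radius_r_m=250)
        )
        assert not (small.visible_mask & ~big.visible_mask).any()


class TestCompliance:
    def _viewshed(self, visible):
        layer = make_grid(visible.astype(np.int64))
        from urban330.rule3 import ViewshedResult

        return ViewshedResult(exposure=layer, config=ViewshedConfig())

    @pytest.mark.parametrize(
        "visible,trees,expected",
        [(True, 5, True), (True, 2, False), (False, 10, False), (True, 3, True)],
    )
    def test_fusion_of_visibility_and_tree_count(self, visible, trees, expected):
        vis = np.zeros((3, 3), dtype=bool)
        vis[1, 1] = visible
        tc = np.zeros((3, 3), dtype=np.int64)
        tc[1, 1] = trees
        out = rule3_compliance(self._viewshed(vis), make_grid(tc, role="tree_count"), ViewshedConfig())
        assert bool(out.values[1, 1]) is expected

    def test_raising_tree_threshold_never_raises_share(self):
        rng = np.random.default_rng(0)
        vis = rng.random((6, 6)) < 0.7
        trees = rng.poisson(3, size=(6, 6)).astype(np.int64)
        pop = make_grid(rng.uniform(0, 50, size=(6, 6)), role="population")
        shares = []
        for thr in (1, 2, 3, 5, 8):
            cfg = ViewshedConfig(tree_threshold=thr)
            comp = rule3_compliance(self._viewshed(vis), make_grid(trees, role="tree_count"), cfg)
            shares.append(rule3_population_share(comp, pop, pop.values.sum()))
        assert all(a >= b for a, b in zip(shares, shares[1:]))

    def test_share_arithmetic(self):
        comp = make_grid(np.array([[1, 0], [1, 0]], dtype=bool))
        pop = make_grid(np.array([[100.0, 700.0], [150.0, 50.0]]), role="population")
        assert rule3_population_share(comp, pop, 1000.0) == pytest.approx(0.25)
        none = make_grid(np.zeros((2, 2), dtype=bool))
        assert rule3_population_share(none, pop, 1000.0) == 0.0
        with pytest.raises(ValueError, match="pop_city"):
            rule3_population_share(comp, pop, 0.0)
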