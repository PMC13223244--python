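"""Rule 3 — visibility of three trees, assessed by viewshed analysis.

Observation points are scattered over the city with a minimum Euclidean
spacing ``d`` (dart throwing). From each point, every cell center within
the analysis radius ``r`` is tested for line of sight against the
building-height obstacle layer: terrain is flat, the observer's eye sits
at ``observer_height_m`` above ground and the target at
``target_height_m``. A cell is visible when the straight sight line
stays strictly above the obstacle height over every cell it traverses
(the observer's and target's own cells are excluded, so a 100 m cell
cannot occlude a tree co-located with the viewpoint). Summing the
single-point viewsheds gives a visual-exposure count per cell; a cell
complies with Rule 3 when it is visible from at least one point *and*
contains at least ``tree_threshold`` trees. The population share is the
population in compliant cells over the city total.

The line-of-sight test is exact: the sight segment is cut at every grid
line it crosses, so each traversed cell contributes its exact parameter
interval, and an obstacle blocks when its height reaches the sight line
anywhere on that interval (ties block). This avoids the corner-clipping
misses of fixed-step sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

from .grid import GridLayer, require_aligned

__all__ = [
    "ViewshedConfig",
    "ObservationPointSet",
    "ViewshedResult",
    "sample_viewpoints",
    "line_of_sight",
    "compute_visual_exposure",
    "rule3_compliance",
    "rule3_population_share",
]


@dataclass(frozen=True)
class ViewshedConfig:
    """Parameters of the Rule-3 viewshed stage.

    ``min_spacing_d_m`` in {100, 250, 500} and ``radius_r_m`` in
    {100, 250} are the configurations explored in practice; any positive
    values are accepted. Heights are in meters above flat ground.
    """

    min_spacing_d_m: float = 100.0
    radius_r_m: float = 100.0
    observer_height_m: float = 1.6
    target_height_m: float = 1.6
    tree_threshold: int = 3
    seed: int = 0
    max_sample_attempts: int = 2000

    def __post_init__(self) -> None:
        if not self.min_spacing_d_m > 0:
            raise ValueError("min_spacing_d_m must be > 0")
        if not self.radius_r_m > 0:
            raise ValueError("radius_r_m must be > 0")
        if self.tree_threshold < 1:
            raise ValueError("tree_threshold must be >= 1")


@dataclass
class ObservationPointSet:
    """Accepted viewpoints: pairwise Euclidean distance >= min spacing."""

    points: np.ndarray  # (n, 2) x/y meters
    config: ViewshedConfig

    @property
    def count(self) -> int:
        return len(self.points)


@dataclass
class ViewshedResult:
    """Per-cell visual-exposure counts (viewpoints that see each cell)."""

    exposure: GridLayer
    config: ViewshedConfig

    @property
    def visible_mask(self) -> np.ndarray:
        return (self.exposure.values >= 1) & ~self.exposure.nodata_mask


def sample_viewpoints(boundary: BaseGeometry, config: ViewshedConfig) -> ObservationPointSet:
    """Dart-throwing point sampling with minimum spacing inside a boundary.

    Uniform candidates are drawn in the boundary's bounding box and
    accepted when inside the boundary and at least ``min_spacing_d_m``
    from every accepted point; sampling stops after
    ``max_sample_attempts`` consecutive rejections. Deterministic for a
    given seed.
    """
    if boundary.is_empty or boundary.area <= 0:
        raise ValueError("degenerate boundary: zero area")
    rng = np.random.default_rng(config.seed)
    d = config.min_spacing_d_m
    d2 = d * d
    xmin, ymin, xmax, ymax = boundary.bounds
    shapely.prepare(boundary)
    # spatial hash at cell size d: neighbors within d live in the 3x3 block
    buckets: dict[tuple[int, int], list[tuple[float, float]]] = {}
    accepted: list[tuple[float, float]] = []
    rejections = 0
    while rejections < config.max_sample_attempts:
        x = rng.uniform(xmin, xmax)
        y = rng.uniform(ymin, ymax)
        if not shapely.intersects_xy(boundary, x, y):
            rejections += 1
            continue
        bi, bj = int(x // d), int(y // d)
        ok = True
        for ii in (bi - 1, bi, bi + 1):
            for jj in (bj - 1, bj, bj + 1):
                for (px, py) in buckets.get((ii, jj), ()):
                    if (px - x) ** 2 + (py - y) ** 2 < d2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            accepted.append((x, y))
            buckets.setdefault((bi, bj), []).append((x, y))
            rejections = 0
        else:
            rejections += 1
    pts = np.array(accepted, dtype=float).reshape(-1, 2)
    return ObservationPointSet(points=pts, config=config)


def _traversal_intervals(grid: GridLayer, p0, p1, eps: float = 1e-12):
    """Exact (row, col, t0, t1) intervals of the segment p0->p1 on the grid.

    The segment is split at every crossing of a grid line; each piece is
    attributed to the cell containing its midpoint. Pieces shorter than
    ``eps`` in parameter length (edge/corner touches) are dropped.
    """
    (x0, y0), (x1, y1) = p0, p1
    s = grid.cell_size
    ts = [0.0, 1.0]
    dx, dy = x1 - x0, y1 - y0
    if dx != 0.0:
        c0 = (x0 - grid.origin_x) / s
        c1 = (x1 - grid.origin_x) / s
        for k in range(math.ceil(min(c0, c1)), math.floor(max(c0, c1)) + 1):
            t = (grid.origin_x + k * s - x0) / dx
            if 0.0 < t < 1.0:
                ts.append(t)
    if dy != 0.0:
        r0 = (grid.origin_y - y0) / s
        r1 = (grid.origin_y - y1) / s
        for k in range(math.ceil(min(r0, r1)), math.floor(max(r0, r1)) + 1):
            t = (grid.origin_y - k * s - y0) / dy
            if 0.0 < t < 1.0:
                ts.append(t)
    ts.sort()
    out = []
    for ta, tb in zip(ts[:-1], ts[1:]):
        if tb - ta <= eps:
            continue
        tm = 0.5 * (ta + tb)
        xm, ym = x0 + tm * dx, y0 + tm * dy
        row = int((grid.origin_y - ym) // s)
        col = int((xm - grid.origin_x) // s)
        out.append((row, col, ta, tb))
    return out


def line_of_sight(
    height_grid: GridLayer,
    obs: tuple[float, float],
    target: tuple[float, float],
    config: ViewshedConfig,
) -> bool:
    """True when the target point is visible from the observer.

    Both points must lie within the grid and within ``radius_r_m`` of
    each other. Visibility requires the obstacle height to stay strictly
    below the sight line over every traversed cell except the two
    endpoint cells (own-cell exclusion); a tie blocks.
    """
    if not (height_grid.contains_point(*obs) and height_grid.contains_point(*target)):
        raise ValueError("observer and target must lie within the height grid")
    dist = math.hypot(target[0] - obs[0], target[1] - obs[1])
    if dist > config.radius_r_m + 1e-9:
        raise ValueError("target beyond the viewshed radius")
    return _los_unchecked(height_grid, obs, target, config)


def _los_unchecked(height_grid, obs, target, config) -> bool:
    obs_cell = height_grid.point_to_rowcol(*obs)
    tgt_cell = height_grid.point_to_rowcol(*target)
    z0 = config.observer_height_m
    z1 = config.target_height_m
    H = height_grid.values
    mask = height_grid.nodata_mask
    nr, nc = H.shape
    for row, col, ta, tb in _traversal_intervals(height_grid, obs, target):
        if (row, col) == obs_cell or (row, col) == tgt_cell:
            continue
        if not (0 <= row < nr and 0 <= col < nc):
            continue
        if mask[row, col]:
            continue  # unknown height: treated as no obstacle
        h = H[row, col]
        # sight line is linear in t; visibility needs h < z(t) on [ta, tb]
        if h >= min(z0 + ta * (z1 - z0), z0 + tb * (z1 - z0)):
            return False
    return True


def compute_visual_exposure(
    height_grid: GridLayer,
    points: ObservationPointSet,
    config: ViewshedConfig,
) -> ViewshedResult:
    """Sum single-point viewsheds into a per-cell visual-exposure raster.

    For each observation point, every cell whose center lies within
    ``radius_r_m`` (closed disk) and passes the line-of-sight test is
    counted once; exposure is additive over points.
    """
    s = height_grid.cell_size
    r = config.radius_r_m
    exposure = np.zeros(height_grid.values.shape, dtype=np.int64)
    nr, nc = exposure.shape
    eye = min(config.observer_height_m, config.target_height_m)
    for (px, py) in points.points:
        if not height_grid.contains_point(px, py):
            raise ValueError("observation point outside the height grid")
        # candidate cells: centers within r of the point
        col_lo = max(0, int((px - r - height_grid.origin_x) // s))
        col_hi = min(nc - 1, int((px + r - height_grid.origin_x) // s))
        row_lo = max(0, int((height_grid.origin_y - (py + r)) // s))
        row_hi = min(nr - 1, int((height_grid.origin_y - (py - r)) // s))
        sub = np.s_[row_lo : row_hi + 1, col_lo : col_hi + 1]
        cols = np.arange(col_lo, col_hi + 1)
        rows = np.arange(row_lo, row_hi + 1)
        cx = height_grid.origin_x + (cols + 0.5) * s
        cy = height_grid.origin_y - (rows + 0.5) * s
        DX = cx[None, :] - px
        DY = cy[:, None] - py
        in_disk = DX**2 + DY**2 <= r * r
        if not in_disk.any():
            continue
        window = np.where(height_grid.nodata_mask[sub], 0.0, height_grid.values[sub])
        if window.max(initial=0.0) < eye:
            # no obstacle can reach the sight line anywhere in the window
            exposure[sub][in_disk] += 1
            continue
        rr, cc = np.nonzero(in_disk)
        for i, j in zip(rr, cc):
            tx = cx[j]
            ty = cy[i]
            if _los_unchecked(height_grid, (px, py), (tx, ty), config):
                exposure[rows[i], cols[j]] += 1
    layer = GridLayer(
        origin_x=height_grid.origin_x,
        origin_y=height_grid.origin_y,
        cell_size=s,
        values=exposure,
        nodata_mask=height_grid.nodata_mask.copy(),
        variable_role=None,
    )
    return ViewshedResult(exposure=layer, config=config)


def rule3_compliance(
    viewshed: ViewshedResult, tree_count: GridLayer, config: ViewshedConfig
) -> GridLayer:
    """Cell complies when visible from >= 1 point and trees >= threshold."""
    require_aligned(viewshed.exposure, tree_count)
    ok = viewshed.visible_mask & (tree_count.values >= config.tree_threshold)
    mask = viewshed.exposure.nodata_mask | tree_count.nodata_mask
    ok = ok & ~mask
    return tree_count.copy_with(values=ok, nodata_mask=mask, variable_role=None)


def rule3_population_share(
    compliance: GridLayer, population: GridLayer, pop_city: float
) -> float:
    """POP_R3: population in compliant cells over the city total."""
    return population_share(compliance, population, pop_city)


def population_share(compliance: GridLayer, population: GridLayer, pop_city: float) -> float:
    """Population-weighted share of compliant cells (shared by all rules)."""
    if not pop_city > 0:
        raise ValueError("pop_city must be > 0")
    require_aligned(compliance, population)
    ok = compliance.values.astype(bool) & ~compliance.nodata_mask & ~population.nodata_mask
    return float(population.values[ok].sum() / pop_city)
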