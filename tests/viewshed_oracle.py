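"""Independent brute-force viewshed oracle.

Line of sight is decided per (point, cell) pair by clipping the sight
segment against every grid cell with the Liang-Barsky slab method —
each cell's exact parameter interval on the segment — and blocking when
the obstacle height reaches the (linear) sight line anywhere on a
positive-length interval. This shares no code with the package's
grid-traversal implementation.
"""

from __future__ import annotations

import numpy as np


def _clip_to_cell(x0, y0, dx, dy, xa, xb, ya, yb):
    """Liang-Barsky parameter interval of the segment inside [xa,xb]x[ya,yb]."""
    t0, t1 = 0.0, 1.0
    for p, q in ((-dx, x0 - xa), (dx, xb - x0), (-dy, y0 - ya), (dy, yb - y0)):
        if p == 0.0:
            if q < 0.0:
                return None
        else:
            t = q / p
            if p < 0.0:
                t0 = max(t0, t)
            else:
                t1 = min(t1, t)
    if t1 - t0 <= 1e-12:
        return None
    return t0, t1


def line_of_sight_oracle(grid, obs, target, observer_h, target_h) -> bool:
    (x0, y0), (x1, y1) = obs, target
    dx, dy = x1 - x0, y1 - y0
    s = grid.cell_size
    obs_cell = grid.point_to_rowcol(x0, y0)
    tgt_cell = grid.point_to_rowcol(x1, y1)
    for row in range(grid.n_rows):
        for col in range(grid.n_cols):
            if (row, col) in (obs_cell, tgt_cell) or grid.nodata_mask[row, col]:
                continue
            xa = grid.origin_x + col * s
            yb = grid.origin_y - row * s
            interval = _clip_to_cell(x0, y0, dx, dy, xa, xa + s, yb - s, yb)
            if interval is None:
                continue
            t0, t1 = interval
            zmin = min(observer_h + t0 * (target_h - observer_h),
                       observer_h + t1 * (target_h - observer_h))
            if grid.values[row, col] >= zmin:
                return False
    return True


def exposure_oracle(grid, points, radius, observer_h, target_h) -> np.ndarray:
    """Per-cell exposure counts, fully vectorized over grid cells.

    For each (point, target-cell) pair the segment is clipped against
    every cell at once; a cell blocks when traversed with positive
    parameter length and its height reaches the sight-line minimum on
    the interval.
    """
    s = grid.cell_size
    nr, nc = grid.values.shape
    cols = np.arange(nc)
    rows = np.arange(nr)
    XA = grid.origin_x + cols[None, :] * s + np.zeros((nr, 1))
    XB = XA + s
    YB = grid.origin_y - rows[:, None] * s + np.zeros((1, nc))
    YA = YB - s
    CX = XA + s / 2.0
    CY = YA + s / 2.0
    H = np.where(grid.nodata_mask, -np.inf, grid.values.astype(float))
    exposure = np.zeros((nr, nc), dtype=np.int64)
    dz = target_h - observer_h
    for (px, py) in points:
        obs_cell = grid.point_to_rowcol(px, py)
        in_disk = (CX - px) ** 2 + (CY - py) ** 2 <= radius * radius
        for ti, tj in zip(*np.nonzero(in_disk)):
            tx, ty = CX[ti, tj], CY[ti, tj]
            dx, dy = tx - px, ty - py
            with np.errstate(divide="ignore", invalid="ignore"):
                if dx != 0.0:
                    t1x = (XA - px) / dx
                    t2x = (XB - px) / dx
                    tminx = np.minimum(t1x, t2x)
                    tmaxx = np.maximum(t1x, t2x)
                else:
                    inside = (XA <= px) & (px <= XB)
                    tminx = np.where(inside, -np.inf, np.inf)
                    tmaxx = np.where(inside, np.inf, -np.inf)
                if dy != 0.0:
                    t1y = (YA - py) / dy
                    t2y = (YB - py) / dy
                    tminy = np.minimum(t1y, t2y)
                    tmaxy = np.maximum(t1y, t2y)
                else:
                    inside = (YA <= py) & (py <= YB)
                    tminy = np.where(inside, -np.inf, np.inf)
                    tmaxy = np.where(inside, np.inf, -np.inf)
            t0 = np.maximum(0.0, np.maximum(tminx, tminy))
            t1 = np.minimum(1.0, np.minimum(tmaxx, tmaxy))
            traversed = (t1 - t0) > 1e-12
            traversed[obs_cell] = False
            traversed[ti, tj] = False
            zmin = observer_h + np.minimum(t0 * dz, t1 * dz)
            blocked = traversed & (H >= zmin)
            if not blocked.any():
                exposure[ti, tj] += 1
    return exposure
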