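"""Rule 30 — neighborhood tree-canopy cover.

Neighborhoods are square blocks (default 1 km x 1 km) anchored at the
raster origin. Each block's canopy value is the arithmetic mean of the
100 m tree-cover-density cells whose centers fall inside the city
boundary; a block complies when that mean reaches the threshold
(default 30%, inclusive). Edge blocks are evaluated on their
inside-boundary cells rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

from .grid import GridLayer
from .rule3 import population_share

__all__ = [
    "Rule30Config",
    "aggregate_neighborhood_canopy",
    "rule30_compliance",
    "rule30_population_share",
]


@dataclass(frozen=True)
class Rule30Config:
    block_size_m: float = 1000.0
    canopy_threshold_pct: float = 30.0

    def __post_init__(self) -> None:
        if not 0 <= self.canopy_threshold_pct <= 100:
            raise ValueError("canopy_threshold_pct must be in [0, 100]")
        if not self.block_size_m > 0:
            raise ValueError("block_size_m must be > 0")


def _block_indices(tcd: GridLayer, config: Rule30Config):
    """Block (row, col) index of every cell, assigned by cell center.

    Blocks are anchored at the raster origin. Center assignment keeps
    block sizes that are not whole cell multiples (e.g. 250 m blocks on
    a 100 m grid) well defined: each cell belongs to the block holding
    its center.
    """
    if config.block_size_m + 1e-9 < tcd.cell_size:
        raise ValueError(
            "block_size_m must be at least the cell size (blocks are "
            "aggregates of whole cells, assigned by center)"
        )
    s, b = tcd.cell_size, config.block_size_m
    brow = (((np.arange(tcd.n_rows) + 0.5) * s) // b).astype(int)
    bcol = (((np.arange(tcd.n_cols) + 0.5) * s) // b).astype(int)
    return brow, bcol


def aggregate_neighborhood_canopy(
    tcd: GridLayer, config: Rule30Config, boundary: BaseGeometry
) -> GridLayer:
    """Mean tree-cover density per neighborhood block, % in [0, 100].

    Blocks are anchored at the raster origin; a block's mean runs over
    its non-nodata cells with centers inside the boundary, and blocks
    with no such cells are nodata.
    """
    brow, bcol = _block_indices(tcd, config)
    nbr, nbc = brow[-1] + 1, bcol[-1] + 1
    X, Y = tcd.cell_centers()
    inside = shapely.intersects_xy(boundary, X.ravel(), Y.ravel()).reshape(X.shape)
    valid = inside & ~tcd.nodata_mask
    ids = (brow[:, None] * nbc + bcol[None, :]).ravel()
    tot = np.bincount(ids, weights=np.where(valid, tcd.values, 0.0).ravel(), minlength=nbr * nbc)
    n = np.bincount(ids, weights=valid.ravel().astype(float), minlength=nbr * nbc)
    mean = np.where(n > 0, tot / np.maximum(n, 1), 0.0).reshape(nbr, nbc)
    return GridLayer(
        origin_x=tcd.origin_x,
        origin_y=tcd.origin_y,
        cell_size=config.block_size_m,
        values=mean,
        nodata_mask=(n == 0).reshape(nbr, nbc),
        variable_role="tree_cover_density_pct",
    )


def rule30_compliance(
    block_canopy: GridLayer, config: Rule30Config, template: GridLayer
) -> GridLayer:
    """Broadcast block compliance (canopy >= threshold) back to the cells."""
    brow, bcol = _block_indices(template, config)
    block_ok = (block_canopy.values >= config.canopy_threshold_pct) & ~block_canopy.nodata_mask
    fine = block_ok[np.ix_(brow, bcol)]
    finemask = block_canopy.nodata_mask[np.ix_(brow, bcol)]
    return template.copy_with(
        values=fine.copy(), nodata_mask=finemask.copy(), variable_role=None
    )


def rule30_population_share(
    compliance: GridLayer, population: GridLayer, pop_city: float
) -> float:
    """POP_R30: population in >=30%-canopy neighborhoods over the city total."""
    return population_share(compliance, population, pop_city)
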