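"""Synthetic city generator.

Produces :class:`~urban330.grid.CityBundle`\\ s whose layers mimic the
statistical structure of the real inputs — spatially autocorrelated
building heights and canopy, Poisson tree counts tied to canopy,
census-style population disaggregated onto built cells, polygonal parks
in a 50 m land-use raster, and a coarser income grid rank-coupled to
local greenness — so every downstream stage can be tested against
known, planted structure without any data download.

Two entry points:

* :func:`generate_city` — a statistically realistic random city.
* :func:`generate_city_with_planted_compliance` — a block-engineered
  city whose per-rule compliant population fractions are known exactly
  by construction, returned together with the analytically expected
  assessment (the recovery oracle for the population-share equations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from shapely.geometry import box

from .assessment import CityAssessment
from .grid import CityBundle, GridLayer
from .rule300 import DEFAULT_GREEN_CLASSES, GREEN_URBAN_AREAS, URBAN_FABRIC

__all__ = [
    "SyntheticCitySpec",
    "generate_city",
    "generate_city_with_planted_compliance",
    "local_greenness",
]


@dataclass(frozen=True)
class SyntheticCitySpec:
    """Knobs of the random-city generator (defaults: mid-size European core).

    The 100 m grid spans ``n_rows x n_cols`` cells. ``building_density``
    is the fraction of built cells; heights are log-normal with the
    given mean/sd (m). ``tree_intensity`` is the mean tree count per
    cell and ``canopy_autocorr_range_m`` the spatial correlation length
    of the canopy field. Parks are axis-aligned rectangles
    ``((cx, cy), width_m, height_m)``. ``income_greenness_rho`` is the
    target Spearman correlation between income-cell greenness and
    income, implemented by a Gaussian-copula rank coupling.
    """

    n_rows: int = 60
    n_cols: int = 60
    seed: int = 0
    cell_size_m: float = 100.0
    building_density: float = 0.35
    height_mean_m: float = 12.0
    height_sd_m: float = 6.0
    tree_intensity: float = 2.0
    canopy_autocorr_range_m: float = 800.0
    canopy_mean_pct: float = 25.0
    canopy_sd_pct: float = 15.0
    park_specs: tuple = ()
    pop_total: int = 100_000
    income_greenness_rho: float = 0.0
    income_cell_size_m: float = 200.0

    def __post_init__(self) -> None:
        if not (0 <= self.building_density <= 1):
            raise ValueError("building_density must be in [0, 1]")
        if not (-1 <= self.income_greenness_rho <= 1):
            raise ValueError("income_greenness_rho must be in [-1, 1]")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid shape must be positive")


def default_park_specs(spec: SyntheticCitySpec) -> tuple:
    """Two rectangular parks placed well inside the domain."""
    w = spec.n_cols * spec.cell_size_m
    h = spec.n_rows * spec.cell_size_m
    return (
        ((0.25 * w, 0.70 * h), min(600.0, 0.2 * w), min(400.0, 0.2 * h)),
        ((0.70 * w, 0.30 * h), min(500.0, 0.2 * w), min(500.0, 0.2 * h)),
    )


def _smooth_standard_field(rng, shape, sigma_cells) -> np.ndarray:
    """Gaussian random field, zero mean unit variance, given smoothing."""
    z = rng.standard_normal(shape)
    if sigma_cells > 0:
        z = ndimage.gaussian_filter(z, sigma=sigma_cells, mode="reflect")
    sd = z.std()
    return z / sd if sd > 0 else z


def generate_city(spec: SyntheticCitySpec) -> CityBundle:
    """Generate one random city bundle; bit-identical for a given seed."""
    rng = np.random.default_rng(spec.seed)
    nr, nc, s = spec.n_rows, spec.n_cols, spec.cell_size_m
    origin_y = nr * s
    boundary = box(0.0, 0.0, nc * s, origin_y)
    nodata = np.zeros((nr, nc), dtype=bool)

    def layer(values, role):
        return GridLayer(0.0, origin_y, s, values, nodata.copy(), role)

    # built mask: smoothed field thresholded at the density quantile
    built_field = _smooth_standard_field(rng, (nr, nc), sigma_cells=2.0)
    if spec.building_density >= 1.0:
        built = np.ones((nr, nc), dtype=bool)
    elif spec.building_density <= 0.0:
        built = np.zeros((nr, nc), dtype=bool)
    else:
        thr = np.quantile(built_field, 1.0 - spec.building_density)
        built = built_field > thr
    if not built.any():
        built[nr // 2, nc // 2] = True

    # heights: log-normal (method of moments) on built cells
    cv2 = (spec.height_sd_m / spec.height_mean_m) ** 2 if spec.height_mean_m > 0 else 0.0
    sig = math.sqrt(math.log1p(cv2))
    mu = math.log(spec.height_mean_m) - 0.5 * sig**2 if spec.height_mean_m > 0 else 0.0
    heights = np.zeros((nr, nc))
    heights[built] = rng.lognormal(mean=mu, sigma=sig, size=int(built.sum()))

    # canopy: smoothed field mapped to a [0, 100] density
    sigma_cells = spec.canopy_autocorr_range_m / s
    g = _smooth_standard_field(rng, (nr, nc), sigma_cells)
    tcd = np.clip(spec.canopy_mean_pct + spec.canopy_sd_pct * g, 0.0, 100.0)

    # trees: Poisson counts with intensity proportional to canopy
    if spec.tree_intensity > 0 and tcd.mean() > 0:
        lam = spec.tree_intensity * tcd / tcd.mean()
    else:
        lam = np.full((nr, nc), spec.tree_intensity)
    trees = rng.poisson(lam).astype(np.int64)

    # population: multinomial split of the total over built cells,
    # weighted by building height (built volume proxy)
    w = np.where(built, np.maximum(heights, 3.0), 0.0).ravel()
    p = w / w.sum()
    pop = rng.multinomial(spec.pop_total, p).reshape(nr, nc).astype(np.int64)

    # land use at 50 m: urban fabric everywhere, green class in parks
    lu = np.full((2 * nr, 2 * nc), URBAN_FABRIC, dtype=np.int64)
    park_specs = spec.park_specs or default_park_specs(spec)
    half = s / 2.0
    xs = (np.arange(2 * nc) + 0.5) * half
    ys = origin_y - (np.arange(2 * nr) + 0.5) * half
    for (cx, cy), pw, ph in park_specs:
        x0, x1 = cx - pw / 2.0, cx + pw / 2.0
        y0, y1 = cy - ph / 2.0, cy + ph / 2.0
        if x0 < 0 or y0 < 0 or x1 > nc * s or y1 > origin_y:
            raise ValueError("park rectangle exceeds the city domain")
        in_x = (xs >= x0) & (xs <= x1)
        in_y = (ys >= y0) & (ys <= y1)
        lu[np.ix_(in_y, in_x)] = GREEN_URBAN_AREAS
    landuse = GridLayer(0.0, origin_y, half, lu, np.zeros_like(lu, dtype=bool), "landuse_class")

    greenness = _greenness_index(tcd, lu, s, spec.income_cell_size_m)
    income_layer = _income_grid(spec, rng, greenness, origin_y)

    layers = {
        "building_height_m": layer(heights, "building_height_m"),
        "tree_count": layer(trees, "tree_count"),
        "tree_cover_density_pct": layer(tcd, "tree_cover_density_pct"),
        "population": layer(pop, "population"),
        "landuse_class": landuse,
        "income": income_layer,
    }
    return CityBundle(city_id=f"synthetic-{spec.seed}", boundary=boundary, layers=layers)


def _block_mean(arr: np.ndarray, f: int) -> np.ndarray:
    nr, nc = arr.shape
    nir, nic = -(-nr // f), -(-nc // f)
    padded = np.zeros((nir * f, nic * f))
    padded[:nr, :nc] = arr
    cnt = np.zeros((nir * f, nic * f))
    cnt[:nr, :nc] = 1.0
    tot = padded.reshape(nir, f, nic, f).sum(axis=(1, 3))
    n = cnt.reshape(nir, f, nic, f).sum(axis=(1, 3))
    return tot / np.maximum(n, 1)


def _greenness_index(
    tcd: np.ndarray, landuse_50m: np.ndarray, cell_size_m: float, income_cell_size_m: float
) -> np.ndarray:
    """Local greenness per income cell: canopy plus park proximity.

    Standardized mean canopy minus standardized distance to the nearest
    green land-use cell, averaged over each income cell. Including park
    proximity mirrors real cities, where access to green space and
    vegetated surroundings co-vary; with no parks the index reduces to
    canopy alone.
    """
    f = round(income_cell_size_m / cell_size_m)
    canopy = _block_mean(tcd, f)
    green50 = np.isin(landuse_50m, list(DEFAULT_GREEN_CLASSES))
    parts = [_standardize(canopy)]
    if green50.any() and not green50.all():
        dist50 = ndimage.distance_transform_edt(~green50, sampling=cell_size_m / 2.0)
        dist = _block_mean(_block_mean(dist50, 2), f)
        parts.append(-_standardize(dist))
    return sum(parts)


def _standardize(a: np.ndarray) -> np.ndarray:
    sd = a.std()
    return (a - a.mean()) / sd if sd > 0 else np.zeros_like(a)


def local_greenness(bundle: CityBundle) -> np.ndarray:
    """The greenness index income is coupled to, recomputed from a bundle.

    Returns one value per income-grid cell (canopy + park-proximity
    composite); useful for checking the planted income-greenness rank
    correlation on generated cities.
    """
    tcd = bundle.layer("tree_cover_density_pct")
    lu = bundle.layer("landuse_class")
    inc = bundle.layer("income")
    return _greenness_index(tcd.values, lu.values, tcd.cell_size, inc.cell_size)


def _income_grid(spec: SyntheticCitySpec, rng, greenness: np.ndarray, origin_y: float) -> GridLayer:
    """Income raster rank-coupled to income-cell greenness.

    Incomes are log-normal with normal scores built by a Gaussian
    copula at the Pearson coefficient matching the target Spearman rho
    (``rho_p = 2 sin(pi rho_s / 6)``).
    """
    nir, nic = greenness.shape
    flat = greenness.ravel()
    ranks = stats.rankdata(flat, method="average")
    z_green = stats.norm.ppf((ranks - 0.5) / flat.size)
    rho_p = 2.0 * math.sin(math.pi * spec.income_greenness_rho / 6.0)
    eps = rng.standard_normal(flat.size)
    z_inc = rho_p * z_green + math.sqrt(max(0.0, 1.0 - rho_p**2)) * eps
    income = 20_000.0 * np.exp(0.4 * z_inc)  # median ~20k, log-normal
    vals = income.reshape(nir, nic)
    return GridLayer(
        0.0,
        origin_y,
        spec.income_cell_size_m,
        vals,
        np.zeros_like(vals, dtype=bool),
        "income",
    )


# ---------------------------------------------------------------------------
# planted-compliance construction
# ---------------------------------------------------------------------------

_BLOCK_CELLS = 10  # planted neighborhoods are 1 km = 10 cells


def generate_city_with_planted_compliance(
    shape: tuple[int, int],
    seed: int,
    target_shares: tuple[float, float, float],
    pop_per_cell: float = 10.0,
) -> tuple[CityBundle, CityAssessment]:
    """City engineered so each rule's compliant population share is known.

    Population is uniform over all cells and buildings are absent, so:

    * Rule 3 — exactly ``round(t3 * n_cells)`` cells (row-major from the
      top-left) carry 5 trees, the rest none; with no obstacles every
      cell is visible, so the compliant set is the tree set.
    * Rule 30 — canopy is constant 40% on ``round(t30 * n_blocks)``
      whole 1 km blocks and 10% elsewhere, so block means are exact.
    * Rule 300 — a full-height park strip on the left occupies
      ``k - 3`` columns when ``k = round(t300 * n_cols)`` columns should
      comply: the 300 m buffer reaches exactly 3 further 100 m cell
      centers east of the park edge.

    Returns the bundle and the assessment expected analytically from the
    constructed masks (achieved fractions, not the raw targets — block
    and column granularity quantizes them).

    Requires ``shape`` to be a multiple of 10 in both dimensions and a
    grid large enough for the requested park (n_cols >= 8).
    """
    nr, nc = shape
    t3, t30, t300 = target_shares
    for t in (t3, t30, t300):
        if not 0 <= t <= 1:
            raise ValueError("target shares must lie in [0, 1]")
    if nr % _BLOCK_CELLS or nc % _BLOCK_CELLS:
        raise ValueError("planted city shape must be a multiple of 10 cells")
    if nc < 8:
        raise ValueError("grid too small to plant a park and its buffer")
    s = 100.0
    origin_y = nr * s
    boundary = box(0.0, 0.0, nc * s, origin_y)
    nodata = np.zeros((nr, nc), dtype=bool)
    n_cells = nr * nc

    # Rule 3: first k3 cells in row-major order hold 5 trees
    k3 = round(t3 * n_cells)
    m3 = np.zeros(n_cells, dtype=bool)
    m3[:k3] = True
    m3 = m3.reshape(nr, nc)
    trees = np.where(m3, 5, 0).astype(np.int64)

    # Rule 30: whole 1 km blocks at 40% canopy, rest at 10%
    nbr, nbc = nr // _BLOCK_CELLS, nc // _BLOCK_CELLS
    n_blocks = nbr * nbc
    kb = round(t30 * n_blocks)
    mblock = np.zeros(n_blocks, dtype=bool)
    mblock[:kb] = True
    mblock = mblock.reshape(nbr, nbc)
    m30 = np.repeat(np.repeat(mblock, _BLOCK_CELLS, axis=0), _BLOCK_CELLS, axis=1)
    tcd = np.where(m30, 40.0, 10.0)

    # Rule 300: park strip of p columns; compliant columns = p + 3
    k300 = round(t300 * nc)
    if k300 <= 0:
        pcols = 0
    else:
        pcols = max(1, min(k300 - 3, nc))
    m300 = np.zeros((nr, nc), dtype=bool)
    if pcols > 0:
        m300[:, : min(pcols + 3, nc)] = True
    lu = np.full((2 * nr, 2 * nc), URBAN_FABRIC, dtype=np.int64)
    if pcols > 0:
        lu[:, : 2 * pcols] = GREEN_URBAN_AREAS
    landuse = GridLayer(0.0, origin_y, s / 2, lu, np.zeros_like(lu, dtype=bool), "landuse_class")

    heights = np.zeros((nr, nc))
    pop = np.full((nr, nc), float(pop_per_cell))
    rng = np.random.default_rng(seed)
    income = 20_000.0 * np.exp(0.2 * rng.standard_normal((nr // 2, nc // 2)))

    def layer(values, role, cell=s, oy=origin_y):
        return GridLayer(0.0, oy, cell, values, np.zeros(values.shape, dtype=bool), role)

    bundle = CityBundle(
        city_id=f"planted-{seed}",
        boundary=boundary,
        layers={
            "building_height_m": GridLayer(0.0, origin_y, s, heights, nodata.copy(), "building_height_m"),
            "tree_count": layer(trees, "tree_count"),
            "tree_cover_density_pct": layer(tcd, "tree_cover_density_pct"),
            "population": layer(pop, "population"),
            "landuse_class": landuse,
            "income": GridLayer(0.0, origin_y, 200.0, income, np.zeros(income.shape, dtype=bool), "income"),
        },
    )

    score = m3.astype(int) + m30.astype(int) + m300.astype(int)
    shares = tuple(float((score == k).mean()) for k in range(4))
    expected = CityAssessment(
        pop_r3=float(m3.mean()),
        pop_r30=float(m30.mean()),
        pop_r300=float(m300.mean()),
        share_by_score=shares,
        config={"city_id": bundle.city_id, "planted_targets": [t3, t30, t300], "seed": seed},
    )
    return bundle, expected
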