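"""Gridded city data model and raster/vector I/O.

All layers live on axis-aligned grids in a projected, meter-based
coordinate system. Cell (row, col) covers the half-open square
``[x0 + col*s, x0 + (col+1)*s) x (y0 - (row+1)*s, y0 - row*s]`` where
``(x0, y0)`` is the top-left corner of the raster and ``s`` the cell
size; row 0 is the top row (north-up convention). A cell's location is
its center.

Rasters are stored as single-band ESRI ASCII grids (``.asc``), a plain
text format; vector geometries (city boundaries, green-space polygons)
as GeoJSON. No CRS metadata is carried: grids are assumed projected in
meters, and degree-scale grids are rejected heuristically on read.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import box, mapping, shape as shapely_shape
from shapely.geometry.base import BaseGeometry

VARIABLE_ROLES = frozenset(
    {
        "building_height_m",
        "tree_count",
        "tree_cover_density_pct",
        "population",
        "landuse_class",
        "income",
        "score",
    }
)

#: minimum plausible cell size (m); smaller values indicate degree units
_MIN_PROJECTED_CELL_M = 0.5


@dataclass
class GridLayer:
    """One georeferenced single-variable raster."""

    origin_x: float
    origin_y: float  # y of the TOP edge
    cell_size: float
    values: np.ndarray
    nodata_mask: np.ndarray
    variable_role: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("GridLayer values must be 2-D")
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("nodata_mask shape must match values shape")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")
        if self.variable_role is not None and self.variable_role not in VARIABLE_ROLES:
            raise ValueError(f"unknown variable_role {self.variable_role!r}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint."""
        s = self.cell_size
        return (
            self.origin_x,
            self.origin_y - self.n_rows * s,
            self.origin_x + self.n_cols * s,
            self.origin_y,
        )

    def footprint(self) -> BaseGeometry:
        return box(*self.bounds)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (X, Y) of cell-center coordinates, shape (n_rows, n_cols)."""
        s = self.cell_size
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * s
        ys = self.origin_y - (np.arange(self.n_rows) + 0.5) * s
        return np.meshgrid(xs, ys)

    def point_to_rowcol(self, x: float, y: float) -> tuple[int, int]:
        """Cell containing (x, y) under the half-open footprint convention."""
        s = self.cell_size
        col = math.floor((x - self.origin_x) / s)
        row = math.floor((self.origin_y - y) / s)
        return row, col

    def contains_point(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.bounds
        return xmin <= x <= xmax and ymin <= y <= ymax

    def aligned_with(self, other: "GridLayer", tol: float = 1e-6) -> bool:
        return (
            abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
            and self.values.shape == other.values.shape
        )

    def copy_with(self, **kwargs) -> "GridLayer":
        return replace(self, **kwargs)


def require_aligned(*layers: GridLayer) -> None:
    first = layers[0]
    for other in layers[1:]:
        if not first.aligned_with(other):
            raise ValueError(
                "grids are misaligned: all cross-layer operations require a "
                "shared origin, cell size and shape"
            )


# ---------------------------------------------------------------------------
# raster I/O (ESRI ASCII grid)
# ---------------------------------------------------------------------------

_DEFAULT_NODATA = -9999.0


def read_raster(path: str | Path, variable_role: str | None = None) -> GridLayer:
    """Read a single-band ESRI ASCII grid into a :class:`GridLayer`.

    The grid must be in a projected meter-based system; degree-scale
    grids (cell size below ~0.5) are rejected. Integer-valued bands
    (no decimal point in the data block) are read as integers.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    header: dict[str, float] = {}
    data_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            data_start = i + 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ASCII-grid header field {key!r}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    cellsize = header["cellsize"]
    if cellsize < _MIN_PROJECTED_CELL_M:
        raise ValueError(
            f"{path}: cell size {cellsize} looks like geographic (degree) "
            "units; only projected meter-based grids are supported"
        )
    nodata = header.get("nodata_value", _DEFAULT_NODATA)
    data_block = "\n".join(lines[data_start:])
    tokens = data_block.split()
    if len(tokens) != nrows * ncols:
        raise ValueError(
            f"{path}: expected one band of {nrows * ncols} values, got "
            f"{len(tokens)} (multi-band or truncated files are not supported)"
        )
    is_int = not any(("." in t) or ("e" in t) or ("E" in t) for t in tokens)
    dtype = np.int64 if is_int else np.float64
    values = np.array(tokens, dtype=dtype).reshape(nrows, ncols)
    mask = values == (int(nodata) if is_int else nodata)
    return GridLayer(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + nrows * cellsize,
        cell_size=cellsize,
        values=values,
        nodata_mask=mask,
        variable_role=variable_role,
    )


def write_raster(layer: GridLayer, path: str | Path) -> None:
    """Write a layer as an ESRI ASCII grid; round-trips bit-exactly."""
    path = Path(path)
    is_int = np.issubdtype(layer.values.dtype, np.integer)
    nodata = int(_DEFAULT_NODATA) if is_int else _DEFAULT_NODATA
    vals = layer.values.copy()
    vals[layer.nodata_mask] = nodata
    with path.open("w") as fh:
        fh.write(f"ncols {layer.n_cols}\n")
        fh.write(f"nrows {layer.n_rows}\n")
        fh.write(f"xllcorner {layer.origin_x!r}\n")
        fh.write(f"yllcorner {layer.origin_y - layer.n_rows * layer.cell_size!r}\n")
        fh.write(f"cellsize {layer.cell_size!r}\n")
        fh.write(f"nodata_value {nodata}\n")
        if is_int:
            for row in vals:
                fh.write(" ".join("%d" % v for v in row))
                fh.write("\n")
        else:
            # repr round-trips float64 exactly
            for row in vals:
                fh.write(" ".join(repr(float(v)) for v in row))
                fh.write("\n")


# ---------------------------------------------------------------------------
# resampling between nested grids
# ---------------------------------------------------------------------------


def resample_to(layer: GridLayer, template: GridLayer, method: str) -> GridLayer:
    """Resample ``layer`` onto ``template``'s grid.

    Only nested grids (shared origin, integer cell-size ratio) are
    supported; there is no general reprojection. ``method`` is one of
    ``nearest`` (categorical), ``area_weighted_mean`` (densities) or
    ``sum`` (counts — conserves the global total).
    """
    if method not in {"nearest", "area_weighted_mean", "sum"}:
        raise ValueError(f"unknown resampling method {method!r}")
    if (
        abs(layer.origin_x - template.origin_x) > 1e-6
        or abs(layer.origin_y - template.origin_y) > 1e-6
    ):
        raise ValueError("non-nested grids: origins differ (no reprojection in scope)")
    ratio = template.cell_size / layer.cell_size
    if ratio >= 1:
        f = round(ratio)
        if abs(ratio - f) > 1e-9:
            raise ValueError("non-nested grids: cell sizes are not integer multiples")
        return _downsample(layer, template, f, method)
    f = round(1 / ratio)
    if abs(1 / ratio - f) > 1e-9:
        raise ValueError("non-nested grids: cell sizes are not integer multiples")
    return _upsample(layer, template, f, method)


def _downsample(layer: GridLayer, template: GridLayer, f: int, method: str) -> GridLayer:
    nr, nc = template.n_rows, template.n_cols
    if nr * f < layer.n_rows or nc * f < layer.n_cols:
        raise ValueError("template extent does not cover the source layer")
    vals = np.full((nr * f, nc * f), np.nan)
    valid = np.zeros((nr * f, nc * f), dtype=bool)
    vals[: layer.n_rows, : layer.n_cols] = np.where(layer.nodata_mask, np.nan, layer.values)
    valid[: layer.n_rows, : layer.n_cols] = ~layer.nodata_mask
    blocks = vals.reshape(nr, f, nc, f)
    vblocks = valid.reshape(nr, f, nc, f)
    n_valid = vblocks.sum(axis=(1, 3))
    if method == "nearest":
        # value of the fine cell containing the coarse-cell center
        out = blocks[:, f // 2, :, f // 2]
        mask = ~vblocks[:, f // 2, :, f // 2]
        out = np.where(mask, 0, out)
        out = out.astype(layer.values.dtype)
    elif method == "area_weighted_mean":
        with np.errstate(invalid="ignore"):
            out = np.nansum(np.where(vblocks, blocks, 0.0), axis=(1, 3))
            out = np.where(n_valid > 0, out / np.maximum(n_valid, 1), 0.0)
        mask = n_valid == 0
    else:  # sum
        out = np.nansum(np.where(vblocks, blocks, 0.0), axis=(1, 3))
        mask = n_valid == 0
        if np.issubdtype(layer.values.dtype, np.integer):
            out = out.astype(layer.values.dtype)
    return GridLayer(
        origin_x=template.origin_x,
        origin_y=template.origin_y,
        cell_size=template.cell_size,
        values=out,
        nodata_mask=mask,
        variable_role=layer.variable_role,
    )


def _upsample(layer: GridLayer, template: GridLayer, f: int, method: str) -> GridLayer:
    nr, nc = template.n_rows, template.n_cols
    big = np.repeat(np.repeat(layer.values, f, axis=0), f, axis=1)
    bigmask = np.repeat(np.repeat(layer.nodata_mask, f, axis=0), f, axis=1)
    if big.shape[0] < nr or big.shape[1] < nc:
        raise ValueError("source layer does not cover the template extent")
    out = big[:nr, :nc]
    mask = bigmask[:nr, :nc]
    if method == "sum":
        out = out / (f * f)  # conserve totals: split each coarse count evenly
    return GridLayer(
        origin_x=template.origin_x,
        origin_y=template.origin_y,
        cell_size=template.cell_size,
        values=out.copy(),
        nodata_mask=mask.copy(),
        variable_role=layer.variable_role,
    )


# ---------------------------------------------------------------------------
# polygonization
# ---------------------------------------------------------------------------

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class RasterPatch:
    """A connected same-class patch of cells as a polygon."""

    geometry: BaseGeometry
    area_m2: float
    value: float


def polygonize(layer: GridLayer, keep_values: set) -> list[RasterPatch]:
    """Vectorize edge-connected (4-connectivity) patches of the given classes.

    Returns disjoint polygons; areas sum exactly to kept-cell-count x s^2.
    """
    patches: list[RasterPatch] = []
    s = layer.cell_size
    for value in sorted(keep_values):
        mask = (layer.values == value) & ~layer.nodata_mask
        if not mask.any():
            continue
        labels, n = ndimage.label(mask, structure=_FOUR_CONN)
        objects = ndimage.find_objects(labels)
        for lab in range(1, n + 1):
            sl = objects[lab - 1]
            rows, cols = np.nonzero(labels[sl] == lab)
            rows = rows + sl[0].start
            cols = cols + sl[1].start
            cells = [
                box(
                    layer.origin_x + c * s,
                    layer.origin_y - (r + 1) * s,
                    layer.origin_x + (c + 1) * s,
                    layer.origin_y - r * s,
                )
                for r, c in zip(rows, cols)
            ]
            geom = shapely.unary_union(cells)
            patches.append(RasterPatch(geometry=geom, area_m2=len(cells) * s * s, value=value))
    return patches


# ---------------------------------------------------------------------------
# vector I/O (GeoJSON)
# ---------------------------------------------------------------------------


def read_geojson(path: str | Path) -> BaseGeometry:
    """Read the first geometry from a GeoJSON file."""
    obj = json.loads(Path(path).read_text())
    if obj.get("type") == "FeatureCollection":
        obj = obj["features"][0]
    if obj.get("type") == "Feature":
        obj = obj["geometry"]
    return shapely_shape(obj)


def write_geojson(geoms, path: str | Path, properties=None) -> None:
    """Write one geometry or a list of (geometry, properties) as GeoJSON."""
    if isinstance(geoms, BaseGeometry):
        geoms = [geoms]
    features = []
    for i, g in enumerate(geoms):
        props = dict(properties[i]) if properties else {}
        features.append({"type": "Feature", "geometry": mapping(g), "properties": props})
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


# ---------------------------------------------------------------------------
# CityBundle
# ---------------------------------------------------------------------------


@dataclass
class CityBundle:
    """Aligned layer set + boundary polygon for one city (the unit of analysis).

    All 100 m layers share one grid; the land-use layer is at 50 m on the
    same origin. ``pop_city`` is the population summed over cells whose
    centers fall inside the boundary.
    """

    city_id: str
    boundary: BaseGeometry
    layers: dict[str, GridLayer] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # land use (50 m) and income (200 m / 1 km) live on their own grids
        fine = [
            l for r, l in self.layers.items() if r not in ("landuse_class", "income")
        ]
        if fine:
            require_aligned(*fine)

    def layer(self, role: str) -> GridLayer:
        try:
            return self.layers[role]
        except KeyError:
            raise KeyError(f"bundle {self.city_id!r} has no {role!r} layer") from None

    @property
    def pop_city(self) -> float:
        pop = self.layer("population")
        X, Y = pop.cell_centers()
        inside = shapely.intersects_xy(self.boundary, X.ravel(), Y.ravel()).reshape(X.shape)
        vals = np.where(pop.nodata_mask, 0.0, pop.values)
        return float(vals[inside].sum())


_LAYER_FILES = {
    "building_height_m": "building_height.asc",
    "tree_count": "tree_count.asc",
    "tree_cover_density_pct": "tree_cover_density.asc",
    "population": "population.asc",
    "landuse_class": "landuse.asc",
    "income": "income.asc",
    "score": "score.asc",
}


def write_city_bundle(bundle: CityBundle, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for role, layer in bundle.layers.items():
        write_raster(layer, directory / _LAYER_FILES[role])
    write_geojson(bundle.boundary, directory / "boundary.geojson")
    (directory / "city.json").write_text(
        json.dumps({"city_id": bundle.city_id, "pop_city": bundle.pop_city})
    )


def read_city_bundle(directory: str | Path) -> CityBundle:
    directory = Path(directory)
    meta = json.loads((directory / "city.json").read_text())
    layers = {}
    for role, fname in _LAYER_FILES.items():
        p = directory / fname
        if p.exists():
            layers[role] = read_raster(p, variable_role=role)
    boundary = read_geojson(directory / "boundary.geojson")
    return CityBundle(city_id=meta["city_id"], boundary=boundary, layers=layers)
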