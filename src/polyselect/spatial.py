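"""Equal-area gridding of species ranges and range-based climate extraction.

All spatial aggregation runs on a Behrmann grid: a cylindrical equal-area
projection with standard parallel 30 degrees, so every cell covers the same
area regardless of latitude.  Forward and inverse mappings are closed form:

    x = R * lon_rad * cos(30 deg)
    y = R * sin(lat_rad) / cos(30 deg)

The workflow uses two resolutions: a fine grid (occupancy and climate; the
study convention is 5 km) and a coarse analysis grid (default 200 km) whose
species list is the union over its nested fine cells.  Cell membership uses
half-open intervals [min, max) in projected space so no point is counted
twice, and cell ids are row-major and reproducible from (resolution,
origin), with the origin anchored at projected (0, 0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Set

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box
from shapely.ops import transform as shapely_transform

logger = logging.getLogger(__name__)

__all__ = [
    "BehrmannGrid",
    "Raster",
    "rasterize_range",
    "occupancy_from_bands",
    "coarsen_occupancy",
    "cell_means",
    "range_mean_raster",
    "bio4_from_monthly",
    "centroid_latitude",
    "bin_by_latitude",
    "read_cell_lists",
    "write_cell_lists",
]

#: Authalic Earth radius, km.
EARTH_RADIUS_KM = 6371.0072


@dataclass(frozen=True)
class BehrmannGrid:
    """Regular square lattice on the Behrmann projection.

    Cells are ``resolution_km`` on a side in projected space, hence equal
    area on the sphere.  Row/column indices count from the south-west
    corner of the covering lattice; ``cell_id = row * n_cols + col``.
    """

    resolution_km: float
    radius_km: float = EARTH_RADIUS_KM
    standard_parallel: float = 30.0

    def __post_init__(self):
        if self.resolution_km <= 0:
            raise ValueError("resolution must be positive")

    @property
    def _k(self) -> float:
        return math.cos(math.radians(self.standard_parallel))

    @property
    def x_max(self) -> float:
        return math.pi * self.radius_km * self._k

    @property
    def y_max(self) -> float:
        return self.radius_km / self._k

    @property
    def n_cols(self) -> int:
        return 2 * math.ceil(self.x_max / self.resolution_km)

    @property
    def n_rows(self) -> int:
        return 2 * math.ceil(self.y_max / self.resolution_km)

    @property
    def cell_area_km2(self) -> float:
        return self.resolution_km**2

    # -- projection ---------------------------------------------------------
    def project(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        x = self.radius_km * np.radians(lon) * self._k
        y = self.radius_km * np.sin(np.radians(lat)) / self._k
        return x, y

    def unproject(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lon = np.degrees(x / (self.radius_km * self._k))
        s = np.clip(y * self._k / self.radius_km, -1.0, 1.0)
        lat = np.degrees(np.arcsin(s))
        return lon, lat

    # -- lattice indexing ---------------------------------------------------
    def _col_of_x(self, x):
        return np.floor(np.asarray(x) / self.resolution_km).astype(int) + self.n_cols // 2

    def _row_of_y(self, y):
        return np.floor(np.asarray(y) / self.resolution_km).astype(int) + self.n_rows // 2

    def cell_of_projected(self, x, y):
        return self._row_of_y(y) * self.n_cols + self._col_of_x(x)

    def cell_of(self, lon, lat):
        """Cell id containing a geographic point (half-open membership)."""
        x, y = self.project(lon, lat)
        return self.cell_of_projected(x, y)

    def rowcol(self, cell_id):
        cell_id = np.asarray(cell_id)
        return cell_id // self.n_cols, cell_id % self.n_cols

    def cell_bounds(self, cell_id):
        """Projected (x0, y0, x1, y1) of a cell."""
        row, col = self.rowcol(cell_id)
        x0 = (np.asarray(col) - self.n_cols // 2) * self.resolution_km
        y0 = (np.asarray(row) - self.n_rows // 2) * self.resolution_km
        return x0, y0, x0 + self.resolution_km, y0 + self.resolution_km

    def centroid_latlon(self, cell_id):
        x0, y0, x1, y1 = self.cell_bounds(cell_id)
        return self.unproject((np.asarray(x0) + x1) / 2.0, (np.asarray(y0) + y1) / 2.0)

    def centroid_abs_latitude(self, cell_id):
        return np.abs(self.centroid_latlon(cell_id)[1])


@dataclass
class Raster:
    """Gridded values aligned to a :class:`BehrmannGrid` lattice.

    ``values`` is indexed ``[row, col]`` in the grid's own row/column
    frame; NaN marks invalid (e.g. ocean) cells when a validity mask is in
    use.
    """

    grid: BehrmannGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.grid.n_rows, self.grid.n_cols)
        if self.values.shape != expected:
            raise ValueError(f"raster shape {self.values.shape} != grid shape {expected}")

    def value_at_cell(self, cell_id):
        row, col = self.grid.rowcol(cell_id)
        return self.values[row, col]

    @classmethod
    def constant(cls, grid: BehrmannGrid, value: float) -> "Raster":
        return cls(grid, np.full((grid.n_rows, grid.n_cols), float(value)))

    def write_text(self, path) -> None:
        header = (
            f"# behrmann_raster resolution_km={self.grid.resolution_km} "
            f"radius_km={self.grid.radius_km} n_rows={self.grid.n_rows} "
            f"n_cols={self.grid.n_cols}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.values, fmt="%.8g")

    @classmethod
    def read_text(cls, path) -> "Raster":
        with open(path) as fh:
            header = fh.readline()
            meta = dict(tok.split("=") for tok in header.split() if "=" in tok)
            grid = BehrmannGrid(
                resolution_km=float(meta["resolution_km"]),
                radius_km=float(meta["radius_km"]),
            )
            values = np.loadtxt(fh)
        return cls(grid, values)


# ---------------------------------------------------------------------------
# range handling

def _project_polygon(poly: Polygon, grid: BehrmannGrid) -> Polygon:
    """Project polygon vertices to the Behrmann plane.

    Edges are mapped as straight segments between projected vertices;
    lon/lat-aligned rectangle edges are exact under this projection.
    """
    return shapely_transform(lambda lon, lat: grid.project(lon, lat), poly)


def rasterize_range(
    range_geometry: Polygon,
    fine_grid: BehrmannGrid,
    min_overlap: float = 0.5,
    geographic: bool = True,
) -> Set[int]:
    """Fine-grid cells covered by a breeding-range polygon.

    A cell is occupied iff the polygon covers at least ``min_overlap`` of
    its (equal) area.  ``geographic=True`` means coordinates are lon/lat
    degrees; pass False for a polygon already in projected km.
    """
    if not 0.0 < min_overlap <= 1.0:
        raise ValueError("min_overlap must lie in (0, 1]")
    if range_geometry.is_empty:
        logger.warning("empty range geometry -> empty occupancy")
        return set()
    poly = _project_polygon(range_geometry, fine_grid) if geographic else range_geometry
    res = fine_grid.resolution_km
    minx, miny, maxx, maxy = poly.bounds
    col_lo = math.floor(minx / res)
    col_hi = math.floor(max(maxx - 1e-12, minx) / res)
    row_lo = math.floor(miny / res)
    row_hi = math.floor(max(maxy - 1e-12, miny) / res)
    occupied: Set[int] = set()
    area = fine_grid.cell_area_km2
    for i in range(row_lo, row_hi + 1):
        for j in range(col_lo, col_hi + 1):
            cell = box(j * res, i * res, (j + 1) * res, (i + 1) * res)
            frac = poly.intersection(cell).area / area
            if frac >= min_overlap - 1e-12:
                row = i + fine_grid.n_rows // 2
                col = j + fine_grid.n_cols // 2
                occupied.add(row * fine_grid.n_cols + col)
    return occupied


def occupancy_from_bands(
    bands: pd.DataFrame, fine_grid: BehrmannGrid
) -> Dict[str, Set[int]]:
    """Occupancy for latitude-band ranges.

    ``bands`` columns: species_id, lat_min, lat_max, lon_min, lon_max.
    A cell is occupied iff its centroid falls inside the band — the
    analytic analogue of the >=50%-overlap rule for box ranges.
    """
    occ: Dict[str, Set[int]] = {}
    res = fine_grid.resolution_km
    for rec in bands.itertuples(index=False):
        x0, y0 = fine_grid.project(rec.lon_min, rec.lat_min)
        x1, y1 = fine_grid.project(rec.lon_max, rec.lat_max)
        cols = np.arange(math.floor(x0 / res), math.floor(x1 / res) + 1)
        rows = np.arange(math.floor(y0 / res), math.floor(y1 / res) + 1)
        cx = (cols + 0.5) * res
        cy = (rows + 0.5) * res
        cols = cols[(cx >= x0) & (cx <= x1)]
        rows = rows[(cy >= y0) & (cy <= y1)]
        if rows.size == 0 or cols.size == 0:
            # band narrower than one cell: fall back to the centre cell
            cid = fine_grid.cell_of_projected((x0 + x1) / 2.0, (y0 + y1) / 2.0)
            occ[str(rec.species_id)] = {int(cid)}
            continue
        rr = rows[:, None] + fine_grid.n_rows // 2
        cc = cols[None, :] + fine_grid.n_cols // 2
        ids = (rr * fine_grid.n_cols + cc).ravel()
        occ[str(rec.species_id)] = set(int(i) for i in ids)
    return occ


def coarsen_occupancy(
    occupancy: Mapping[str, Set[int]],
    fine_grid: BehrmannGrid,
    coarse_grid: BehrmannGrid,
) -> Dict[str, Set[int]]:
    """Union fine-cell occupancy up to the coarse analysis lattice.

    A species occupies a coarse cell iff it occupies any nested fine cell
    (membership judged by the fine-cell centroid).
    """
    out: Dict[str, Set[int]] = {}
    for sp, cells in occupancy.items():
        ids = np.fromiter(cells, dtype=int, count=len(cells))
        if ids.size == 0:
            out[sp] = set()
            continue
        x0, y0, x1, y1 = fine_grid.cell_bounds(ids)
        coarse = coarse_grid.cell_of_projected((x0 + x1) / 2.0, (y0 + y1) / 2.0)
        out[sp] = set(int(c) for c in np.unique(coarse))
    return out


# ---------------------------------------------------------------------------
# aggregation

def cell_means(
    occupancies: Mapping[str, Set[int]],
    scores: Mapping[str, float],
    grid: BehrmannGrid,
    min_richness: int = 10,
    certainties: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Per-cell species richness and mean score, with the richness filter.

    Every occupied species must carry a score; cells with fewer than
    ``min_richness`` species are dropped from the model-ready output.
    Columns: cell_id, richness, mean_score, (mean_certainty,) abs_latitude.
    """
    missing = [sp for sp in occupancies if sp not in scores]
    if missing:
        raise ValueError(f"species with occupancy but no score: {sorted(missing)[:10]}")
    sums: Dict[int, float] = {}
    counts: Dict[int, int] = {}
    cert_sums: Dict[int, float] = {}
    for sp, cells in occupancies.items():
        s = float(scores[sp])
        c = float(certainties[sp]) if certainties is not None else 0.0
        for cell in cells:
            sums[cell] = sums.get(cell, 0.0) + s
            counts[cell] = counts.get(cell, 0) + 1
            if certainties is not None:
                cert_sums[cell] = cert_sums.get(cell, 0.0) + c
    rows = []
    for cell, n in sorted(counts.items()):
        if n < min_richness:
            continue
        rec = {
            "cell_id": cell,
            "richness": n,
            "mean_score": sums[cell] / n,
            "abs_latitude": float(grid.centroid_abs_latitude(cell)),
        }
        if certainties is not None:
            rec["mean_certainty"] = cert_sums[cell] / n
        rows.append(rec)
    return pd.DataFrame(rows)


def range_mean_raster(occupancy: Set[int], raster: Raster) -> float:
    """Unweighted mean of raster values over a species' occupied cells."""
    if not occupancy:
        logger.warning("occupancy empty: range mean undefined")
        return float("nan")
    ids = np.fromiter(occupancy, dtype=int, count=len(occupancy))
    vals = raster.value_at_cell(ids)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        logger.warning("no valid raster cells under range: range mean undefined")
        return float("nan")
    return float(vals.mean())


def bio4_from_monthly(monthly: Iterable[Raster], ddof: int = 0) -> Raster:
    """Temperature seasonality: per-cell SD of the 12 monthly mean layers.

    Population SD (``ddof=0``) by default, matching the bioclim convention.
    """
    layers = list(monthly)
    if len(layers) != 12:
        raise ValueError(f"need exactly 12 monthly layers, got {len(layers)}")
    grid = layers[0].grid
    for lyr in layers[1:]:
        if lyr.grid != grid:
            raise ValueError("monthly layers are not aligned to the same grid")
    stack = np.stack([lyr.values for lyr in layers])
    return Raster(grid, stack.std(axis=0, ddof=ddof))


def centroid_latitude(range_geometry: Polygon, grid: Optional[BehrmannGrid] = None) -> float:
    """Latitude of the range's area centroid, computed on the equal-area plane."""
    grid = grid or BehrmannGrid(resolution_km=5.0)
    proj = _project_polygon(range_geometry, grid)
    _, lat = grid.unproject(proj.centroid.x, proj.centroid.y)
    return float(lat)


def bin_by_latitude(
    species: pd.DataFrame,
    width: float = 5.0,
    value_col: str = "score",
    lat_col: str = "centroid_lat",
    min_count: int = 10,
) -> pd.DataFrame:
    """Mean score and species count per latitude bin of ``width`` degrees.

    Bins cover [-90, 90); bins with fewer than ``min_count`` species are
    flagged (``excluded=True``) rather than dropped, mirroring plot-level
    filtering.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    lat = species[lat_col].to_numpy(float)
    idx = np.floor((lat + 90.0) / width).astype(int)
    df = species.assign(_bin=idx)
    grouped = df.groupby("_bin")[value_col].agg(["mean", "count"]).reset_index()
    grouped["bin_lat_mid"] = grouped["_bin"] * width - 90.0 + width / 2.0
    grouped["excluded"] = grouped["count"] < min_count
    return grouped.rename(columns={"mean": "mean_score", "count": "n_species"})[
        ["bin_lat_mid", "mean_score", "n_species", "excluded"]
    ]


# ---------------------------------------------------------------------------
# cell-list I/O

def read_cell_lists(path) -> Dict[str, Set[int]]:
    df = pd.read_csv(path)
    occ: Dict[str, Set[int]] = {}
    for sp, grp in df.groupby("species_id"):
        occ[str(sp)] = set(int(c) for c in grp["cell_id"])
    return occ


def write_cell_lists(occupancy: Mapping[str, Set[int]], path) -> None:
    rows = [(sp, cell) for sp in sorted(occupancy) for cell in sorted(occupancy[sp])]
    pd.DataFrame(rows, columns=["species_id", "cell_id"]).to_csv(path, index=False)
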