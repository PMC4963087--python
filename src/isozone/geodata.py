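"""Plot-local grids, rasters, sample tables and canopy geometry.

All coordinates are plot-local Cartesian metres with the origin at the
south-west plot corner. Cell centres sit at ``(x_min + (j+0.5)*res,
y_min + (i+0.5)*res)`` with row 0 the southernmost row. No CRS handling:
field plots here are tens of metres across and surveyed with a tape.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
import shapely.geometry
import shapely.wkt
from scipy.ndimage import distance_transform_edt
from shapely.geometry.base import BaseGeometry

log = logging.getLogger(__name__)

NODATA = -9999.0

TRACERS = ("n_conc", "d15N", "d13C")
TRACER_UNITS = {"n_conc": "g N kg-1", "d15N": "permil", "d13C": "permil"}


class SchemaError(ValueError):
    """A required column is absent from an input table."""


class ValidationError(ValueError):
    """Input records violate an invariant (duplicates, non-positive N, ...)."""


@dataclass(frozen=True)
class PlotExtent:
    """Rectangular plot footprint in metres."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate extent: ({self.x_min}, {self.y_min}) .. "
                f"({self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def diagonal(self) -> float:
        return math.hypot(self.width, self.height)


@dataclass(frozen=True)
class PlotGrid:
    """Regular square-cell raster grid over a plot extent."""

    extent: PlotExtent
    resolution: float

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")

    @property
    def n_cols(self) -> int:
        return int(math.ceil(self.extent.width / self.resolution - 1e-12))

    @property
    def n_rows(self) -> int:
        return int(math.ceil(self.extent.height / self.resolution - 1e-12))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of cell-centre coordinates, shape (n_rows, n_cols)."""
        xs = self.extent.x_min + (np.arange(self.n_cols) + 0.5) * self.resolution
        ys = self.extent.y_min + (np.arange(self.n_rows) + 0.5) * self.resolution
        return np.meshgrid(xs, ys)

    def fingerprint(self) -> str:
        e = self.extent
        return (f"{float(e.x_min)}:{float(e.y_min)}:{float(e.x_max)}:"
                f"{float(e.y_max)}:{float(self.resolution)}")


@dataclass
class Raster:
    """One value per grid cell; ``np.nan`` marks missing cells in memory."""

    grid: PlotGrid
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"value shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds a value."""
        return ~np.isnan(self.values)


# ---------------------------------------------------------------------------
# sample tables
# ---------------------------------------------------------------------------

DEFAULT_COLUMNS = {"x": "x", "y": "y", "n_conc": "n_conc", "d15N": "d15N", "d13C": "d13C"}


def read_samples(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a georeferenced tracer sample table from CSV.

    Parameters
    ----------
    path : str or Path
        CSV file with a header row.
    column_map : dict, optional
        Maps canonical names (``x``, ``y``, ``n_conc``, ``d15N``, ``d13C``)
        to the column names used in the file.

    Returns
    -------
    DataFrame with canonical columns, row order preserved. Records with any
    missing tracer are rejected; duplicated (x, y) pairs and non-positive N
    concentrations raise :class:`ValidationError`.
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path)
    missing = [src for src in cmap.values() if src not in raw.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}; found {list(raw.columns)}")
    out = pd.DataFrame({canon: raw[src] for canon, src in cmap.items()})
    if "sample_id" in raw.columns:
        out["sample_id"] = raw["sample_id"]
    for canon in cmap:
        vals = pd.to_numeric(out[canon], errors="coerce")
        bad = vals.isna() & out[canon].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"non-numeric value {out[canon].iloc[row]!r} in column {canon!r}, data row {row}"
            )
        out[canon] = vals
    if out[list(cmap)].isna().any(axis=None):
        nrows = out[list(cmap)].isna().any(axis=1).sum()
        raise ValidationError(f"{nrows} record(s) with missing tracer or coordinate values")
    dup = out.duplicated(subset=["x", "y"])
    if dup.any():
        xy = out.loc[dup.idxmax(), ["x", "y"]].tolist()
        raise ValidationError(f"duplicate sample coordinates at {tuple(xy)}")
    if (out["n_conc"] <= 0).any():
        raise ValidationError("n_conc must be > 0 for every record")
    return out.reset_index(drop=True)


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# canopy polygons
# ---------------------------------------------------------------------------


def read_canopies(path) -> list[BaseGeometry]:
    """Read canopy outlines from GeoJSON (.geojson/.json) or WKT text (.wkt).

    A WKT file holds one geometry per non-empty line. Returns a flat list of
    shapely polygons (MultiPolygons are split).
    """
    path = str(path)
    geoms: list[BaseGeometry] = []
    if path.endswith((".geojson", ".json")):
        with open(path) as fh:
            gj = json.load(fh)
        feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
        for feat in feats:
            geom = feat.get("geometry", feat)
            geoms.append(shapely.geometry.shape(geom))
    elif path.endswith(".wkt"):
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    geoms.append(shapely.wkt.loads(line))
    else:
        raise ValueError(f"unsupported canopy format for {path!r}: use .geojson/.json or .wkt")
    flat: list[BaseGeometry] = []
    for g in geoms:
        if g.geom_type == "MultiPolygon":
            flat.extend(g.geoms)
        else:
            flat.append(g)
    for g in flat:
        if not g.is_valid:
            raise ValidationError(f"invalid (self-intersecting?) canopy polygon: {g.wkt[:80]}")
    return flat


def write_canopies(canopies: list[BaseGeometry], path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {}, "geometry": shapely.geometry.mapping(g)}
            for g in canopies
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh)


def rasterize_canopy(canopies: list[BaseGeometry], grid: PlotGrid) -> Raster:
    """Boolean canopy raster: a cell is occupied iff its centre lies inside a polygon.

    Centre containment (not area fraction) matches treating a cell as
    "occupied" by the invader canopy. An empty canopy list gives an all-false
    raster (an uninvaded plot, not an error).
    """
    X, Y = grid.cell_centers()
    occupied = np.zeros(grid.shape, dtype=bool)
    if canopies:
        pts = shapely.points(X.ravel(), Y.ravel())
        for poly in canopies:
            occupied |= shapely.contains(poly, pts).reshape(grid.shape)
    return Raster(grid, occupied.astype(float), units="bool")


def distance_to_canopy(canopy_raster: Raster) -> Raster:
    """Euclidean centre-to-centre distance (m) to the nearest occupied cell.

    Occupied cells get 0. With no occupied cell at all the result is
    all-missing and a warning is logged (uninvaded control plots).
    """
    occ = canopy_raster.values > 0.5
    grid = canopy_raster.grid
    if not occ.any():
        log.warning("distance_to_canopy: no occupied cells; returning all-missing raster")
        return Raster(grid, np.full(grid.shape, np.nan), units="m")
    # exact EDT of the complement, scaled to metres
    dist = distance_transform_edt(~occ, sampling=grid.resolution)
    return Raster(grid, dist, units="m")


# ---------------------------------------------------------------------------
# raster I/O — ESRI ASCII grid (text, round-trips exactly via repr floats)
# ---------------------------------------------------------------------------

SUPPORTED_RASTER_FORMATS = ("asc",)


def write_raster(raster: Raster, path, fmt: str = "asc") -> None:
    """Write a raster to disk. Supported: ESRI ASCII grid (``asc``).

    Values are written with ``repr`` precision so a read-back is
    bit-identical; missing cells use the ESRI NODATA sentinel.
    """
    if fmt != "asc":
        raise ValueError(
            f"unknown raster format {fmt!r}; supported: {', '.join(SUPPORTED_RASTER_FORMATS)}"
        )
    g = raster.grid
    vals = raster.values
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.extent.x_min!r}\n")
        fh.write(f"yllcorner {g.extent.y_min!r}\n")
        fh.write(f"cellsize {g.resolution!r}\n")
        fh.write(f"NODATA_value {NODATA!r}\n")
        # ESRI convention: first data row is the NORTHERNMOST row
        for i in range(g.n_rows - 1, -1, -1):
            row = [NODATA if np.isnan(v) else v for v in vals[i]]
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_raster(path, units: str = "") -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_raster`."""
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        n_cols = int(header["ncols"])
        n_rows = int(header["nrows"])
        res = header["cellsize"]
        x0 = header["xllcorner"]
        y0 = header["yllcorner"]
        nodata = header["nodata_value"]
        rows = [np.array(fh.readline().split(), dtype=float) for _ in range(n_rows)]
    vals = np.vstack(rows)[::-1]  # back to row 0 = south
    vals[vals == nodata] = np.nan
    extent = PlotExtent(x0, y0, x0 + n_cols * res, y0 + n_rows * res)
    return Raster(PlotGrid(extent, res), vals, units=units)
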