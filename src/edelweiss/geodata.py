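"""Raster/vector data model and terrain computations.

Conventions used throughout the package (stated once here):

* Coordinates are planar map units (pre-projected; no great-circle math).
* A grid cell ``(row, col)`` covers the half-open square
  ``[x_origin + col*s, x_origin + (col+1)*s) x (y_origin - (row+1)*s, y_origin - row*s]``
  with row 0 at the **top** of the grid.  A point lying exactly on a shared
  edge belongs to the cell on the greater-index side.
* Nodata cells are carried as ``NaN`` in memory; the nodata sentinel of a
  :class:`GridSpec` is only used when reading/writing the plain-text grid
  format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, MultiLineString, Point, shape

__all__ = [
    "GridSpec",
    "Raster",
    "TrailSet",
    "compute_tri",
    "assign_cells",
    "dedupe_presences",
    "distance_to_trails",
    "extract_at_points",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_points_csv",
    "write_points_csv",
]

#: canonical column names for point tables
PRESENCE = "presence"
PSEUDO_ABSENCE = "pseudo_absence"


@dataclass(frozen=True)
class GridSpec:
    """Georeferencing of a regular square-celled grid (row 0 at top)."""

    n_rows: int
    n_cols: int
    x_origin: float  # x of the top-left corner
    y_origin: float  # y of the top-left corner
    cell_size: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid."""
        return (
            self.x_origin,
            self.y_origin - self.n_rows * self.cell_size,
            self.x_origin + self.n_cols * self.cell_size,
            self.y_origin,
        )

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) under the half-open convention."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x_origin) / self.cell_size).astype(int)
        # rows grow downward from y_origin; the top edge of row r is
        # y_origin - r*s and the interval is open at the bottom, so a point
        # exactly on a horizontal edge falls in the cell below (greater row).
        row = np.floor((self.y_origin - y) / self.cell_size).astype(int)
        return row, col

    def cell_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        s = self.cell_size
        x = self.x_origin + (np.asarray(col) + 0.5) * s
        y = self.y_origin - (np.asarray(row) + 0.5) * s
        return x, y

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, col = self.cell_of(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)


@dataclass
class Raster:
    """Single-band raster; ``NaN`` marks nodata."""

    spec: GridSpec
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.spec.shape}"
            )

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    def copy_with(self, values: np.ndarray, name: str | None = None) -> "Raster":
        return Raster(self.spec, np.asarray(values, dtype=float), self.name if name is None else name)

    def aligned_with(self, other: "Raster") -> bool:
        return self.spec == other.spec


@dataclass
class TrailSet:
    """A collection of polylines (hiking trails) in map units."""

    polylines: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned = []
        for line in self.polylines:
            arr = np.asarray(line, dtype=float)
            if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] != 2:
                raise ValueError("each polyline needs >= 2 (x, y) vertices")
            cleaned.append(arr)
        self.polylines = cleaned

    def __len__(self) -> int:
        return len(self.polylines)

    def as_multilinestring(self) -> MultiLineString:
        return MultiLineString([LineString(p) for p in self.polylines])

    @classmethod
    def from_geojson(cls, path: str) -> "TrailSet":
        with open(path) as fh:
            doc = json.load(fh)
        geoms = []
        features = doc.get("features", [doc]) if doc.get("type") == "FeatureCollection" else [doc]
        for feat in features:
            geom = shape(feat["geometry"] if "geometry" in feat else feat)
            if isinstance(geom, LineString):
                geoms.append(np.asarray(geom.coords))
            elif isinstance(geom, MultiLineString):
                geoms.extend(np.asarray(g.coords) for g in geom.geoms)
            else:
                raise ValueError(f"unsupported geometry type {geom.geom_type!r}")
        return cls(geoms)

    def to_geojson(self, path: str) -> None:
        doc = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"trail_id": i},
                    "geometry": {"type": "LineString", "coordinates": p.tolist()},
                }
                for i, p in enumerate(self.polylines)
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)


# ---------------------------------------------------------------------------
# terrain


def compute_tri(elevation: Raster) -> Raster:
    """Terrain Ruggedness Index: per cell, the mean absolute elevation
    difference to its (up to 8) neighbours.

    Edge cells use the neighbours that exist; nodata neighbours are skipped;
    a cell whose whole neighbourhood is nodata (or that is nodata itself)
    yields nodata.
    """
    z = elevation.values
    if z.size < 1:
        raise ValueError("elevation raster is empty")
    n_rows, n_cols = z.shape
    abs_sum = np.zeros_like(z)
    count = np.zeros_like(z)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.full_like(z, np.nan)
            rs = slice(max(dr, 0), n_rows + min(dr, 0))
            rd = slice(max(-dr, 0), n_rows + min(-dr, 0))
            cs = slice(max(dc, 0), n_cols + min(dc, 0))
            cd = slice(max(-dc, 0), n_cols + min(-dc, 0))
            shifted[rd, cd] = z[rs, cs]
            diff = np.abs(z - shifted)
            ok = np.isfinite(diff)
            abs_sum[ok] += diff[ok]
            count[ok] += 1
    with np.errstate(invalid="ignore"):
        tri = np.where(count > 0, abs_sum / np.maximum(count, 1), np.nan)
    tri[~np.isfinite(z)] = np.nan
    return elevation.copy_with(tri, name="tri")


# ---------------------------------------------------------------------------
# point bookkeeping


def assign_cells(points: pd.DataFrame, spec: GridSpec) -> pd.DataFrame:
    """Attach ``row``/``col`` cell indices to a point table (columns x, y).

    Raises if any point lies outside the grid extent, listing the offenders.
    """
    out = points.copy()
    row, col = spec.cell_of(out["x"].to_numpy(), out["y"].to_numpy())
    bad = (row < 0) | (row >= spec.n_rows) | (col < 0) | (col >= spec.n_cols)
    if bad.any():
        idx = list(out.index[bad][:20])
        raise ValueError(f"{int(bad.sum())} point(s) outside grid extent, e.g. indices {idx}")
    out["row"] = row
    out["col"] = col
    return out


def dedupe_presences(points: pd.DataFrame) -> pd.DataFrame:
    """Collapse presences to one record per occupied grid cell.

    The first point (input order) in each cell is retained; requires
    ``row``/``col`` columns from :func:`assign_cells`.
    """
    if points.empty:
        return points.copy()
    if "row" not in points or "col" not in points:
        raise ValueError("cell indices missing; run assign_cells first")
    return points.drop_duplicates(subset=["row", "col"], keep="first").copy()


def distance_to_trails(points: pd.DataFrame, trails: TrailSet) -> np.ndarray:
    """Minimum Euclidean distance from each point to the trail network."""
    if len(trails) == 0:
        raise ValueError("empty trail set: distance to trails is undefined")
    mls = trails.as_multilinestring()
    pts = shapely.points(points["x"].to_numpy(), points["y"].to_numpy())
    return shapely.distance(pts, mls)


def extract_at_points(raster: Raster, points: pd.DataFrame, column: str | None = None) -> pd.DataFrame:
    """Attach the containing cell's value to each point (no interpolation).

    Points whose cell is nodata get ``NaN`` in the new column; callers decide
    whether to drop them (count reported via the returned frame).
    """
    out = points if {"row", "col"}.issubset(points.columns) else assign_cells(points, raster.spec)
    out = out.copy()
    name = column or (raster.name or "value")
    out[name] = raster.values[out["row"].to_numpy(), out["col"].to_numpy()]
    return out


# ---------------------------------------------------------------------------
# plain-text I/O


def write_ascii_grid(raster: Raster, path: str) -> None:
    spec = raster.spec
    vals = np.where(np.isfinite(raster.values), raster.values, spec.nodata)
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {spec.x_origin!r}\n"
        f"yllcorner {spec.y_origin - spec.n_rows * spec.cell_size!r}\n"
        f"cellsize {spec.cell_size!r}\n"
        f"NODATA_value {spec.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path: str, name: str = "") -> Raster:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    vals = vals.reshape(n_rows, n_cols)
    spec = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + n_rows * header["cellsize"],
        cell_size=header["cellsize"],
        nodata=header["nodata_value"],
    )
    vals = np.where(vals == spec.nodata, np.nan, vals)
    return Raster(spec, vals, name=name)


def read_points_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "x" not in df or "y" not in df:
        raise ValueError("point CSV needs 'x' and 'y' columns")
    return df


def write_points_csv(points: pd.DataFrame, path: str) -> None:
    points.to_csv(path, index=False)
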