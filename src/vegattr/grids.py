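"""Grid geometry, raster containers and GeoTIFF-style I/O.

Every layer in the pipeline lives on one shared equal-area grid. The grid is
defined by its upper-left corner in projected meters, a square cell size and
a row-major (north-to-south) storage order. Cell membership is half-open: a
point belongs to cell (r, c) iff

    c <= (x - origin_x) / cell_size < c + 1
    r <= (origin_y - y) / cell_size < r + 1

so boundary points on the west/north edges of a cell belong to it and
east/south edges belong to the neighbour. Rasters are written as single-band
TIFF files with the grid geometry, nodata value and time label serialized as
JSON in the ImageDescription tag.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
from scipy import ndimage


class GridMismatchError(ValueError):
    """Raised when a layer's geometry disagrees with the pipeline grid."""


@dataclass(frozen=True)
class GridSpec:
    """Fixed equal-area analysis grid.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions; at least 1 each.
    cell_size : float
        Cell edge length in projected meters (default 250 m).
    origin_x, origin_y : float
        Projected coordinates of the upper-left corner of cell (0, 0).
    crs_label : str
        Identifier of the equal-area projection; metadata only.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 250.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs_label: str = "albers_equal_area"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not (self.cell_size > 0):
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid bounding box."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    def contains(self, x, y) -> np.ndarray:
        """Half-open membership test for points (vectorized)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        xmin, ymin, xmax, ymax = self.extent
        return (x >= xmin) & (x < xmax) & (y > ymin) & (y <= ymax)

    def point_to_cell(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map projected points to (row, col); caller must ensure containment."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(np.int64)
        row = np.floor((self.origin_y - y) / self.cell_size).astype(np.int64)
        # the north/west edge of the grid belongs to row/col 0
        row = np.where(row == -0, 0, row)
        return row, col

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinate arrays of shape (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "cell_size": self.cell_size,
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "crs_label": self.crs_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**{k: d[k] for k in (
            "n_rows", "n_cols", "cell_size", "origin_x", "origin_y", "crs_label")})


@dataclass
class AnnualRasterSeries:
    """Time-stacked raster values on a fixed grid.

    ``values`` has shape (n_times, n_rows, n_cols) with NaN as nodata.
    ``times`` is a strictly increasing float array (year, or year plus a
    within-year composite fraction); ``labels`` keeps the original string
    labels when the series was read from files.
    """

    grid: GridSpec
    times: np.ndarray
    values: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (time, row, col)")
        if self.values.shape != (len(self.times), *self.grid.shape):
            raise GridMismatchError(
                f"value stack {self.values.shape} inconsistent with grid "
                f"{self.grid.shape} and {len(self.times)} times")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not self.labels:
            self.labels = [_format_time(t) for t in self.times]

    @property
    def n_times(self) -> int:
        return len(self.times)

    def copy(self) -> "AnnualRasterSeries":
        return AnnualRasterSeries(self.grid, self.times.copy(),
                                  self.values.copy(), list(self.labels))


def _format_time(t: float) -> str:
    return str(int(t)) if float(t).is_integer() else f"{t:g}"


# ---------------------------------------------------------------------------
# TIFF I/O

def write_raster(path, values: np.ndarray, grid: GridSpec, *,
                 nodata: float = np.nan, time_label: str | None = None) -> None:
    """Write one single-band raster with geometry in the description tag."""
    values = np.asarray(values, dtype=np.float32)
    if values.shape != grid.shape:
        raise GridMismatchError(
            f"array {values.shape} does not match grid {grid.shape}")
    meta = {"grid": grid.to_dict(), "nodata": None if np.isnan(nodata) else nodata}
    if time_label is not None:
        meta["time"] = str(time_label)
    tifffile.imwrite(str(path), values, description=json.dumps(meta))


def read_raster(path) -> tuple[np.ndarray, GridSpec, str | None]:
    """Read one raster; returns (values with NaN nodata, grid, time label)."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        desc = page.tags.get("ImageDescription")
        if desc is None:
            raise ValueError(f"{path}: missing grid metadata")
        meta = json.loads(desc.value)
    grid = GridSpec.from_dict(meta["grid"])
    nodata = meta.get("nodata")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    return values, grid, meta.get("time")


_TIME_RE = re.compile(r"(\d{4}(?:\.\d+)?)")


def _parse_time_label(label: str, fallback: str) -> float:
    for text in (label, fallback):
        if text:
            m = _TIME_RE.search(str(text))
            if m:
                return float(m.group(1))
    raise ValueError(f"cannot parse a time label from {label!r} / {fallback!r}")


def write_raster_series(directory, series: AnnualRasterSeries,
                        prefix: str = "layer") -> list[Path]:
    """One file per time step, named ``<prefix>_<label>.tif``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for t, label in enumerate(series.labels):
        p = directory / f"{prefix}_{label}.tif"
        write_raster(p, np.nan_to_num(series.values[t], nan=np.nan),
                     series.grid, time_label=label)
        paths.append(p)
    return paths


def read_raster_series(paths: Sequence, grid: GridSpec | None = None,
                       *, resample: str | None = None) -> AnnualRasterSeries:
    """Read a stack of single-band rasters into a time-sorted series.

    Layers must share the target geometry; with ``resample`` in
    {"nearest", "bilinear"} mismatching layers are aligned to ``grid``
    instead of raising.
    """
    if not paths:
        raise ValueError("no input paths")
    entries = []
    for p in paths:
        values, g, label = read_raster(p)
        if grid is None:
            grid = g
        if g != grid:
            if resample is None:
                raise GridMismatchError(
                    f"layer {p} geometry {g.to_dict()} does not match the "
                    "series grid; pass resample='nearest'|'bilinear'")
            values = align_to_grid(values, g, grid, method=resample)
        t = _parse_time_label(label or "", Path(p).stem)
        entries.append((t, str(label or Path(p).stem), values))
    entries.sort(key=lambda e: e[0])
    times = np.array([e[0] for e in entries])
    labels = [e[1] for e in entries]
    stack = np.stack([e[2] for e in entries])
    return AnnualRasterSeries(grid, times, stack, labels)


# ---------------------------------------------------------------------------
# Grid-to-grid alignment

def align_to_grid(values: np.ndarray, src: GridSpec, dst: GridSpec,
                  method: str = "bilinear") -> np.ndarray:
    """Resample a raster from one grid onto another.

    ``nearest`` is used for counts and masks, ``bilinear`` for continuous
    fields. Bilinear interpolates between cell centers and clamps at the
    edges, so output values never leave the input min/max range; NaN nodata
    propagates to any output cell whose interpolation stencil touches it.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown resampling method {method!r}")
    values = np.asarray(values, dtype=float)
    if values.shape != src.shape:
        raise GridMismatchError("array does not match source grid")
    sxmin, symin, sxmax, symax = src.extent
    dxmin, dymin, dxmax, dymax = dst.extent
    if dxmin >= sxmax or dxmax <= sxmin or dymin >= symax or dymax <= symin:
        raise ValueError("source and target grids do not overlap")
    x, y = dst.cell_centers()
    # fractional source array indices of the target cell centers
    col = (x - src.origin_x) / src.cell_size - 0.5
    row = (src.origin_y - y) / src.cell_size - 0.5
    order = 0 if method == "nearest" else 1
    return ndimage.map_coordinates(values, [row, col], order=order,
                                   mode="nearest")


def assert_shared_grid(layers: Iterable, grid: GridSpec) -> None:
    """Pipeline-level check that every layer sits on the one analysis grid."""
    for i, layer in enumerate(layers):
        g = getattr(layer, "grid", None)
        if g is not None and g != grid:
            raise GridMismatchError(f"layer {i} is not on the shared grid")
        shape = getattr(layer, "shape", None)
        if g is None and shape is not None and tuple(shape[-2:]) != grid.shape:
            raise GridMismatchError(f"layer {i} shape {shape} is off-grid")
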