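"""Gridded raster container and plain-text (ESRI ASCII grid) I/O.

All grids are north-up, pixel-is-area, geographic lon/lat on the WGS84
sphere. Nodata is IEEE NaN in memory and the sentinel ``-9999`` on disk.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

NODATA = -9999.0
#: mean spherical Earth radius used for pixel areas (m), MODIS sinusoidal sphere
EARTH_RADIUS_M = 6371007.181


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up geographic grid.

    ``origin_lon``/``origin_lat`` locate the *top-left corner* of the
    top-left pixel; ``cell_size`` is in decimal degrees (square cells).
    """

    rows: int
    cols: int
    cell_size: float
    origin_lon: float
    origin_lat: float

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    def lon_centers(self) -> np.ndarray:
        return self.origin_lon + (np.arange(self.cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        return self.origin_lat - (np.arange(self.rows) + 0.5) * self.cell_size

    def pixel_area_m2(self) -> np.ndarray:
        """Per-row pixel area (m^2), spherical cos-latitude scaling.

        area = (R dphi) * (R dlambda cos(lat_center)); broadcastable to the
        grid as a column vector.
        """
        d = np.deg2rad(self.cell_size)
        lat = np.deg2rad(self.lat_centers())
        return (EARTH_RADIUS_M * d) ** 2 * np.cos(lat)[:, None] * np.ones(self.cols)


@dataclass
class Raster:
    """A 2-D field on a :class:`GridSpec`; NaN marks nodata."""

    data: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    def copy(self) -> "Raster":
        return Raster(self.data.copy(), self.grid)

    def same_grid(self, other: "Raster") -> bool:
        return self.grid == other.grid


def _require_same_grid(*rasters: Raster) -> None:
    g = rasters[0].grid
    for r in rasters[1:]:
        if r.grid != g:
            raise ValueError("rasters are not co-registered (grid mismatch)")


@dataclass
class CompositeStack:
    """Ordered co-registered layers at 16-day steps within one season."""

    layers: np.ndarray  # (n, rows, cols)
    start_dates: list[_dt.date]
    grid: GridSpec
    variable: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.ndim != 3:
            raise ValueError("layers must be a (n, rows, cols) array")
        if self.layers.shape[1:] != self.grid.shape:
            raise ValueError("layer shape does not match grid")
        if self.layers.shape[0] != len(self.start_dates):
            raise ValueError("one start date required per layer")
        for a, b in zip(self.start_dates, self.start_dates[1:]):
            if (b - a).days != 16:
                raise ValueError("start dates must be strictly increasing at 16-day spacing")

    def __len__(self) -> int:
        return self.layers.shape[0]

    def layer(self, i: int) -> Raster:
        return Raster(self.layers[i], self.grid)


def write_ascii_grid(raster: Raster, path) -> None:
    """Write one raster as an ESRI ASCII grid (text; -9999 nodata)."""
    g = raster.grid
    data = np.where(np.isnan(raster.data), NODATA, raster.data)
    header = (
        f"ncols {g.cols}\n"
        f"nrows {g.rows}\n"
        f"xllcorner {g.origin_lon!r}\n"
        f"yllcorner {g.origin_lat - g.rows * g.cell_size!r}\n"
        f"cellsize {g.cell_size!r}\n"
        f"NODATA_value {NODATA:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in data:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`.

    The format is inherently north-up geographic; malformed headers are
    rejected.
    """
    with open(path) as fh:
        hdr: dict[str, float] = {}
        for _ in range(6):
            line = fh.readline()
            try:
                key, val = line.split()
            except ValueError as exc:
                raise ValueError(f"malformed ASCII grid header line: {line!r}") from exc
            hdr[key.lower()] = float(val)
        for k in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
            if k not in hdr:
                raise ValueError(f"ASCII grid header missing {k}")
        rows, cols = int(hdr["nrows"]), int(hdr["ncols"])
        data = np.loadtxt(fh, dtype=float)
    data = np.atleast_2d(data)
    if data.shape != (rows, cols):
        raise ValueError("ASCII grid body does not match header dimensions")
    data[data == hdr["nodata_value"]] = np.nan
    grid = GridSpec(
        rows=rows,
        cols=cols,
        cell_size=hdr["cellsize"],
        origin_lon=hdr["xllcorner"],
        origin_lat=hdr["yllcorner"] + rows * hdr["cellsize"],
    )
    return Raster(data, grid)
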