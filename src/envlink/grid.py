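"""Container and I/O for gridded spatio-temporal exposure maps.

An :class:`ExposureGrid` holds a daily stack of values on a regular planar
grid (e.g. 1 x 1 km PM2.5 concentrations on the British National Grid).
Cells are referenced by their *centroids*: cell (i, j) sits at
``(origin_x + i*dx, origin_y + j*dy)``.  Missingness (e.g. sea cells in a
Great Britain grid) is carried as an explicit boolean mask rather than
sentinel values.

Three on-disk representations are supported:

``long_csv``
    Tidy table with header ``date,easting,northing,value`` and ISO-8601
    dates; missing cell-days are simply absent rows.
``netcdf``
    NetCDF3 classic file (via xarray's scipy backend) with dimensions
    ``(time, y, x)`` and coordinate variables holding cell centroids.
``tiff_stack``
    One float TIFF image per day plus a JSON manifest mapping file to date
    and carrying the georeferencing (origin, spacing, CRS label).  Rows are
    stored with y ascending.

No reprojection is performed anywhere: the CRS is treated as an opaque
planar system in metres, and cohort coordinates are assumed to share it.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass

import numpy as np
import pandas as pd


class GridError(ValueError):
    """Base class for exposure-grid construction and I/O failures."""


class IrregularGridError(GridError):
    """Raised when coordinates do not form a regular lattice ("irregular grid")."""


class TimeAxisError(GridError):
    """Raised when the time axis is empty, non-daily or gapped ("time axis")."""


def _daily_index(dates) -> pd.DatetimeIndex:
    """Validate and normalise a contiguous daily calendar axis."""
    idx = pd.DatetimeIndex(pd.to_datetime(dates)).normalize()
    if len(idx) == 0:
        raise TimeAxisError("time axis: empty date axis")
    if idx.has_duplicates:
        raise TimeAxisError("time axis: duplicate dates")
    if len(idx) > 1:
        steps = np.diff(idx.values).astype("timedelta64[D]").astype(int)
        if not np.all(steps == 1):
            raise TimeAxisError("time axis: dates are not strictly consecutive days")
    return idx


@dataclass
class ExposureGrid:
    """Daily exposure values on a regular planar grid with centroid-referenced cells.

    Parameters
    ----------
    origin_x, origin_y
        Centroid coordinate of cell (0, 0), in metres.
    dx, dy
        Cell spacing in metres (positive).
    nx, ny
        Number of cells along x (easting) and y (northing); at least 2 each
        so bilinear interpolation is defined.
    dates
        Contiguous daily calendar axis.
    values
        Array of shape ``(n_dates, ny, nx)``; entries under the mask are
        ignored (stored as NaN on disk).
    missing_mask
        Boolean array, same shape as ``values``; True marks missing cells.
    """

    origin_x: float
    origin_y: float
    dx: float
    dy: float
    nx: int
    ny: int
    dates: pd.DatetimeIndex
    values: np.ndarray
    missing_mask: np.ndarray | None = None
    crs_label: str = "EPSG:27700"
    quantity_name: str = "PM2.5"
    units: str = "ug/m3"

    def __post_init__(self):
        if not (self.dx > 0 and self.dy > 0):
            raise GridError("cell spacing must be positive")
        if self.nx < 2 or self.ny < 2:
            raise GridError("grid needs nx >= 2 and ny >= 2 for interpolation use")
        self.dates = _daily_index(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        expect = (len(self.dates), self.ny, self.nx)
        if self.values.shape != expect:
            raise GridError(f"values shape {self.values.shape} != {expect}")
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != expect:
                raise GridError("missing_mask shape mismatch")
        if not np.all(np.isfinite(self.values[~self.missing_mask])):
            raise GridError("non-missing values must be finite")

    # -- geometry ---------------------------------------------------------

    @property
    def x_coords(self) -> np.ndarray:
        return self.origin_x + np.arange(self.nx) * self.dx

    @property
    def y_coords(self) -> np.ndarray:
        return self.origin_y + np.arange(self.ny) * self.dy

    @property
    def n_dates(self) -> int:
        return len(self.dates)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the covered area: centroid hull plus a half cell."""
        return (
            self.origin_x - 0.5 * self.dx,
            self.origin_x + (self.nx - 1) * self.dx + 0.5 * self.dx,
            self.origin_y - 0.5 * self.dy,
            self.origin_y + (self.ny - 1) * self.dy + 0.5 * self.dy,
        )

    def contains(self, x: float, y: float) -> bool:
        xmin, xmax, ymin, ymax = self.extent
        return xmin <= x <= xmax and ymin <= y <= ymax

    def date_offset(self, date) -> int:
        """Offset of ``date`` into the daily axis (may be out of range)."""
        return (pd.Timestamp(date).normalize() - self.dates[0]).days

    def masked_values(self) -> np.ndarray:
        """Values with missing cells replaced by NaN (copy)."""
        out = self.values.copy()
        out[self.missing_mask] = np.nan
        return out


def cell_centroid(grid: ExposureGrid, i: int, j: int) -> tuple[float, float]:
    """Planar coordinates (metres) of the centroid of cell (i, j).

    Raises ``IndexError`` for out-of-range cell indices.
    """
    if not (0 <= i < grid.nx and 0 <= j < grid.ny):
        raise IndexError(f"cell index ({i}, {j}) outside grid {grid.nx} x {grid.ny}")
    return (grid.origin_x + i * grid.dx, grid.origin_y + j * grid.dy)


@dataclass
class MonitorSeries:
    """Daily measurements from one fixed ground monitor."""

    monitor_id: str
    x: float
    y: float
    dates: pd.DatetimeIndex
    values: np.ndarray
    units: str = "ug/m3"

    def __post_init__(self):
        self.dates = pd.DatetimeIndex(pd.to_datetime(self.dates)).normalize()
        if self.dates.has_duplicates:
            raise GridError("monitor dates must be unique")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.dates),):
            raise GridError("monitor values shape mismatch")
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise GridError("monitor coordinates must be finite")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMATS = ("long_csv", "netcdf", "tiff_stack")


def _regular_axis(coords: np.ndarray, what: str) -> tuple[float, float, int, np.ndarray]:
    """Infer (origin, spacing, count, index-per-coord) from observed coordinates.

    All pairwise gaps must be integer multiples of the smallest gap, so a
    fully absent row/column is tolerated but e.g. spacings {1000, 1500} are
    rejected.
    """
    uniq = np.unique(coords)
    if len(uniq) < 2:
        raise IrregularGridError(f"irregular grid: need >= 2 distinct {what} values")
    diffs = np.diff(uniq)
    base = diffs.min()
    if base <= 0:
        raise IrregularGridError(f"irregular grid: non-positive {what} spacing")
    ratio = (uniq - uniq[0]) / base
    if np.any(np.abs(ratio - np.round(ratio)) > 1e-6):
        raise IrregularGridError(f"irregular grid: {what} values are not on a regular lattice")
    n = int(round((uniq[-1] - uniq[0]) / base)) + 1
    idx = np.round((coords - uniq[0]) / base).astype(int)
    return float(uniq[0]), float(base), n, idx


def _read_long_csv(path) -> ExposureGrid:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"date", "easting", "northing", "value"}
    if not required.issubset(df.columns):
        raise GridError(f"long_csv requires columns {sorted(required)}")
    dates_all = pd.to_datetime(df["date"]).dt.normalize()
    axis = _daily_index(np.sort(dates_all.unique()))
    ox, dx, nx, ix = _regular_axis(df["easting"].to_numpy(float), "easting")
    oy, dy, ny, iy = _regular_axis(df["northing"].to_numpy(float), "northing")
    it = ((dates_all - axis[0]).dt.days).to_numpy()
    values = np.full((len(axis), ny, nx), np.nan)
    if df.duplicated(subset=["date", "easting", "northing"]).any():
        raise GridError("long_csv has duplicate (date, easting, northing) rows")
    values[it, iy, ix] = df["value"].to_numpy(float)
    return ExposureGrid(ox, oy, dx, dy, nx, ny, axis, values)


def _write_long_csv(grid: ExposureGrid, path) -> None:
    tt, jj, ii = np.nonzero(~grid.missing_mask)
    df = pd.DataFrame(
        {
            "date": grid.dates[tt].strftime("%Y-%m-%d"),
            "easting": grid.x_coords[ii],
            "northing": grid.y_coords[jj],
            "value": grid.values[tt, jj, ii],
        }
    )
    # %.17g round-trips float64 exactly; pandas' default float path does not
    df.to_csv(path, index=False, float_format="%.17g")


def _read_netcdf(path) -> ExposureGrid:
    import xarray as xr

    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    da = ds["exposure"]
    x = np.asarray(ds["x"].values, float)
    y = np.asarray(ds["y"].values, float)
    ox, dx, nx, _ = _regular_axis(x, "x")
    oy, dy, ny, _ = _regular_axis(y, "y")
    if nx != len(x) or ny != len(y):
        raise IrregularGridError("irregular grid: coordinate variables have gaps")
    axis = _daily_index(ds["time"].values)
    return ExposureGrid(
        ox, oy, dx, dy, nx, ny, axis, np.asarray(da.values, float),
        crs_label=str(ds.attrs.get("crs_label", "unknown")),
        quantity_name=str(ds.attrs.get("quantity_name", "exposure")),
        units=str(ds.attrs.get("units", "")),
    )


def _write_netcdf(grid: ExposureGrid, path) -> None:
    import xarray as xr

    ds = xr.Dataset(
        {"exposure": (("time", "y", "x"), grid.masked_values())},
        coords={"time": grid.dates, "y": grid.y_coords, "x": grid.x_coords},
        attrs={
            "crs_label": grid.crs_label,
            "quantity_name": grid.quantity_name,
            "units": grid.units,
        },
    )
    ds.to_netcdf(path, engine="scipy")


def _read_tiff_stack(path) -> ExposureGrid:
    import tifffile

    root = pathlib.Path(path)
    manifest = json.loads((root / "manifest.json").read_text())
    days = manifest["days"]
    axis = _daily_index([d["date"] for d in days])
    planes = [tifffile.imread(root / d["file"]) for d in days]
    values = np.stack([np.asarray(p, float) for p in planes])
    return ExposureGrid(
        manifest["origin_x"], manifest["origin_y"], manifest["dx"], manifest["dy"],
        manifest["nx"], manifest["ny"], axis, values,
        crs_label=manifest.get("crs_label", "unknown"),
        quantity_name=manifest.get("quantity_name", "exposure"),
        units=manifest.get("units", ""),
    )


def _write_tiff_stack(grid: ExposureGrid, path) -> None:
    import tifffile

    root = pathlib.Path(path)
    root.mkdir(parents=True, exist_ok=True)
    masked = grid.masked_values()
    days = []
    for t, date in enumerate(grid.dates):
        name = f"day{t:05d}.tif"
        tifffile.imwrite(root / name, masked[t])
        days.append({"file": name, "date": date.strftime("%Y-%m-%d")})
    manifest = {
        "origin_x": grid.origin_x, "origin_y": grid.origin_y,
        "dx": grid.dx, "dy": grid.dy, "nx": grid.nx, "ny": grid.ny,
        "crs_label": grid.crs_label, "quantity_name": grid.quantity_name,
        "units": grid.units, "row_order": "y_ascending", "days": days,
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_grid(path, format: str = "long_csv") -> ExposureGrid:
    """Read an :class:`ExposureGrid` from disk.

    ``format`` is one of ``long_csv``, ``netcdf`` or ``tiff_stack``.  The
    file must describe a regular planar grid on a gapless daily time axis;
    violations raise :class:`IrregularGridError` / :class:`TimeAxisError`.
    """
    if format == "long_csv":
        return _read_long_csv(path)
    if format == "netcdf":
        return _read_netcdf(path)
    if format == "tiff_stack":
        return _read_tiff_stack(path)
    raise GridError(f"unknown grid format {format!r}; expected one of {_FORMATS}")


def write_grid(grid: ExposureGrid, path, format: str = "long_csv") -> None:
    """Write an :class:`ExposureGrid`; ``read_grid(write_grid(g))`` round-trips
    values bit-comparably and axes exactly."""
    if format == "long_csv":
        _write_long_csv(grid, path)
    elif format == "netcdf":
        _write_netcdf(grid, path)
    elif format == "tiff_stack":
        _write_tiff_stack(grid, path)
    else:
        raise GridError(f"unknown grid format {format!r}; expected one of {_FORMATS}")


def grids_equal(a: ExposureGrid, b: ExposureGrid) -> bool:
    """Exact equality of geometry, axes, masks and non-missing values."""
    return (
        a.origin_x == b.origin_x and a.origin_y == b.origin_y
        and a.dx == b.dx and a.dy == b.dy and a.nx == b.nx and a.ny == b.ny
        and a.dates.equals(b.dates)
        and np.array_equal(a.missing_mask, b.missing_mask)
        and np.array_equal(a.values[~a.missing_mask], b.values[~b.missing_mask])
    )
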