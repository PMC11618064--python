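"""Seeded generators for exposure grids, monitor networks and cohorts.

The grid generator emulates, at toy scale, the structure of a national
daily air-pollution product (e.g. 1 x 1 km PM2.5 over Great Britain): a
mean level, smooth large-scale spatial trend, a few Gaussian spatial bumps
(urban hot/cold spots), annual seasonality, a spatially-uniform AR(1) day
anomaly (synoptic weather), iid cell-day noise (the gridded product's
measurement error) and an optional static missing-cell mask (sea cells).

The cohort generator produces baseline, event and residence tables that
pass the cohort readers unchanged: residential periods abut under the
closed-interval convention, the last period is open-ended ("Present"),
coordinates are drawn uniformly over the grid and then rounded to a
coarser lattice (default 100 m, mimicking privacy-buffer centroids), and
events are drawn daily with hazard ``baseline * exp(beta * z / 10)`` where
``z`` is the configured backward lag-window mean of the subject's TRUE
exposure — the smooth analytic field evaluated at the exact (pre-rounding)
coordinates, excluding the cell-level noise.  Basing events on the truth
keeps linkage error measurable: the gap between the recovered and the true
log-odds ratio is exactly the misclassification cost of the pipeline.

All generators are fully deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import ExposureGrid
from .linkage import extract_point_series
from .summaries import LagWindow


class SimulationError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# Exposure grid simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSimConfig:
    """Configuration for the synthetic daily exposure grid.

    Units: coordinates and spacings in metres, values in the grid's
    quantity units (ug/m3 by default), trends per metre, temporal
    parameters per day.
    """

    nx: int = 12
    ny: int = 12
    dx: float = 1000.0
    dy: float = 1000.0
    origin_x: float = 500.0
    origin_y: float = 500.0
    start_date: str = "2008-01-01"
    n_days: int = 730
    mean: float = 12.0
    trend_x: float = 2e-4
    trend_y: float = -1e-4
    n_bumps: int = 3
    bump_amplitude: float = 4.0
    bump_scale: float = 3000.0
    seasonal_amplitude: float = 3.0
    seasonal_phase: float = np.pi / 2  # peak near the turn of the year
    ar1_coef: float = 0.8
    ar1_sd: float = 5.0  # innovation sd
    noise_sd: float = 1.5
    missing_fraction: float = 0.0
    seed: int = 0
    crs_label: str = "EPSG:27700"
    quantity_name: str = "PM2.5"
    units: str = "ug/m3"

    def __post_init__(self):
        if not -1.0 < self.ar1_coef < 1.0:
            raise SimulationError("AR(1) coefficient must lie in (-1, 1)")
        if min(self.ar1_sd, self.noise_sd, self.bump_scale) < 0:
            raise SimulationError("scale parameters must be non-negative")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise SimulationError("missing_fraction must be in [0, 1)")


class GridSimulation:
    """Realised synthetic grid model: holds the drawn bumps, day anomaly,
    noise and mask, and can evaluate the smooth field at arbitrary points."""

    def __init__(self, config: GridSimConfig):
        self.config = c = config
        self.dates = pd.date_range(c.start_date, periods=c.n_days, freq="D")
        rng = np.random.default_rng(c.seed)
        xmin = c.origin_x
        xmax = c.origin_x + (c.nx - 1) * c.dx
        ymin = c.origin_y
        ymax = c.origin_y + (c.ny - 1) * c.dy
        self.bump_x = rng.uniform(xmin, xmax, c.n_bumps)
        self.bump_y = rng.uniform(ymin, ymax, c.n_bumps)
        self.bump_amp = c.bump_amplitude * rng.uniform(-1.0, 1.0, c.n_bumps)
        # spatially-uniform AR(1) day anomaly, started at its stationary law
        self.anomaly = np.zeros(c.n_days)
        if c.ar1_sd > 0:
            stat_sd = c.ar1_sd / np.sqrt(1.0 - c.ar1_coef**2)
            self.anomaly[0] = rng.normal(0.0, stat_sd)
            innov = rng.normal(0.0, c.ar1_sd, c.n_days - 1)
            for t in range(1, c.n_days):
                self.anomaly[t] = c.ar1_coef * self.anomaly[t - 1] + innov[t - 1]
        doy = self.dates.dayofyear.to_numpy()
        self.seasonal = c.seasonal_amplitude * np.sin(
            2 * np.pi * doy / 365.25 + c.seasonal_phase
        )
        self.cell_missing = rng.random((c.ny, c.nx)) < c.missing_fraction
        self._noise_rng_state = rng  # consumed once, in grid()
        self._grid: ExposureGrid | None = None

    # -- analytic (noise-free) field -------------------------------------

    def spatial_surface(self, x, y) -> np.ndarray:
        """Time-constant part of the field at point(s) (x, y)."""
        c = self.config
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        out = c.mean + c.trend_x * (x - c.origin_x) + c.trend_y * (y - c.origin_y)
        for bx, by, amp in zip(self.bump_x, self.bump_y, self.bump_amp):
            out = out + amp * np.exp(
                -((x - bx) ** 2 + (y - by) ** 2) / (2 * c.bump_scale**2)
            )
        return out

    def true_point_series(self, x: float, y: float) -> np.ndarray:
        """Smooth field value at an exact point for every grid date
        (trend + bumps + seasonality + day anomaly; no cell noise)."""
        return float(self.spatial_surface(x, y)) + self.seasonal + self.anomaly

    # -- realised grid ----------------------------------------------------

    def grid(self) -> ExposureGrid:
        """The realised (noisy, masked) exposure grid; built once, cached."""
        if self._grid is None:
            c = self.config
            xs = c.origin_x + np.arange(c.nx) * c.dx
            ys = c.origin_y + np.arange(c.ny) * c.dy
            xx, yy = np.meshgrid(xs, ys)  # (ny, nx)
            surface = self.spatial_surface(xx, yy)
            values = (
                surface[None, :, :]
                + (self.seasonal + self.anomaly)[:, None, None]
            )
            if c.noise_sd > 0:
                values = values + self._noise_rng_state.normal(
                    0.0, c.noise_sd, values.shape
                )
            mask = np.broadcast_to(self.cell_missing, values.shape).copy()
            values = values.copy()
            values[mask] = np.nan
            self._grid = ExposureGrid(
                c.origin_x, c.origin_y, c.dx, c.dy, c.nx, c.ny, self.dates,
                values, mask, crs_label=c.crs_label,
                quantity_name=c.quantity_name, units=c.units,
            )
        return self._grid


def simulate_grid(config: GridSimConfig) -> ExposureGrid:
    """Simulate a synthetic daily exposure grid (deterministic given the seed)."""
    return GridSimulation(config).grid()


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OutcomeModel:
    """Daily event model: hazard = baseline_rate * exp(beta_per_10 * z / 10)
    with z the backward lag-window mean of the true exposure.  ``kind`` is
    "null" (no exposure dependence), "short_term" or "long_term" (the two
    differ only in their default lag window)."""

    kind: str = "null"
    beta_per_10: float = 0.0
    baseline_rate: float = 5e-4
    window: LagWindow = LagWindow(0, 3)
    icd_code: str = "J45"

    def __post_init__(self):
        if self.kind not in ("null", "short_term", "long_term"):
            raise SimulationError(f"unknown outcome model kind {self.kind!r}")
        if self.baseline_rate < 0:
            raise SimulationError("baseline_rate must be non-negative")


@dataclass(frozen=True)
class CohortSimConfig:
    """Configuration for the synthetic cohort.

    Coordinates are drawn uniformly over the grid's centroid hull and then
    rounded to ``coordinate_rounding`` metres (100 m by default, mimicking
    privacy-buffer centroids); the pre-rounding coordinates drive the event
    model.  Residential histories start at the grid's first day, moves
    arrive with a Poisson(``moves_rate``) count per subject at uniform
    times, periods abut, and the last period is open-ended.
    """

    n_subjects: int = 200
    enrolment_start: str | None = None  # default: grid start + outcome lag guard
    enrolment_end: str | None = None
    followup_min_days: int = 365
    followup_max_days: int = 3650
    moves_rate: float = 1.0
    coordinate_rounding: float = 100.0
    birth_year_min: int = 1940
    birth_year_max: int = 1970
    outcome: OutcomeModel = OutcomeModel()
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise SimulationError("n_subjects must be positive")
        if self.moves_rate < 0:
            raise SimulationError("moves_rate must be non-negative")
        if self.coordinate_rounding <= 0:
            raise SimulationError("coordinate_rounding must be positive")
        if self.followup_min_days > self.followup_max_days:
            raise SimulationError("followup_min_days > followup_max_days")


@dataclass
class SimulatedCohort:
    """Cohort tables (CSV-schema DataFrames) plus the simulation truth."""

    subjects: pd.DataFrame
    events: pd.DataFrame
    residences: pd.DataFrame
    exact_coordinates: pd.DataFrame  # location_id, easting, northing (pre-rounding)

    def frames(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        return self.subjects, self.events, self.residences


def _rolling_lag_mean(values: np.ndarray, window: LagWindow) -> np.ndarray:
    """z[t] = mean of values[t - max_lag .. t - min_lag]; NaN where the
    window reaches before the series start."""
    L = window.length
    cs = np.concatenate([[0.0], np.cumsum(values)])
    n = len(values)
    out = np.full(n, np.nan)
    t = np.arange(n)
    lo = t - window.max_lag
    hi = t - window.min_lag
    valid = lo >= 0
    out[valid] = (cs[hi[valid] + 1] - cs[lo[valid]]) / L
    return out


def simulate_cohort(
    config: CohortSimConfig, source: "ExposureGrid | GridSimulation"
) -> SimulatedCohort:
    """Simulate baseline, event and residence tables on top of a grid.

    ``source`` is the :class:`GridSimulation` model (the smooth analytic
    field defines the true exposure at exact coordinates) or a realised
    :class:`ExposureGrid` (bilinear interpolation at the exact coordinates
    then serves as the operative truth).  The returned tables pass the
    cohort readers unchanged.
    """
    if isinstance(source, GridSimulation):
        model, grid = source, source.grid()
    else:
        model, grid = None, source

    c = config
    rng = np.random.default_rng(c.seed)
    grid_start, grid_end = grid.dates[0], grid.dates[-1]
    n_grid_days = grid.n_dates
    guard = c.outcome.window.max_lag + 1
    e0 = (
        pd.Timestamp(c.enrolment_start)
        if c.enrolment_start is not None
        else grid_start + pd.Timedelta(days=guard)
    )
    e1 = (
        pd.Timestamp(c.enrolment_end)
        if c.enrolment_end is not None
        else max(e0, grid_end - pd.Timedelta(days=c.followup_min_days))
    )
    if not grid_start <= e0 <= e1 <= grid_end:
        raise SimulationError("enrolment window must lie within the grid's date range")

    xmin, xmax = grid.x_coords[0], grid.x_coords[-1]
    ymin, ymax = grid.y_coords[0], grid.y_coords[-1]

    def true_series(x: float, y: float) -> np.ndarray:
        if model is not None:
            return model.true_point_series(x, y)
        return extract_point_series(grid, x, y, method="bilinear").values

    subj_rows, event_rows, res_rows, exact_rows = [], [], [], []
    for s in range(c.n_subjects):
        sid = f"S{s + 1:04d}"
        birth_year = int(rng.integers(c.birth_year_min, c.birth_year_max + 1))
        birth = pd.Timestamp(year=birth_year, month=1, day=1) + pd.Timedelta(
            days=int(rng.integers(0, 365))
        )
        enrol_off = int(rng.integers(0, (e1 - e0).days + 1))
        enrol = e0 + pd.Timedelta(days=enrol_off)
        dur = int(rng.integers(c.followup_min_days, c.followup_max_days + 1))
        followup_end = min(enrol + pd.Timedelta(days=dur), grid_end)

        # residences: abutting periods from the grid start; last one OPEN
        n_moves = int(rng.poisson(c.moves_rate))
        span = (followup_end - grid_start).days
        move_offsets = np.sort(
            rng.choice(np.arange(1, max(span, 2)), size=min(n_moves, max(span - 1, 0)),
                       replace=False)
        )
        starts = [grid_start] + [grid_start + pd.Timedelta(days=int(o)) for o in move_offsets]
        true_vals = np.full(n_grid_days, np.nan)
        for p, pstart in enumerate(starts):
            pend_closed = (
                starts[p + 1] - pd.Timedelta(days=1) if p + 1 < len(starts) else None
            )
            loc_id = f"L{s + 1:04d}_{p + 1}"
            ex = float(rng.uniform(xmin, xmax))
            ey = float(rng.uniform(ymin, ymax))
            r = c.coordinate_rounding
            rx = float(np.clip(np.round(ex / r) * r, xmin, xmax))
            ry = float(np.clip(np.round(ey / r) * r, ymin, ymax))
            res_rows.append(
                {
                    "subject_id": sid,
                    "location_id": loc_id,
                    "start_date": pstart.strftime("%Y-%m-%d"),
                    "end_date": (
                        pend_closed.strftime("%Y-%m-%d") if pend_closed is not None else "Present"
                    ),
                    "easting": rx,
                    "northing": ry,
                }
            )
            exact_rows.append({"location_id": loc_id, "easting": ex, "northing": ey})
            i0 = (pstart - grid_start).days
            i1 = (pend_closed - grid_start).days if pend_closed is not None else n_grid_days - 1
            i1 = min(i1, n_grid_days - 1)
            if i0 <= i1:
                true_vals[i0 : i1 + 1] = true_series(ex, ey)[i0 : i1 + 1]

        subj_rows.append(
            {
                "subject_id": sid,
                "enrolment_date": enrol.strftime("%Y-%m-%d"),
                "last_followup_date": followup_end.strftime("%Y-%m-%d"),
                "birth_date": birth.strftime("%Y-%m-%d"),
            }
        )

        # daily event draws over [enrolment, follow-up end]
        t0 = (enrol - grid_start).days
        t1 = (followup_end - grid_start).days
        if c.outcome.kind == "null" or c.outcome.beta_per_10 == 0.0:
            p_day = np.full(t1 - t0 + 1, c.outcome.baseline_rate)
        else:
            z = _rolling_lag_mean(true_vals, c.outcome.window)[t0 : t1 + 1]
            p_day = c.outcome.baseline_rate * np.exp(
                c.outcome.beta_per_10 * np.nan_to_num(z) / 10.0
            )
        p_day = np.clip(p_day, 0.0, 1.0)
        hits = np.nonzero(rng.random(len(p_day)) < p_day)[0]
        for h in hits:
            event_rows.append(
                {
                    "subject_id": sid,
                    "icd_code": c.outcome.icd_code,
                    "event_date": (grid_start + pd.Timedelta(days=int(t0 + h))).strftime(
                        "%Y-%m-%d"
                    ),
                }
            )

    subjects = pd.DataFrame(
        subj_rows, columns=["subject_id", "enrolment_date", "last_followup_date", "birth_date"]
    )
    events = pd.DataFrame(event_rows, columns=["subject_id", "icd_code", "event_date"])
    residences = pd.DataFrame(
        res_rows,
        columns=["subject_id", "location_id", "start_date", "end_date", "easting", "northing"],
    )
    exact = pd.DataFrame(exact_rows, columns=["location_id", "easting", "northing"])
    return SimulatedCohort(subjects, events, residences, exact)


# ---------------------------------------------------------------------------
# Worked pseudo-data fixture
# ---------------------------------------------------------------------------


def table1_fixture() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """The three-subject worked pseudo-cohort (3 subjects, 7 events,
    6 residential periods), transcribed to the package's ISO-date CSV
    dialect with open-ended entries kept as "Present"."""
    subjects = pd.DataFrame(
        [
            {"subject_id": "1", "enrolment_date": "2007-05-01", "last_followup_date": "2017-03-12"},
            {"subject_id": "2", "enrolment_date": "2009-04-14", "last_followup_date": "2019-09-25"},
            {"subject_id": "3", "enrolment_date": "2006-11-23", "last_followup_date": "Present"},
        ]
    )
    events = pd.DataFrame(
        [
            {"subject_id": "1", "icd_code": "E11", "event_date": "2012-04-23"},
            {"subject_id": "1", "icd_code": "I20", "event_date": "2013-07-04"},
            {"subject_id": "1", "icd_code": "I21", "event_date": "2016-09-30"},
            {"subject_id": "2", "icd_code": "C34", "event_date": "2010-02-24"},
            {"subject_id": "3", "icd_code": "J40", "event_date": "2007-03-14"},
            {"subject_id": "3", "icd_code": "J41", "event_date": "2008-04-11"},
            {"subject_id": "3", "icd_code": "J43", "event_date": "2009-05-22"},
        ]
    )
    residences = pd.DataFrame(
        [
            {"subject_id": "1", "location_id": "Loc_12", "start_date": "2005-04-01",
             "end_date": "2012-05-22", "easting": 515200, "northing": 184800},
            {"subject_id": "1", "location_id": "Loc_43", "start_date": "2012-05-23",
             "end_date": "2017-03-12", "easting": 384800, "northing": 394100},
            {"subject_id": "2", "location_id": "Loc_92", "start_date": "2007-12-18",
             "end_date": "2009-09-03", "easting": 342700, "northing": 387100},
            {"subject_id": "2", "location_id": "Loc_6", "start_date": "2009-09-04",
             "end_date": "2017-04-03", "easting": 528100, "northing": 105600},
            {"subject_id": "2", "location_id": "Loc_24", "start_date": "2017-04-04",
             "end_date": "2019-09-25", "easting": 459900, "northing": 450700},
            {"subject_id": "3", "location_id": "Loc_87", "start_date": "1994-11-20",
             "end_date": "Present", "easting": 177500, "northing": 314500},
        ]
    )
    return subjects, events, residences


def write_cohort_tables(frames, out_dir) -> dict[str, str]:
    """Write (subjects, events, residences) DataFrames as the three CSVs."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = ("subjects.csv", "events.csv", "residences.csv")
    paths = {}
    for frame, name in zip(frames, names):
        p = out / name
        frame.to_csv(p, index=False)
        paths[name.split(".")[0]] = str(p)
    return paths
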