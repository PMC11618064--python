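"""Step 2 — reconstruction of individual-level daily exposure series.

Each subject's series is assembled by concatenating blocks of the
address-level series produced by Step 1, according to the residential
periods: every day inside a period takes that period's location value for
that date.  The resulting axis is contiguous from the first to the last
covered day, even across gaps; each day carries a provenance flag:

``ok``
    day covered by a residence with an available exposure value;
``no_residence``
    day in a gap of the residential history;
``exposure_unavailable``
    day covered by a residence but outside the exposure product's temporal
    coverage, or falling on a missing grid value (e.g. a residence predating
    the mapped period).

The end date of a period belongs to the old address and the following day
to the new one (closed-interval convention).  Gap days are never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import ResidentialHistory
from .linkage import LocationSeries

FLAG_OK = "ok"
FLAG_NO_RESIDENCE = "no_residence"
FLAG_UNAVAILABLE = "exposure_unavailable"


class UnlinkedLocationError(KeyError):
    """A residential period's location has no extracted exposure series."""


@dataclass
class SubjectExposureSeries:
    """Stitched daily exposure series for one subject with per-day provenance."""

    subject_id: str
    start: pd.Timestamp
    values: np.ndarray
    source_location_id: np.ndarray  # object array, None on gap days
    flag: np.ndarray  # one of the FLAG_* strings per day
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.source_location_id = np.asarray(self.source_location_id, dtype=object)
        self.flag = np.asarray(self.flag, dtype=object)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=len(self.values), freq="D")

    @property
    def end(self) -> pd.Timestamp:
        return self.start + pd.Timedelta(days=len(self.values) - 1)

    def offset(self, date) -> int:
        """Day offset of ``date`` into the axis (may fall outside)."""
        return (pd.Timestamp(date).normalize() - self.start).days

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "date": self.dates.strftime("%Y-%m-%d"),
                "value": self.values,
                "source_location_id": [s if s is not None else "" for s in self.source_location_id],
                "flag": self.flag,
            }
        )


def series_from_frame(df: pd.DataFrame) -> dict[str, SubjectExposureSeries]:
    """Rebuild per-subject series from the long-table serialisation."""
    out: dict[str, SubjectExposureSeries] = {}
    for sid, g in df.groupby("subject_id", sort=True):
        g = g.sort_values("date")
        dates = pd.DatetimeIndex(pd.to_datetime(g["date"]))
        src = np.array(
            [s if isinstance(s, str) and s != "" else None for s in g["source_location_id"]],
            dtype=object,
        )
        out[str(sid)] = SubjectExposureSeries(
            str(sid), dates[0], g["value"].to_numpy(float), src,
            g["flag"].to_numpy(object),
        )
    return out


def assemble_subject_series(
    history: ResidentialHistory,
    location_series: Mapping[str, LocationSeries],
    clip_to: tuple | None = None,
) -> SubjectExposureSeries:
    """Assemble one subject's daily exposure series from location blocks.

    ``clip_to`` optionally restricts the axis to a (start, end) range, e.g.
    [enrolment, last follow-up]; the axis is the intersection of that range
    with the history's coverage span.  An empty intersection yields a
    zero-length series carrying a warning rather than an error.
    """
    for p in history.periods:
        if p.location_id not in location_series:
            raise UnlinkedLocationError(
                f"unlinked location: {p.location_id} (subject {history.subject_id})"
            )

    start, end = history.start_date, history.end_date
    if clip_to is not None:
        c0, c1 = (pd.Timestamp(clip_to[0]).normalize(), pd.Timestamp(clip_to[1]).normalize())
        start, end = max(start, c0), min(end, c1)
    if start > end:
        return SubjectExposureSeries(
            history.subject_id, pd.Timestamp(history.start_date),
            np.empty(0), np.empty(0, object), np.empty(0, object),
            warnings=["empty series: history and requested range do not intersect"],
        )

    n = (end - start).days + 1
    values = np.full(n, np.nan)
    src = np.full(n, None, dtype=object)
    flag = np.full(n, FLAG_NO_RESIDENCE, dtype=object)
    warnings: list[str] = []

    for p in history.periods:
        ps, pe = max(p.start_date, start), min(p.end_date, end)
        if ps > pe:
            continue
        i0 = (ps - start).days
        i1 = (pe - start).days
        src[i0 : i1 + 1] = p.location_id
        flag[i0 : i1 + 1] = FLAG_UNAVAILABLE
        ls = location_series[p.location_id]
        os_, oe = max(ps, ls.start), min(pe, ls.end)
        if os_ > oe:
            continue
        j0 = (os_ - ls.start).days
        m = (oe - os_).days + 1
        k0 = (os_ - start).days
        seg = ls.values[j0 : j0 + m]
        miss = ls.missing[j0 : j0 + m]
        values[k0 : k0 + m] = np.where(miss, np.nan, seg)
        flag[k0 : k0 + m] = np.where(miss, FLAG_UNAVAILABLE, FLAG_OK)

    non_gap = flag == FLAG_OK
    if not non_gap.any():
        warnings.append("empty series: no exposure values available over the axis")
    return SubjectExposureSeries(history.subject_id, start, values, src, flag, warnings)


def clip_series(series: SubjectExposureSeries, start, end) -> SubjectExposureSeries:
    """Restrict a subject series to the intersection of its axis with [start, end]."""
    s = max(series.start, pd.Timestamp(start).normalize())
    e = min(series.end, pd.Timestamp(end).normalize())
    if len(series) == 0 or s > e:
        return SubjectExposureSeries(
            series.subject_id, series.start, np.empty(0), np.empty(0, object),
            np.empty(0, object), warnings=["empty series: clip range does not intersect axis"],
        )
    i0, i1 = series.offset(s), series.offset(e)
    return SubjectExposureSeries(
        series.subject_id, s, series.values[i0 : i1 + 1].copy(),
        series.source_location_id[i0 : i1 + 1].copy(), series.flag[i0 : i1 + 1].copy(),
        list(series.warnings),
    )


def series_completeness(series: SubjectExposureSeries, window: tuple) -> float:
    """Fraction of days in [window start, window end] that carry an available
    exposure value (flag ``ok``); days outside the series axis count as
    unavailable."""
    w0 = pd.Timestamp(window[0]).normalize()
    w1 = pd.Timestamp(window[1]).normalize()
    if w0 > w1:
        raise ValueError("window must be non-empty")
    n_days = (w1 - w0).days + 1
    if len(series) == 0:
        return 0.0
    s, e = max(series.start, w0), min(series.end, w1)
    if s > e:
        return 0.0
    i0, i1 = series.offset(s), series.offset(e)
    n_ok = int(np.sum(series.flag[i0 : i1 + 1] == FLAG_OK))
    return n_ok / n_days
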