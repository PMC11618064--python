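"""Step 3 — design-specific exposure summaries.

Given the stitched per-subject daily series, this module derives the
exposure quantities that epidemiological designs actually consume:

* backward *lag-window* aggregates (e.g. the lag 0-364 annual mean for
  long-term analyses, or the lag 0-3 mean for short-term ones);
* *risk sets* for Cox proportional-hazards analyses: for each case event,
  the case plus controls still at risk at the same point on the chosen
  time axis (age in days, or time on study), each summarised backward from
  their own member-specific calendar index date;
* *time-stratified case-crossover sets*: within-subject designs whose
  control days share calendar year, month and day-of-week with the event
  day;
* *distributed-lag matrices*: one aggregate per lag stratum (daily,
  monthly or yearly strata), feeding distributed lag models.

Every summary reads strictly backward: lag k means k days before the index
date, and no day after the index date is ever touched.  Missingness is a
value-level outcome: each summary carries a completeness fraction, and the
value is withheld (NaN) when completeness falls below the window's
``min_completeness`` threshold (default 1.0, i.e. fully observed windows
only; with a lower threshold the mean is taken over the available days).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import HealthEvent, SubjectRecord
from .history import FLAG_OK, SubjectExposureSeries

ONE_DAY = pd.Timedelta(days=1)


class SummaryError(ValueError):
    """Configuration error in summary construction."""


# ---------------------------------------------------------------------------
# Lag windows and strata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LagWindow:
    """Backward exposure window: days index_date - lag for lag in [min_lag, max_lag]."""

    min_lag: int = 0
    max_lag: int = 0
    aggregation: str = "mean"
    min_completeness: float = 1.0

    def __post_init__(self):
        if not (0 <= self.min_lag <= self.max_lag):
            raise SummaryError("lag window requires 0 <= min_lag <= max_lag")
        if self.aggregation not in ("mean", "sum"):
            raise SummaryError(f"unknown aggregation {self.aggregation!r}")
        if not 0.0 <= self.min_completeness <= 1.0:
            raise SummaryError("min_completeness must be in [0, 1]")

    @property
    def length(self) -> int:
        return self.max_lag - self.min_lag + 1


@dataclass(frozen=True)
class LagStrata:
    """Contiguous, non-overlapping strata of lag days covering [min_lag, max_lag]."""

    bounds: tuple[tuple[int, int], ...]
    aggregation: str = "mean"
    min_completeness: float = 1.0

    def __post_init__(self):
        if not self.bounds:
            raise SummaryError("strata must be non-empty")
        for (lo, hi) in self.bounds:
            if not 0 <= lo <= hi:
                raise SummaryError(f"invalid stratum ({lo}, {hi})")
        for (_, hi), (lo2, _) in zip(self.bounds, self.bounds[1:]):
            if lo2 != hi + 1:
                raise SummaryError("strata must be contiguous and non-overlapping")

    @classmethod
    def daily(cls, min_lag: int, max_lag: int, **kw) -> "LagStrata":
        return cls(tuple((k, k) for k in range(min_lag, max_lag + 1)), **kw)

    @classmethod
    def from_widths(cls, min_lag: int, widths: Sequence[int], **kw) -> "LagStrata":
        bounds, lo = [], min_lag
        for w in widths:
            bounds.append((lo, lo + w - 1))
            lo += w
        return cls(tuple(bounds), **kw)

    @classmethod
    def monthly(cls, n_strata: int, min_lag: int = 0, width: int = 30, **kw) -> "LagStrata":
        """30-day lag strata by convention (calendar months have no fixed width)."""
        return cls.from_widths(min_lag, [width] * n_strata, **kw)

    @classmethod
    def yearly(cls, n_strata: int, min_lag: int = 0, **kw) -> "LagStrata":
        """365-day lag strata: [0-364], [365-729], ..."""
        return cls.from_widths(min_lag, [365] * n_strata, **kw)

    def windows(self) -> list[LagWindow]:
        return [
            LagWindow(lo, hi, self.aggregation, self.min_completeness)
            for (lo, hi) in self.bounds
        ]


def lag_window_summary(
    series: SubjectExposureSeries, index_date, window: LagWindow
) -> tuple[float, float]:
    """Aggregate a subject's exposure over a backward lag window.

    Returns ``(value, completeness)``: completeness is the fraction of the
    window's days that carry an available value; value is NaN when
    completeness falls below ``window.min_completeness`` (otherwise the
    aggregation runs over the available days).
    """
    idx = pd.Timestamp(index_date).normalize()
    L = window.length
    first = idx - pd.Timedelta(days=window.max_lag)
    if len(series) == 0:
        return (np.nan, 0.0)
    i0 = series.offset(first)
    lo, hi = max(i0, 0), min(i0 + L, len(series))
    n_avail = 0
    agg_vals = None
    if hi > lo:
        seg = series.values[lo:hi]
        ok = (series.flag[lo:hi] == FLAG_OK) & np.isfinite(seg)
        n_avail = int(ok.sum())
        agg_vals = seg[ok]
    completeness = n_avail / L
    if n_avail == 0 or completeness < window.min_completeness - 1e-12:
        return (np.nan, completeness)
    value = float(agg_vals.sum()) if window.aggregation == "sum" else float(agg_vals.mean())
    return (value, completeness)


def distributed_lag_matrix(
    series: SubjectExposureSeries, index_date, strata: LagStrata
) -> tuple[np.ndarray, np.ndarray]:
    """One backward aggregate per lag stratum.

    Returns ``(values, completeness)`` arrays, one entry per stratum;
    width-1 (daily) strata return the raw lagged values.
    """
    vals, comps = [], []
    for w in strata.windows():
        v, c = lag_window_summary(series, index_date, w)
        vals.append(v)
        comps.append(c)
    return np.asarray(vals), np.asarray(comps)


# ---------------------------------------------------------------------------
# Event selection
# ---------------------------------------------------------------------------


def matches_outcome(icd_code: str, outcome_codes: Iterable[str]) -> bool:
    """ICD-10 prefix match: 'C34' matches 'C34', 'C34.1', 'C341'."""
    return any(icd_code.startswith(code) for code in outcome_codes)


def select_case_events(
    events: Iterable[HealthEvent],
    outcome_codes: Iterable[str],
    first_occurrence_only: bool = True,
) -> list[HealthEvent]:
    """Events matching the outcome codes; by default only each subject's
    earliest matching event (first-occurrence analysis)."""
    matching = sorted(
        (e for e in events if matches_outcome(e.icd_code, outcome_codes)),
        key=lambda e: (e.event_date, e.subject_id, e.icd_code),
    )
    if not first_occurrence_only:
        return matching
    seen: set[str] = set()
    out = []
    for e in matching:
        if e.subject_id not in seen:
            seen.add(e.subject_id)
            out.append(e)
    return out


def _first_outcome_date(
    events: Iterable[HealthEvent], outcome_codes: Iterable[str]
) -> dict[str, pd.Timestamp]:
    first: dict[str, pd.Timestamp] = {}
    for e in events:
        if matches_outcome(e.icd_code, outcome_codes):
            if e.subject_id not in first or e.event_date < first[e.subject_id]:
                first[e.subject_id] = e.event_date
    return first


# ---------------------------------------------------------------------------
# Cox risk sets (incidence-density sampling)
# ---------------------------------------------------------------------------


@dataclass
class RiskSetMember:
    subject_id: str
    index_date: pd.Timestamp
    is_case: bool
    exposure: float
    completeness: float


@dataclass
class RiskSet:
    """Case plus controls at risk at the case's index time on the chosen axis."""

    event: HealthEvent
    time_axis: str
    index_time_days: int
    members: list[RiskSetMember]
    warnings: list[str] = field(default_factory=list)

    @property
    def case(self) -> RiskSetMember:
        return next(m for m in self.members if m.is_case)

    @property
    def controls(self) -> list[RiskSetMember]:
        return [m for m in self.members if not m.is_case]


def _axis_origin(rec: SubjectRecord, time_axis: str) -> pd.Timestamp:
    if time_axis == "age":
        if rec.birth_date is None:
            raise SummaryError(
                f"age axis requires a birth date for subject {rec.subject_id}"
            )
        return rec.birth_date
    if time_axis == "time_on_study":
        return rec.enrolment_date
    raise SummaryError(f"unknown time axis {time_axis!r}")


def eligible_controls(
    case: HealthEvent,
    index_time_days: int,
    subjects: Mapping[str, SubjectRecord],
    first_outcome: Mapping[str, pd.Timestamp],
    time_axis: str,
    caliper_days: int = 0,
) -> list[tuple[str, pd.Timestamp]]:
    """Subjects at risk when they reach the case's index time.

    A subject is eligible when the calendar date at which they attain the
    case's time-axis value (clamped into their follow-up by at most
    ``caliper_days``) lies within their follow-up, and they are event-free
    for the outcome up to that date.  Returns (subject_id, index_date)
    pairs, sorted by subject id; the case subject is excluded.
    """
    out: list[tuple[str, pd.Timestamp]] = []
    for sid in sorted(subjects):
        if sid == case.subject_id:
            continue
        rec = subjects[sid]
        origin = _axis_origin(rec, time_axis)
        idx_date = origin + pd.Timedelta(days=index_time_days)
        lo, hi = rec.enrolment_date, rec.last_followup_date
        clamped = min(max(idx_date, lo), hi)
        if abs((clamped - idx_date).days) > caliper_days:
            continue
        ev = first_outcome.get(sid)
        if ev is not None and ev <= clamped:
            continue
        out.append((sid, clamped))
    return out


def build_risk_sets(
    subjects: Mapping[str, SubjectRecord],
    events: Iterable[HealthEvent],
    series_map: Mapping[str, SubjectExposureSeries],
    outcome_codes: Iterable[str],
    time_axis: str = "age",
    window: LagWindow = LagWindow(0, 364),
    n_controls: int | str = "all",
    seed: int = 0,
    caliper_days: int = 0,
) -> list[RiskSet]:
    """Incidence-density risk sets for a Cox analysis, one per case event.

    For each first-occurrence case, controls are subjects under follow-up
    and event-free at the case's index time on ``time_axis`` ("age" or
    "time_on_study"); each control's index date is the calendar date at
    which they reach that time, and exposure summaries are computed backward
    from each member's own index date.  ``n_controls`` is an integer (sampled
    without replacement, seeded) or "all".  A set with zero eligible
    controls is emitted with a warning, not dropped.
    """
    outcome_codes = list(outcome_codes)
    cases = select_case_events(events, outcome_codes, first_occurrence_only=True)
    first_outcome = _first_outcome_date(events, outcome_codes)
    rng = np.random.default_rng(seed)
    out: list[RiskSet] = []
    for case in cases:
        rec = subjects.get(case.subject_id)
        if rec is None:
            raise SummaryError(f"case subject {case.subject_id} not in baseline table")
        origin = _axis_origin(rec, time_axis)
        index_time = (case.event_date - origin).days
        pool = eligible_controls(
            case, index_time, subjects, first_outcome, time_axis, caliper_days
        )
        if n_controls != "all":
            m = int(n_controls)
            if m < len(pool):
                keep = rng.choice(len(pool), size=m, replace=False)
                pool = [pool[i] for i in sorted(keep)]
        empty = SubjectExposureSeries(
            "", case.event_date, np.empty(0), np.empty(0, object), np.empty(0, object)
        )
        members = []
        v, c = lag_window_summary(
            series_map.get(case.subject_id, empty), case.event_date, window
        )
        members.append(RiskSetMember(case.subject_id, case.event_date, True, v, c))
        for sid, idx_date in pool:
            v, c = lag_window_summary(series_map.get(sid, empty), idx_date, window)
            members.append(RiskSetMember(sid, idx_date, False, v, c))
        warnings = [] if pool else ["risk set has zero eligible controls"]
        out.append(RiskSet(case, time_axis, index_time, members, warnings))
    return out


# ---------------------------------------------------------------------------
# Time-stratified case-crossover
# ---------------------------------------------------------------------------


def casecrossover_controls(case_date) -> list[pd.Timestamp]:
    """Control days for the time-stratified scheme: all days in the case's
    calendar year-month sharing its day-of-week, excluding the case day;
    sorted ascending (always 3 or 4 controls)."""
    d = pd.Timestamp(case_date).normalize()
    month_start = d.replace(day=1)
    first_match = month_start + pd.Timedelta(days=(d.dayofweek - month_start.dayofweek) % 7)
    controls = []
    cur = first_match
    while cur.month == d.month:
        if cur != d:
            controls.append(cur)
        cur += pd.Timedelta(days=7)
    return controls


@dataclass
class CaseCrossoverSet:
    """One event's case day plus its weekday-in-month matched control days."""

    subject_id: str
    icd_code: str
    case_date: pd.Timestamp
    control_dates: list[pd.Timestamp]
    exposures: dict  # date -> (value, completeness)
    case_missing: bool = False

    @property
    def all_dates(self) -> list[pd.Timestamp]:
        return sorted([self.case_date] + self.control_dates)


def build_casecrossover_sets(
    events: Iterable[HealthEvent],
    series_map: Mapping[str, SubjectExposureSeries],
    outcome_codes: Iterable[str],
    window: LagWindow = LagWindow(0, 3),
    first_occurrence_only: bool = True,
) -> list[CaseCrossoverSet]:
    """One time-stratified case-crossover set per qualifying event, with a
    backward lag-window summary at the case day and at each control day.
    Sets whose case summary is missing are emitted flagged, not dropped."""
    out: list[CaseCrossoverSet] = []
    for ev in select_case_events(events, outcome_codes, first_occurrence_only):
        series = series_map.get(ev.subject_id)
        if series is None:
            series = SubjectExposureSeries(
                ev.subject_id, ev.event_date, np.empty(0), np.empty(0, object),
                np.empty(0, object),
            )
        controls = casecrossover_controls(ev.event_date)
        exposures = {}
        for d in [ev.event_date] + controls:
            exposures[d] = lag_window_summary(series, d, window)
        case_missing = not np.isfinite(exposures[ev.event_date][0])
        out.append(
            CaseCrossoverSet(
                ev.subject_id, ev.icd_code, ev.event_date, controls, exposures,
                case_missing,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Long-table serialisations (analysis-ready outputs)
# ---------------------------------------------------------------------------


def risk_sets_to_frame(risk_sets: list[RiskSet]) -> pd.DataFrame:
    rows = []
    for k, rs in enumerate(risk_sets):
        for m in rs.members:
            rows.append(
                {
                    "set_id": k,
                    "subject_id": m.subject_id,
                    "case_flag": int(m.is_case),
                    "index_date": m.index_date.strftime("%Y-%m-%d"),
                    "exposure": m.exposure,
                    "completeness": m.completeness,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["set_id", "subject_id", "case_flag", "index_date", "exposure", "completeness"],
    )


def casecrossover_sets_to_frame(sets: list[CaseCrossoverSet]) -> pd.DataFrame:
    rows = []
    for k, cc in enumerate(sets):
        for d in cc.all_dates:
            v, c = cc.exposures[d]
            rows.append(
                {
                    "set_id": k,
                    "subject_id": cc.subject_id,
                    "date": d.strftime("%Y-%m-%d"),
                    "case_flag": int(d == cc.case_date),
                    "exposure": v,
                    "completeness": c,
                }
            )
    return pd.DataFrame(
        rows, columns=["set_id", "subject_id", "date", "case_flag", "exposure", "completeness"]
    )


def dlm_to_frame(
    events: Iterable[HealthEvent],
    series_map: Mapping[str, SubjectExposureSeries],
    outcome_codes: Iterable[str],
    strata: LagStrata,
    first_occurrence_only: bool = True,
) -> pd.DataFrame:
    """Distributed-lag design matrix: one row per qualifying event, one
    exposure column (and completeness column) per lag stratum."""
    rows = []
    for k, ev in enumerate(select_case_events(events, outcome_codes, first_occurrence_only)):
        series = series_map.get(ev.subject_id)
        if series is None:
            continue
        vals, comps = distributed_lag_matrix(series, ev.event_date, strata)
        row = {
            "set_id": k,
            "subject_id": ev.subject_id,
            "index_date": ev.event_date.strftime("%Y-%m-%d"),
        }
        for (lo, hi), v, c in zip(strata.bounds, vals, comps):
            row[f"lag{lo}_{hi}"] = v
            row[f"lag{lo}_{hi}_completeness"] = c
        rows.append(row)
    return pd.DataFrame(rows)
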