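"""Parsing and validation of cohort tables: baseline info, health events,
residential histories.

The three tables mirror the layout used for pseudonymised cohort extracts:

``subjects.csv``
    ``subject_id,enrolment_date,last_followup_date[,birth_date]``
``events.csv``
    ``subject_id,icd_code,event_date``
``residences.csv``
    ``subject_id,location_id,start_date,end_date,easting,northing``

Dates are ISO-8601.  An empty or ``Present`` end date marks an OPEN
(ongoing) follow-up or residential period; OPEN entries are materialised at
a caller-supplied ``reference_date`` for computation while keeping the OPEN
flag, so downstream summaries can censor correctly.

Date intervals are *closed* on both ends: a period ``[start, end]`` includes
both days, and two abutting periods satisfy ``next.start == prev.end + 1
day``.  Self-reported residential histories are error-prone, so the default
``lenient`` policy repairs overlaps by truncating the earlier period at the
later period's start minus one day (each repair is logged); ``strict`` mode
raises instead.  Gaps between periods are permitted and simply yield
unlinked exposure days downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

ONE_DAY = pd.Timedelta(days=1)


class CohortError(ValueError):
    """Base class for cohort-table validation failures."""


class OverlapError(CohortError):
    """Overlapping residential periods under the strict policy ("overlap")."""


class OrphanRecordError(CohortError):
    """Event or residence referencing an unknown subject ("orphan record")."""


def parse_date(value) -> pd.Timestamp | None:
    """Parse an ISO-8601 date; ``Present``/empty/NaN parse to None (OPEN)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if s == "" or s.lower() in ("present", "nan"):
        return None
    return pd.Timestamp(s).normalize()


@dataclass
class SubjectRecord:
    subject_id: str
    enrolment_date: pd.Timestamp
    last_followup_date: pd.Timestamp
    followup_open: bool = False
    birth_date: pd.Timestamp | None = None

    def __post_init__(self):
        if self.enrolment_date > self.last_followup_date:
            raise CohortError(
                f"subject {self.subject_id}: enrolment after last follow-up"
            )
        if self.birth_date is not None and not self.birth_date < self.enrolment_date:
            raise CohortError(f"subject {self.subject_id}: birth date not before enrolment")


@dataclass
class HealthEvent:
    subject_id: str
    icd_code: str
    event_date: pd.Timestamp


@dataclass
class ResidentialPeriod:
    subject_id: str
    location_id: str
    start_date: pd.Timestamp
    end_date: pd.Timestamp
    easting: float
    northing: float
    open_ended: bool = False

    def __post_init__(self):
        if self.start_date > self.end_date:
            raise CohortError(
                f"subject {self.subject_id} period {self.location_id}: start after end"
            )
        if not (np.isfinite(self.easting) and np.isfinite(self.northing)):
            raise CohortError(
                f"subject {self.subject_id} period {self.location_id}: non-finite coordinates"
            )

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    def contains(self, date) -> bool:
        return self.start_date <= pd.Timestamp(date) <= self.end_date


@dataclass
class ResidentialHistory:
    """Time-ordered, non-overlapping residential periods for one subject."""

    subject_id: str
    periods: list[ResidentialPeriod]

    def __post_init__(self):
        self.periods = sorted(self.periods, key=lambda p: p.start_date)
        for a, b in zip(self.periods, self.periods[1:]):
            if b.start_date <= a.end_date:
                raise OverlapError(
                    f"overlap: subject {self.subject_id} periods "
                    f"{a.location_id} and {b.location_id}"
                )
        opens = [i for i, p in enumerate(self.periods) if p.open_ended]
        if len(opens) > 1 or (opens and opens[0] != len(self.periods) - 1):
            raise CohortError(
                f"subject {self.subject_id}: at most one OPEN period, which must be last"
            )

    @property
    def start_date(self) -> pd.Timestamp:
        return self.periods[0].start_date

    @property
    def end_date(self) -> pd.Timestamp:
        return self.periods[-1].end_date

    def period_on(self, date) -> ResidentialPeriod | None:
        """The period covering ``date``, or None if the day falls in a gap."""
        d = pd.Timestamp(date)
        for p in self.periods:
            if p.start_date <= d <= p.end_date:
                return p
        return None


def coverage_days(history: ResidentialHistory) -> int:
    """Number of calendar days covered by at least one residential period
    (closed intervals, both endpoints inclusive)."""
    return sum(p.n_days for p in history.periods)


@dataclass
class CohortData:
    subjects: dict[str, SubjectRecord]
    events: list[HealthEvent]
    histories: dict[str, ResidentialHistory]
    log: list[str] = field(default_factory=list)


def _resolve_period_overlaps(
    rows: list[dict], subject_id: str, policy: str, log: list[str]
) -> list[dict]:
    rows = sorted(rows, key=lambda r: (r["start_date"], r["end_date"]))
    out: list[dict] = []
    for row in rows:
        if out and row["start_date"] <= out[-1]["end_date"]:
            if policy == "strict":
                raise OverlapError(
                    f"overlap: subject {subject_id} periods "
                    f"{out[-1]['location_id']} and {row['location_id']}"
                )
            new_end = row["start_date"] - ONE_DAY
            log.append(
                f"subject {subject_id}: truncated period {out[-1]['location_id']} "
                f"at {new_end.date()} (overlapped by {row['location_id']})"
            )
            if new_end < out[-1]["start_date"]:
                log.append(
                    f"subject {subject_id}: dropped period {out[-1]['location_id']} "
                    "(fully shadowed)"
                )
                out.pop()
            else:
                out[-1]["end_date"] = new_end
                out[-1]["open_ended"] = False
        out.append(dict(row))
    return out


def validate_cohort_frames(
    subjects_df: pd.DataFrame,
    events_df: pd.DataFrame,
    residences_df: pd.DataFrame,
    reference_date,
    policy: str = "lenient",
) -> CohortData:
    """Validate in-memory cohort tables (same schemas as the CSV files).

    ``reference_date`` closes OPEN follow-ups and residential periods for
    computation; the OPEN flag is retained on each record.  ``policy`` is
    ``lenient`` (repair + log) or ``strict`` (raise).
    """
    if policy not in ("lenient", "strict"):
        raise CohortError(f"unknown policy {policy!r}")
    ref = pd.Timestamp(reference_date).normalize()
    log: list[str] = []

    subjects: dict[str, SubjectRecord] = {}
    has_birth = "birth_date" in subjects_df.columns
    for row in subjects_df.itertuples(index=False):
        sid = str(row.subject_id)
        if sid in subjects:
            raise CohortError(f"duplicate subject id {sid}")
        end = parse_date(row.last_followup_date)
        subjects[sid] = SubjectRecord(
            subject_id=sid,
            enrolment_date=parse_date(row.enrolment_date),
            last_followup_date=end if end is not None else ref,
            followup_open=end is None,
            birth_date=parse_date(row.birth_date) if has_birth else None,
        )

    events: list[HealthEvent] = []
    for row in events_df.itertuples(index=False):
        sid = str(row.subject_id)
        if sid not in subjects:
            raise OrphanRecordError(f"orphan record: event for unknown subject {sid}")
        ev = HealthEvent(sid, str(row.icd_code), parse_date(row.event_date))
        rec = subjects[sid]
        if not rec.enrolment_date <= ev.event_date <= rec.last_followup_date:
            msg = (
                f"subject {sid}: event {ev.icd_code} on {ev.event_date.date()} "
                "outside the follow-up window"
            )
            if policy == "strict":
                raise CohortError(msg)
            log.append(msg)
        events.append(ev)
    events.sort(key=lambda e: (e.event_date, e.subject_id, e.icd_code))

    by_subject: dict[str, list[dict]] = {}
    for row in residences_df.itertuples(index=False):
        sid = str(row.subject_id)
        if sid not in subjects:
            raise OrphanRecordError(f"orphan record: residence for unknown subject {sid}")
        end = parse_date(row.end_date)
        by_subject.setdefault(sid, []).append(
            dict(
                subject_id=sid,
                location_id=str(row.location_id),
                start_date=parse_date(row.start_date),
                end_date=end if end is not None else ref,
                easting=float(row.easting),
                northing=float(row.northing),
                open_ended=end is None,
            )
        )

    histories: dict[str, ResidentialHistory] = {}
    for sid, rows in by_subject.items():
        rows = _resolve_period_overlaps(rows, sid, policy, log)
        histories[sid] = ResidentialHistory(sid, [ResidentialPeriod(**r) for r in rows])

    return CohortData(subjects, events, histories, log)


def read_cohort_tables(
    subjects_path,
    events_path,
    residences_path,
    reference_date,
    policy: str = "lenient",
) -> CohortData:
    """Read and validate the three cohort CSVs.

    See :func:`validate_cohort_frames` for the validation contract.
    """
    subjects_df = pd.read_csv(subjects_path, dtype=str)
    events_df = pd.read_csv(events_path, dtype=str)
    residences_df = pd.read_csv(residences_path, dtype=str)
    return validate_cohort_frames(
        subjects_df, events_df, residences_df, reference_date, policy=policy
    )
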