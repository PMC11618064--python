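"""End-to-end pipeline: simulate -> link -> assemble -> summarize.

A :class:`RunConfig` (usually loaded from YAML) describes where the grid
and cohort tables come from (paths, or simulation sections), the linkage
method, the interval policy, and exactly one summary design per run.  All
randomness flows from the single config seed, outputs are tidy CSV tables,
and a JSON run manifest records the config hash, seed, package version and
per-stage row counts, so identical configs give byte-identical reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .cohort import CohortData, read_cohort_tables, validate_cohort_frames
from .grid import ExposureGrid, read_grid, write_grid
from .history import SubjectExposureSeries, assemble_subject_series
from .linkage import LocationSeries, extract_point_series
from .simulate import (
    CohortSimConfig,
    GridSimConfig,
    GridSimulation,
    OutcomeModel,
    simulate_cohort,
    write_cohort_tables,
)
from .summaries import (
    LagStrata,
    LagWindow,
    build_casecrossover_sets,
    build_risk_sets,
    casecrossover_sets_to_frame,
    dlm_to_frame,
    risk_sets_to_frame,
)

logger = logging.getLogger("envlink")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and offenders."""


@dataclass
class RunConfig:
    """Declarative description of one pipeline run (mirrors the YAML file)."""

    seed: int = 0
    reference_date: str = "2020-01-01"
    grid: dict = field(default_factory=dict)  # {path, format} or {simulate: {...}}
    cohort: dict = field(default_factory=dict)  # paths or {simulate: {...}}
    link: dict = field(default_factory=lambda: {"method": "bilinear"})
    policy: str = "lenient"
    summarize: dict = field(default_factory=dict)  # exactly one design per run

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"stage config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def sha256(self) -> str:
        canon = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def _grid_sim_config(section: Mapping[str, Any], seed: int) -> GridSimConfig:
    kw = dict(section)
    kw.setdefault("seed", seed)
    return GridSimConfig(**kw)


def _cohort_sim_config(section: Mapping[str, Any], seed: int) -> CohortSimConfig:
    kw = dict(section)
    kw.setdefault("seed", seed + 1)
    if "outcome" in kw:
        okw = dict(kw["outcome"])
        if "window" in okw:
            okw["window"] = LagWindow(**okw["window"])
        kw["outcome"] = OutcomeModel(**okw)
    return CohortSimConfig(**kw)


def load_grid_stage(config: RunConfig, out_dir: pathlib.Path) -> ExposureGrid:
    section = config.grid
    if "simulate" in section:
        grid = GridSimulation(_grid_sim_config(section["simulate"], config.seed)).grid()
        write_grid(grid, out_dir / "grid.csv", "long_csv")
        return grid
    path = section.get("path")
    if path is None or not pathlib.Path(path).exists():
        raise PipelineError(f"stage link: grid path missing or not found: {path!r}")
    return read_grid(path, section.get("format", "long_csv"))


def load_cohort_stage(config: RunConfig, grid: ExposureGrid, out_dir: pathlib.Path) -> CohortData:
    section = config.cohort
    if "simulate" in section:
        sim = simulate_cohort(_cohort_sim_config(section["simulate"], config.seed), grid)
        write_cohort_tables(sim.frames(), out_dir / "cohort")
        return validate_cohort_frames(
            sim.subjects, sim.events, sim.residences, config.reference_date, config.policy
        )
    for key in ("subjects", "events", "residences"):
        p = section.get(key)
        if p is None or not pathlib.Path(p).exists():
            raise PipelineError(f"stage assemble: cohort table missing or not found: {key}={p!r}")
    return read_cohort_tables(
        section["subjects"], section["events"], section["residences"],
        config.reference_date, config.policy,
    )


def link_locations(
    grid: ExposureGrid, cohort: CohortData, method: str = "bilinear"
) -> dict[str, LocationSeries]:
    """Step 1 over the whole cohort: one extracted series per unique
    residential location (lenient mode: out-of-grid points give all-missing
    series, flagged downstream rather than aborting the run)."""
    out: dict[str, LocationSeries] = {}
    for history in cohort.histories.values():
        for p in history.periods:
            if p.location_id not in out:
                out[p.location_id] = extract_point_series(
                    grid, p.easting, p.northing, method=method,
                    location_id=p.location_id, mode="lenient",
                )
    return out


def linked_to_frame(linked: Mapping[str, LocationSeries]) -> pd.DataFrame:
    rows = []
    for loc_id in sorted(linked):
        ls = linked[loc_id]
        rows.append(
            pd.DataFrame(
                {
                    "location_id": loc_id,
                    "date": ls.dates.strftime("%Y-%m-%d"),
                    "value": ls.values,
                    "missing": ls.missing.astype(int),
                    "method": ls.method,
                }
            )
        )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["location_id", "date", "value", "missing", "method"]
    )


def linked_from_frame(df: pd.DataFrame, coords: Mapping[str, tuple] | None = None) -> dict:
    """Rebuild LocationSeries from the step-1 long table (coordinates are
    not serialised in the table; pass them if a later step needs them)."""
    out = {}
    for loc_id, g in df.groupby("location_id", sort=True):
        g = g.sort_values("date")
        x, y = (coords or {}).get(str(loc_id), (float("nan"), float("nan")))
        out[str(loc_id)] = LocationSeries(
            str(loc_id), x, y, pd.DatetimeIndex(pd.to_datetime(g["date"])),
            g["value"].to_numpy(float), g["missing"].to_numpy(int).astype(bool),
            str(g["method"].iloc[0]),
        )
    return out


def assemble_cohort(
    cohort: CohortData, linked: Mapping[str, LocationSeries]
) -> dict[str, SubjectExposureSeries]:
    """Step 2 over the whole cohort (deterministic, order-independent)."""
    return {
        sid: assemble_subject_series(cohort.histories[sid], linked)
        for sid in sorted(cohort.histories)
    }


def summarize_stage(
    config: RunConfig,
    cohort: CohortData,
    series_map: Mapping[str, SubjectExposureSeries],
) -> pd.DataFrame:
    section = dict(config.summarize)
    design = section.pop("design", None)
    if design not in ("cox", "casecrossover", "dlm"):
        raise PipelineError(f"stage summarize: unknown or missing design {design!r}")
    lags = section.get("lags", {"min": 0, "max": 0})
    window = LagWindow(
        lags.get("min", 0), lags.get("max", 0),
        section.get("aggregation", "mean"), section.get("min_completeness", 1.0),
    )
    outcome_codes = section.get("outcome_codes", [])
    if not outcome_codes:
        raise PipelineError("stage summarize: outcome_codes required")
    if design == "cox":
        rs = build_risk_sets(
            cohort.subjects, cohort.events, series_map, outcome_codes,
            time_axis=section.get("time_axis", "age"), window=window,
            n_controls=section.get("n_controls", "all"),
            seed=section.get("seed", config.seed),
        )
        return risk_sets_to_frame(rs)
    if design == "casecrossover":
        cc = build_casecrossover_sets(
            cohort.events, series_map, outcome_codes, window=window,
            first_occurrence_only=section.get("first_occurrence_only", True),
        )
        return casecrossover_sets_to_frame(cc)
    strata_cfg = section.get("strata", {"kind": "daily"})
    kind = strata_cfg.get("kind", "daily")
    mc = section.get("min_completeness", 1.0)
    if kind == "daily":
        strata = LagStrata.daily(lags.get("min", 0), lags.get("max", 0), min_completeness=mc)
    elif kind == "monthly":
        strata = LagStrata.monthly(strata_cfg.get("n", 1), lags.get("min", 0), min_completeness=mc)
    elif kind == "yearly":
        strata = LagStrata.yearly(strata_cfg.get("n", 1), lags.get("min", 0), min_completeness=mc)
    else:
        strata = LagStrata(tuple(tuple(b) for b in strata_cfg.get("bounds", [])), min_completeness=mc)
    return dlm_to_frame(cohort.events, series_map, outcome_codes, strata)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the three linkage steps in order and write a run manifest.

    Any stage error aborts with the stage name in the message.  Reruns with
    an identical config write byte-identical outputs.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_sha256": config.sha256(),
        "seed": config.seed,
        "envlink_version": __version__,
        "stages": {},
    }

    grid = load_grid_stage(config, out)
    manifest["stages"]["grid"] = {
        "n_dates": grid.n_dates, "nx": grid.nx, "ny": grid.ny,
    }
    cohort = load_cohort_stage(config, grid, out)
    manifest["stages"]["cohort"] = {
        "n_subjects": len(cohort.subjects),
        "n_events": len(cohort.events),
        "n_periods": sum(len(h.periods) for h in cohort.histories.values()),
        "validation_log": len(cohort.log),
    }

    try:
        linked = link_locations(grid, cohort, config.link.get("method", "bilinear"))
    except Exception as e:  # noqa: BLE001 - annotate with stage name
        raise PipelineError(f"stage link: {e}") from e
    linked_df = linked_to_frame(linked)
    linked_df.to_csv(out / "linked.csv", index=False)
    manifest["stages"]["link"] = {"n_locations": len(linked), "rows": len(linked_df)}

    try:
        series_map = assemble_cohort(cohort, linked)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage assemble: {e}") from e
    assembled = pd.concat(
        [s.to_frame() for _, s in sorted(series_map.items())], ignore_index=True
    )
    assembled.to_csv(out / "assembled.csv", index=False)
    manifest["stages"]["assemble"] = {"n_subjects": len(series_map), "rows": len(assembled)}

    if config.summarize:
        try:
            summary = summarize_stage(config, cohort, series_map)
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"stage summarize: {e}") from e
        summary.to_csv(out / "summary.csv", index=False)
        manifest["stages"]["summarize"] = {
            "design": config.summarize.get("design"), "rows": len(summary),
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete: %s", manifest["stages"])
    return manifest
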