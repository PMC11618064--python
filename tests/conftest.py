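import numpy as np
import pandas as pd
import pytest

import envlink as el


@pytest.fixture(scope="session")
def table1_cohort() -> el.CohortData:
    """The three-subject worked pseudo-cohort, validated with OPEN entries
    materialised at 2020-01-01."""
    subs, ev, res = el.table1_fixture()
    return el.validate_cohort_frames(subs, ev, res, "2020-01-01")


@pytest.fixture(scope="session")
def small_grid() -> el.ExposureGrid:
    """A 12x12 two-year synthetic grid with a continuous random component."""
    return el.simulate_grid(el.GridSimConfig(seed=42))


@pytest.fixture(scope="session")
def trend_grid() -> el.ExposureGrid:
    """A purely linear (trend-only, noise-free) field: bilinear is exact here."""
    cfg = el.GridSimConfig(
        nx=8, ny=6, n_days=5, seed=0, n_bumps=0, bump_amplitude=0.0,
        seasonal_amplitude=0.0, ar1_sd=0.0, noise_sd=0.0,
        trend_x=3e-4, trend_y=-2e-4,
    )
    return el.simulate_grid(cfg)


def brute_force_day_lookup(history, location_series, date):
    """Independent day -> period -> location-series lookup used as the
    stitching oracle: returns (value_or_nan, flag)."""
    period = None
    for p in history.periods:
        if p.start_date <= date <= p.end_date:
            period = p
            break
    if period is None:
        return (np.nan, el.FLAG_NO_RESIDENCE)
    ls = location_series[period.location_id]
    if not (ls.start <= date <= ls.end):
        return (np.nan, el.FLAG_UNAVAILABLE)
    k = (date - ls.start).days
    if ls.missing[k]:
        return (np.nan, el.FLAG_UNAVAILABLE)
    return (float(ls.values[k]), el.FLAG_OK)
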