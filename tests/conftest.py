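import datetime as dt

import numpy as np
import pytest

from fullcycle.annual_cycle import (
    ExposureSegment,
    default_calendar,
    default_scheme,
)
from fullcycle.simulate import SimulationConfig


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def calendar(scheme):
    return default_calendar(scheme)


def make_segments(durations, events, age_class="young_adult", stage="breeding"):
    """Exposure segments on a shared within-stage axis, for estimator tests."""
    start = dt.date(2010, 3, 1)
    return [
        ExposureSegment(
            individual_id=f"seg_{i}",
            age_class=age_class,
            stage=stage,
            start_date=start,
            end_date=start + dt.timedelta(days=int(d) - 1),
            days_at_risk=int(d),
            event=bool(e),
        )
        for i, (d, e) in enumerate(zip(durations, events))
    ]


def uniform_hazard_config(
    n,
    hazard,
    seed,
    censoring=0.0,
    years=1.0,
    ages=(2, 3, 4, 5),
    stage_hazards=None,
):
    """All individuals tagged on Mar 1 (a stage boundary) of a common year;
    constant hazard everywhere unless a per-stage override is given."""
    scheme = default_scheme()
    calendar = default_calendar(scheme)
    if stage_hazards is None:
        table = {
            (label, stg): hazard
            for label in scheme.labels
            for stg in calendar.stages_for(label)
        }
    else:
        table = {
            (label, stg): stage_hazards[stg]
            for label in scheme.labels
            for stg in calendar.stages_for(label)
        }
    return SimulationConfig(
        n_individuals=n,
        tagging_age_weights={a: 1.0 / len(ages) for a in ages},
        study_start=dt.date(2010, 3, 1),
        study_years=years,
        tagging_window_years=0.0,
        daily_hazard=table,
        censoring_hazard=censoring,
        calendar=calendar,
        scheme=scheme,
        seed=seed,
    )
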