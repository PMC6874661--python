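"""Significance machinery for death patterns across age and stage.

Kaplan-Meier significance testing needs larger samples than a tracking
study provides, so stage/age effects on *where in the cycle* death occurs
are tested by a resampling construction: every individual that never died
(a control) is assigned one simulated death day drawn uniformly over its
own tracking period, which inherits the exposure structure of the data.
Actual deaths (coded 1) are then contrasted with simulated ones (coded 0)
in a binomial GLM with logit link, with likelihood-ratio tests for stage,
age and their interaction.  Pearson chi-square tests of pooled age x stage
death frequencies and one-way ANOVAs of death attributes (age at death,
latitude of death) by stage complete the report.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .annual_cycle import (
    AgeClassScheme,
    AnnualCycleCalendar,
    classify_day,
)
from .simulate import CENSORED, DIED, TrackingRecord

__all__ = [
    "DeathEvent",
    "actual_death_events",
    "simulate_control_deaths",
    "filter_min_tracking",
    "death_glm_test",
    "chisq_death_frequency",
    "anova_by_stage",
    "DEFAULT_AGE_POOLING",
    "DEFAULT_MIN_TRACKING_DAYS",
]

#: pooled two-level age partition used when cells are sparse
DEFAULT_AGE_POOLING: tuple[tuple[int, int], ...] = ((1, 6), (7, 28))
#: individuals tracked fewer days than this are excluded before testing
DEFAULT_MIN_TRACKING_DAYS = 7


@dataclass(frozen=True)
class DeathEvent:
    """An actual or simulated (control) death."""

    individual_id: str
    age_at_death: int
    age_class: str
    stage: str
    latitude: float | None
    simulated: bool


def filter_min_tracking(
    records: Iterable[TrackingRecord],
    min_days: int = DEFAULT_MIN_TRACKING_DAYS,
) -> list[TrackingRecord]:
    """Drop individuals tracked for fewer than ``min_days`` days."""
    return [
        r for r in records if (r.fate_date - r.tagging_date).days + 1 >= min_days
    ]


def actual_death_events(
    records: Iterable[TrackingRecord],
    calendar: AnnualCycleCalendar,
    scheme: AgeClassScheme,
) -> list[DeathEvent]:
    """Death events of the individuals that died, labelled by the calendar."""
    events = []
    for rec in records:
        if rec.fate != DIED:
            continue
        age, label, stage = classify_day(
            rec.fate_date, rec.tagging_date, rec.age_at_tagging, calendar, scheme
        )
        events.append(
            DeathEvent(
                individual_id=rec.individual_id,
                age_at_death=age,
                age_class=label,
                stage=stage,
                latitude=rec.death_lat,
                simulated=False,
            )
        )
    return events


def simulate_control_deaths(
    controls: Sequence[TrackingRecord],
    calendar: AnnualCycleCalendar,
    scheme: AgeClassScheme,
    seed: int,
) -> list[DeathEvent]:
    """One uniformly drawn simulated death day per censored control.

    The day is drawn uniformly over [tagging_date, censoring_date]; the
    event's age and stage are looked up from the calendar on that day.
    Reproducible by seed.
    """
    if not controls:
        raise ValueError("no control individuals supplied")
    bad = [r.individual_id for r in controls if r.fate != CENSORED]
    if bad:
        raise ValueError(f"controls must all be censored; died: {bad}")
    rng = np.random.default_rng(seed)
    events = []
    for rec in controls:
        n_days = (rec.fate_date - rec.tagging_date).days + 1
        offset = int(rng.integers(0, n_days))
        day = rec.tagging_date + dt.timedelta(days=offset)
        age, label, stage = classify_day(
            day, rec.tagging_date, rec.age_at_tagging, calendar, scheme
        )
        events.append(
            DeathEvent(
                individual_id=rec.individual_id,
                age_at_death=age,
                age_class=label,
                stage=stage,
                latitude=None,
                simulated=True,
            )
        )
    return events


def _age_group(event: DeathEvent, age_coding, pooling) -> str:
    if age_coding == "classes":
        return event.age_class
    for lo, hi in pooling:
        if lo <= event.age_at_death <= hi:
            return f"age_{lo}_{hi}"
    # clamp outside the pooled range to the nearest group
    lows = [lo for lo, _ in pooling]
    if event.age_at_death < min(lows):
        lo, hi = pooling[0]
    else:
        lo, hi = pooling[-1]
    return f"age_{lo}_{hi}"


def _fit_binomial(cells: pd.DataFrame, design_cols: list[str]):
    X = np.column_stack(
        [np.ones(len(cells))] + [cells[c].to_numpy(float) for c in design_cols]
    )
    endog = cells[["actual", "simulated"]].to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
    rank = int(np.linalg.matrix_rank(X))
    return res, rank


def death_glm_test(
    actual: Sequence[DeathEvent],
    simulated: Sequence[DeathEvent],
    age_coding: str = "pooled",
    pooling: tuple[tuple[int, int], ...] = DEFAULT_AGE_POOLING,
) -> dict:
    """Binomial-GLM likelihood-ratio tests of stage, age and interaction.

    The response is actual (1) vs simulated (0) death; predictors are
    stage and age group (``age_coding="pooled"`` for the two-level 1-6 /
    7+ partition, ``"classes"`` for the four life-cycle classes) as
    categorical factors.  Each term's LRT compares nested fits:
    interaction = full vs additive; stage = additive vs age-only;
    age = additive vs stage-only.  Cells observed in only one response
    class are flagged as quasi-separated rather than failing.
    """
    if not actual or not simulated:
        raise ValueError("both actual and simulated events are required")
    events = list(actual) + list(simulated)
    df = pd.DataFrame(
        {
            "stage": [e.stage for e in events],
            "age_group": [_age_group(e, age_coding, pooling) for e in events],
            "actual": [0 if e.simulated else 1 for e in events],
        }
    )
    cells = (
        df.groupby(["stage", "age_group"], sort=True)["actual"]
        .agg(actual="sum", total="count")
        .reset_index()
    )
    cells["simulated"] = cells["total"] - cells["actual"]

    warnings_list = []
    separated = cells[(cells["actual"] == 0) | (cells["simulated"] == 0)]
    if len(separated):
        warnings_list.append(
            "quasi-separation: cells with a single response class: "
            + ", ".join(
                f"({r.stage}, {r.age_group})" for r in separated.itertuples()
            )
        )

    stage_d = pd.get_dummies(cells["stage"], prefix="stage", drop_first=True)
    age_d = pd.get_dummies(cells["age_group"], prefix="age", drop_first=True)
    inter = pd.DataFrame(
        {
            f"{s}:{a}": stage_d[s] * age_d[a]
            for s in stage_d.columns
            for a in age_d.columns
        },
        index=cells.index,
    )
    cells = pd.concat([cells, stage_d, age_d, inter], axis=1)

    designs = {
        "null": [],
        "stage_only": list(stage_d.columns),
        "age_only": list(age_d.columns),
        "additive": list(stage_d.columns) + list(age_d.columns),
        "full": list(stage_d.columns) + list(age_d.columns) + list(inter.columns),
    }
    fits = {name: _fit_binomial(cells, cols) for name, cols in designs.items()}

    def lrt(full_name: str, reduced_name: str) -> dict:
        full, rank_f = fits[full_name]
        red, rank_r = fits[reduced_name]
        stat = float(2.0 * (full.llf - red.llf))
        stat = max(stat, 0.0)
        dof = rank_f - rank_r
        p = float(stats.chi2.sf(stat, dof)) if dof > 0 else float("nan")
        return {
            "lrt": stat,
            "df": int(dof),
            "p": p,
            "deviance_full": float(full.deviance),
            "deviance_reduced": float(red.deviance),
        }

    report = {
        "terms": {
            "stage": lrt("additive", "age_only"),
            "age": lrt("additive", "stage_only"),
            "interaction": lrt("full", "additive"),
        },
        "n_actual": int(len(actual)),
        "n_simulated": int(len(simulated)),
        "age_coding": age_coding,
        "cells": cells[["stage", "age_group", "actual", "simulated"]].to_dict(
            orient="records"
        ),
        "warnings": warnings_list,
    }
    return report


def chisq_death_frequency(
    deaths: Sequence[DeathEvent],
    pooling: tuple[tuple[int, int], ...] = DEFAULT_AGE_POOLING,
) -> dict:
    """Pearson chi-square on the pooled age x stage death-frequency table.

    All-zero rows/columns are dropped with a warning; a flag marks
    expected counts below 5.
    """
    if not deaths:
        raise ValueError("no death events supplied")
    df = pd.DataFrame(
        {
            "age_group": [_age_group(e, "pooled", pooling) for e in deaths],
            "stage": [e.stage for e in deaths],
        }
    )
    table = pd.crosstab(df["age_group"], df["stage"])
    warnings_list = []
    zero_rows = table.index[(table.sum(axis=1) == 0)].tolist()
    zero_cols = table.columns[(table.sum(axis=0) == 0)].tolist()
    if zero_rows or zero_cols:
        warnings_list.append(f"dropped all-zero rows {zero_rows} / columns {zero_cols}")
        table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table needs at least 2 rows and 2 columns")
    chi2, p, dof, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    if (expected < 5).any():
        warnings_list.append(
            f"{int((expected < 5).sum())} cells have expected count < 5"
        )
    return {
        "chi2": float(chi2),
        "df": int(dof),
        "p": float(p),
        "table": table.to_dict(),
        "expected_min": float(expected.min()),
        "warnings": warnings_list,
    }


def anova_by_stage(
    deaths: Sequence[DeathEvent],
    response: str = "age_at_death",
) -> dict:
    """One-way fixed-effects ANOVA of a death attribute across stages.

    ``response`` is ``"age_at_death"`` or ``"latitude"``; events lacking
    the response value are dropped.  Reports F, (df1, df2), p, and per
    stage group means +/- 1 SE.
    """
    if response not in ("age_at_death", "latitude"):
        raise ValueError(f"unknown response {response!r}")
    groups: dict[str, list[float]] = {}
    for e in deaths:
        value = e.age_at_death if response == "age_at_death" else e.latitude
        if value is None:
            continue
        groups.setdefault(e.stage, []).append(float(value))
    groups = {k: v for k, v in groups.items() if v}
    k = len(groups)
    n_total = sum(len(v) for v in groups.values())
    if k < 2:
        raise ValueError("need deaths in at least two stages")
    if n_total <= k:
        raise ValueError("need more deaths than stages")
    warnings_list = [
        f"stage {s!r} has a single observation (no within-group variance)"
        for s, v in groups.items()
        if len(v) == 1
    ]
    arrays = [np.asarray(v) for v in groups.values()]
    F, p = stats.f_oneway(*arrays)
    summary = {
        s: {
            "n": len(v),
            "mean": float(np.mean(v)),
            "se": float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan"),
        }
        for s, v in groups.items()
    }
    return {
        "response": response,
        "F": float(F),
        "df1": int(k - 1),
        "df2": int(n_total - k),
        "p": float(p),
        "groups": summary,
        "warnings": warnings_list,
    }
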