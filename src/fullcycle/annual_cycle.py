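"""Annual-cycle stage calendar, life-cycle age classes, and exposure decomposition.

The annual cycle of a trans-Saharan migratory raptor is modelled as four
stages — breeding, southward (post-breeding) migration, African wintering,
northward (pre-breeding) migration — that tile a 365-day reference year.
The life cycle is partitioned into integer-age classes (juvenile, young
adult, prime, senescent).  Every tracked day of an individual belongs to
exactly one (age class, stage) combination; a known-fate tracking history
is decomposed here into contiguous exposure segments within combinations,
with the within-segment clock restarting at each stage or age-class
boundary ("a bird exiting a period alive re-enters the next as a new
individual").
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "BREEDING",
    "SOUTHWARD",
    "WINTERING",
    "NORTHWARD",
    "STAGES",
    "DAYS_IN_YEAR",
    "BIRTHDAY_DOY",
    "AgeClassScheme",
    "AnnualCycleCalendar",
    "ExposureSegment",
    "default_scheme",
    "default_calendar",
    "assign_age_class",
    "age_on",
    "label_days",
    "classify_day",
    "decompose_exposure",
]

BREEDING = "breeding"
SOUTHWARD = "southward_migration"
WINTERING = "wintering"
NORTHWARD = "northward_migration"
STAGES: tuple[str, ...] = (BREEDING, SOUTHWARD, WINTERING, NORTHWARD)

DAYS_IN_YEAR = 365
#: day-of-year (365-day reference year) on which integer age advances;
#: March 1, the start of the breeding season, so age-class transitions
#: coincide with a stage boundary.
BIRTHDAY_DOY = 60

_EPOCH_YEAR = 1970


class CalendarError(ValueError):
    """Raised for calendars or schemes that violate their invariants."""


@dataclass(frozen=True)
class AgeClassScheme:
    """Ordered partition of integer ages into life-cycle classes.

    Default follows the raptor life cycle: juvenile (age 1), young adult
    (2-6, establishing a territory), prime (7-11, maximum survival and
    breeding), senescent (12-28).
    """

    classes: tuple[tuple[str, int, int], ...] = (
        ("juvenile", 1, 1),
        ("young_adult", 2, 6),
        ("prime", 7, 11),
        ("senescent", 12, 28),
    )

    def __post_init__(self) -> None:
        if not self.classes:
            raise CalendarError("scheme needs at least one age class")
        prev_hi = None
        for label, lo, hi in self.classes:
            if lo > hi:
                raise CalendarError(f"class {label!r} has min_age > max_age")
            if prev_hi is not None and lo != prev_hi + 1:
                raise CalendarError(
                    f"classes must be contiguous; gap/overlap before {label!r}"
                )
            prev_hi = hi
        labels = [c[0] for c in self.classes]
        if len(set(labels)) != len(labels):
            raise CalendarError("duplicate class labels")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c[0] for c in self.classes)

    @property
    def min_age(self) -> int:
        return self.classes[0][1]

    @property
    def max_age(self) -> int:
        return self.classes[-1][2]

    def class_index(self, age: int) -> int:
        if not (self.min_age <= age <= self.max_age):
            raise ValueError(
                f"age {age} outside scheme coverage "
                f"[{self.min_age}, {self.max_age}]"
            )
        for i, (_, lo, hi) in enumerate(self.classes):
            if lo <= age <= hi:
                return i
        raise AssertionError("unreachable")  # pragma: no cover

    def index_by_age(self) -> np.ndarray:
        """Lookup array over ages ``min_age..max_age`` -> class index."""
        out = np.empty(self.max_age - self.min_age + 1, dtype=np.intp)
        for i, (_, lo, hi) in enumerate(self.classes):
            out[lo - self.min_age : hi - self.min_age + 1] = i
        return out


def default_scheme() -> AgeClassScheme:
    return AgeClassScheme()


def assign_age_class(age: int, scheme: AgeClassScheme) -> str:
    """Label of the unique class whose [min, max] range contains ``age``."""
    return scheme.classes[scheme.class_index(age)][0]


class AnnualCycleCalendar:
    """Per age-class tiling of the 365-day year into annual-cycle stages.

    ``spans`` maps a class label to an ordered sequence of
    ``(stage_name, start_day_of_year, duration_days)`` entries.  Stages may
    wrap across the year end (wintering does); per class the spans must
    cover every day of the 365-day reference year exactly once.  Feb 29 of
    leap years takes the stage of Feb 28.
    """

    def __init__(self, spans: Mapping[str, Sequence[tuple[str, int, int]]]):
        self.spans: dict[str, tuple[tuple[str, int, int], ...]] = {
            label: tuple((str(s), int(d0), int(l)) for s, d0, l in entries)
            for label, entries in spans.items()
        }
        self._tables: dict[str, np.ndarray] = {}
        for label, entries in self.spans.items():
            occupancy = np.full(DAYS_IN_YEAR, -1, dtype=np.intp)
            for stage, start_doy, duration in entries:
                if stage not in STAGES:
                    raise CalendarError(
                        f"unknown stage {stage!r} in calendar for {label!r}"
                    )
                if duration < 1:
                    raise CalendarError(
                        f"stage {stage!r} of {label!r} has duration < 1"
                    )
                if not (1 <= start_doy <= DAYS_IN_YEAR + 1):
                    raise CalendarError(
                        f"stage {stage!r} of {label!r} has start day {start_doy} "
                        f"outside 1..{DAYS_IN_YEAR}"
                    )
                idx = (start_doy - 1 + np.arange(duration)) % DAYS_IN_YEAR
                if (occupancy[idx] != -1).any():
                    raise CalendarError(
                        f"overlapping stages in calendar for {label!r}"
                    )
                occupancy[idx] = STAGES.index(stage)
            if (occupancy == -1).any():
                raise CalendarError(
                    f"calendar for {label!r} does not cover the full year"
                )
            self._tables[label] = occupancy

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AnnualCycleCalendar) and self.spans == other.spans

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.spans)

    def stages_for(self, label: str) -> tuple[str, ...]:
        return tuple(s for s, _, _ in self.spans[label])

    def duration(self, label: str, stage: str) -> int:
        for s, _, l in self.spans[label]:
            if s == stage:
                return l
        raise KeyError(f"stage {stage!r} not in calendar for {label!r}")

    def stage_table(self, scheme: AgeClassScheme) -> np.ndarray:
        """(n_classes, 365) array of stage indices into :data:`STAGES`."""
        missing = [lab for lab in scheme.labels if lab not in self.spans]
        if missing:
            raise CalendarError(f"calendar missing age classes: {missing}")
        return np.stack([self._tables[lab] for lab in scheme.labels])

    def stage_on_doy(self, label: str, doy: int) -> str:
        return STAGES[self._tables[label][doy - 1]]

    def to_dict(self) -> dict:
        return {
            label: [list(entry) for entry in entries]
            for label, entries in self.spans.items()
        }


# Default stage boundaries (day-of-year in the 365-day reference year):
# breeding Mar 1 - Aug 31 (184 d), southward migration Sep 1 - Sep 20 (20 d),
# wintering Sep 21 - Feb 13 (146 d), northward migration Feb 14 - Feb 28
# (15 d).  Juveniles never undertake the northward migration: their
# southward journey is slower (25 d) and wintering runs to the end of their
# year (156 d).
_ADULT_SPANS = (
    (BREEDING, 60, 184),
    (SOUTHWARD, 244, 20),
    (WINTERING, 264, 146),
    (NORTHWARD, 45, 15),
)
_JUVENILE_SPANS = (
    (BREEDING, 60, 184),
    (SOUTHWARD, 244, 25),
    (WINTERING, 269, 156),
)


def default_calendar(scheme: AgeClassScheme | None = None) -> AnnualCycleCalendar:
    scheme = scheme or default_scheme()
    spans = {}
    for label in scheme.labels:
        spans[label] = _JUVENILE_SPANS if label == "juvenile" else _ADULT_SPANS
    return AnnualCycleCalendar(spans)


@dataclass(frozen=True)
class ExposureSegment:
    """Contiguous days an individual spends at risk in one (class, stage).

    ``days_at_risk = end_date - start_date + 1``; ``event`` marks the
    segment terminated by the individual's death (its last day is the
    death day).
    """

    individual_id: str
    age_class: str
    stage: str
    start_date: dt.date
    end_date: dt.date
    days_at_risk: int
    event: bool


def _doy_365(days: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map datetime64[D] array -> (calendar year, 365-day day-of-year).

    Feb 29 maps onto Feb 28's day-of-year (59), so stage labels are
    identical in leap and common years.
    """
    years_m8 = days.astype("datetime64[Y]")
    years = years_m8.astype(int) + _EPOCH_YEAR
    doy = (days - years_m8).astype(int) + 1
    leap = (years % 4 == 0) & ((years % 100 != 0) | (years % 400 == 0))
    doy = doy - (leap & (doy > 59))
    return years, doy


def age_on(day: dt.date, tagging_date: dt.date, age_at_tagging: int) -> int:
    """Integer age on ``day``, advancing on the Mar-1 reference birthday."""

    def bird_year(d: dt.date) -> int:
        arr = np.array([np.datetime64(d, "D")])
        years, doy = _doy_365(arr)
        return int(years[0]) - int(doy[0] < BIRTHDAY_DOY)

    return age_at_tagging + bird_year(day) - bird_year(tagging_date)


def label_days(
    tagging_date: dt.date,
    n_days: int,
    age_at_tagging: int,
    calendar: AnnualCycleCalendar,
    scheme: AgeClassScheme,
) -> tuple[np.ndarray, np.ndarray]:
    """Label each of ``n_days`` from tagging with (class index, stage index).

    Ages below the scheme's minimum (birds tagged as fledglings before
    their first reference birthday) or above its maximum are clamped to
    the boundary classes.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    start = np.datetime64(tagging_date, "D")
    days = start + np.arange(n_days)
    years, doy = _doy_365(days)
    bird_year = years - (doy < BIRTHDAY_DOY)
    age = age_at_tagging + bird_year - bird_year[0]
    eff_age = np.clip(age, scheme.min_age, scheme.max_age)
    class_idx = scheme.index_by_age()[eff_age - scheme.min_age]
    stage_idx = calendar.stage_table(scheme)[class_idx, doy - 1]
    return class_idx, stage_idx


def classify_day(
    day: dt.date,
    tagging_date: dt.date,
    age_at_tagging: int,
    calendar: AnnualCycleCalendar,
    scheme: AgeClassScheme,
) -> tuple[int, str, str]:
    """(integer age, age-class label, stage name) on a single tracked day."""
    offset = (day - tagging_date).days
    if offset < 0:
        raise ValueError("day precedes tagging date")
    cls, stg = label_days(tagging_date, offset + 1, age_at_tagging, calendar, scheme)
    age = age_on(day, tagging_date, age_at_tagging)
    return age, scheme.labels[cls[-1]], STAGES[stg[-1]]


def decompose_exposure(
    record,
    calendar: AnnualCycleCalendar,
    scheme: AgeClassScheme,
) -> list[ExposureSegment]:
    """Partition [tagging_date, fate_date] into (class, stage) segments.

    A new segment starts at every stage boundary and every age-class
    transition; the boundary day belongs to the earlier stage.  Exactly
    one segment (the last) carries ``event=True`` iff the record's fate is
    death; the summed ``days_at_risk`` equal the total tracked days.
    """
    n_days = (record.fate_date - record.tagging_date).days + 1
    if n_days < 1:
        raise ValueError(
            f"record {record.individual_id!r}: fate date precedes tagging date"
        )
    class_idx, stage_idx = label_days(
        record.tagging_date, n_days, record.age_at_tagging, calendar, scheme
    )
    breaks = np.flatnonzero(
        (np.diff(class_idx) != 0) | (np.diff(stage_idx) != 0)
    )
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [n_days - 1]))
    died = record.fate == "died"
    segments = []
    for s, e in zip(starts, ends):
        segments.append(
            ExposureSegment(
                individual_id=record.individual_id,
                age_class=scheme.labels[class_idx[s]],
                stage=STAGES[stage_idx[s]],
                start_date=record.tagging_date + dt.timedelta(days=int(s)),
                end_date=record.tagging_date + dt.timedelta(days=int(e)),
                days_at_risk=int(e - s + 1),
                event=bool(died and e == n_days - 1),
            )
        )
    return segments


def decompose_all(
    records: Iterable,
    calendar: AnnualCycleCalendar,
    scheme: AgeClassScheme,
) -> list[ExposureSegment]:
    """Exposure segments for a whole set of tracking records."""
    out: list[ExposureSegment] = []
    for rec in records:
        out.extend(decompose_exposure(rec, calendar, scheme))
    return out
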