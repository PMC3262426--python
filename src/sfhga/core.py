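"""Domain types, series validation, cohort exclusion rules and date arithmetic.

The package estimates gestational age (GA) from serial symphysis-pubis
fundal height (SFH) measurements.  Everything downstream works on the
types defined here:

* :class:`Measurement` — one dated SFH observation (cm).
* :class:`UltrasoundAnchor` — an early ultrasound dating (CRL or BPD
  biometry) that fixes the gestational clock for a pregnancy.
* :class:`MotherRecord` — a mother's ordered SFH series, plus optional
  anchor, delivery date and mother-level covariates.
* :class:`Cohort` — a collection of mothers with unique identifiers.

GA is carried as continuous weeks; all date arithmetic uses exactly
7 days per week.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Optional, Sequence

DAYS_PER_WEEK = 7.0

#: Sanity ceiling on a recorded fundal height, cm.
SFH_CEILING_CM = 60.0

#: GA at which the expected date of delivery is defined (standard
#: obstetric convention; configurable in :func:`edd_from_ga`).
DEFAULT_TERM_WEEKS = 40.0

#: Cohort inclusion requires at least this many SFH measurements ...
DEFAULT_MIN_MEASURES = 3
#: ... spaced at least this many days apart (two weeks).
DEFAULT_MIN_GAP_DAYS = 14

#: Fixed list of mother-level risk factors the covariate adjustment
#: recognises (weight kg, height m, BMI, age years, gravidity, parity,
#: smoker flag, P. falciparum and P. vivax slide-positivity flags).
COVARIATE_NAMES = (
    "weight_kg",
    "height_m",
    "bmi",
    "age",
    "gravida",
    "parity",
    "smoker",
    "pf",
    "pv",
)

ANCHOR_METHODS = ("CRL", "BPD")


@dataclass(frozen=True)
class Measurement:
    """One dated SFH observation.

    ``height`` is in centimetres.  Recorded (file-sourced) values are
    whole centimetres — midwives round to the nearest cm — but the type
    itself accepts any real so that :func:`validate_series` can diagnose
    bad values instead of refusing to represent them.
    """

    date: dt.date
    height: float


@dataclass(frozen=True)
class GA:
    """Continuous gestational age in weeks (strictly positive)."""

    weeks: float

    def __post_init__(self) -> None:
        if not self.weeks > 0:
            raise ValueError(f"gestational age must be positive, got {self.weeks}")


@dataclass(frozen=True)
class UltrasoundAnchor:
    """Ultrasound dating of a pregnancy: GA ``ega_weeks`` at ``anchor_date``.

    ``method`` records which biometry produced the estimate: crown-rump
    length (first-trimester scan window) or biparietal diameter
    (second-trimester window).
    """

    anchor_date: dt.date
    ega_weeks: float
    method: str = "CRL"

    def __post_init__(self) -> None:
        if not 0 < self.ega_weeks < 45:
            raise ValueError(
                f"anchor EGA must lie in (0, 45) weeks, got {self.ega_weeks}"
            )
        if self.method not in ANCHOR_METHODS:
            raise ValueError(
                f"anchor method must be one of {ANCHOR_METHODS}, got {self.method!r}"
            )


@dataclass(frozen=True)
class MotherRecord:
    """A mother's measurement series with optional truth and covariates.

    ``measurements`` should be ordered by strictly increasing date; the
    readers in :mod:`sfhga.io` and the simulator guarantee this, and
    :func:`validate_series` diagnoses violations for hand-built records.
    """

    mother_id: str
    measurements: tuple[Measurement, ...]
    anchor: Optional[UltrasoundAnchor] = None
    delivery_date: Optional[dt.date] = None
    covariates: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "measurements", tuple(self.measurements))
        if self.covariates is not None:
            unknown = set(self.covariates) - set(COVARIATE_NAMES)
            if unknown:
                raise ValueError(
                    f"unknown covariate name(s) {sorted(unknown)}; "
                    f"recognised names are {COVARIATE_NAMES}"
                )

    @property
    def n_measurements(self) -> int:
        return len(self.measurements)

    @property
    def last_date(self) -> dt.date:
        if not self.measurements:
            raise ValueError(f"mother {self.mother_id} has no measurements")
        return self.measurements[-1].date

    def sorted_by_date(self) -> "MotherRecord":
        return replace(
            self, measurements=tuple(sorted(self.measurements, key=lambda m: m.date))
        )


@dataclass(frozen=True)
class Cohort:
    """A set of mothers with unique identifiers."""

    mothers: tuple[MotherRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mothers", tuple(self.mothers))
        ids = [m.mother_id for m in self.mothers]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate mother_id(s) in cohort: {dupes}")

    def __len__(self) -> int:
        return len(self.mothers)

    def __iter__(self) -> Iterator[MotherRecord]:
        return iter(self.mothers)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(m.mother_id for m in self.mothers)

    def get(self, mother_id: str) -> MotherRecord:
        for m in self.mothers:
            if m.mother_id == mother_id:
                return m
        raise KeyError(mother_id)

    def subset(self, mother_ids: Sequence[str]) -> "Cohort":
        wanted = set(mother_ids)
        return Cohort(tuple(m for m in self.mothers if m.mother_id in wanted))


@dataclass(frozen=True)
class Exclusion:
    """One mother removed by :func:`apply_exclusions` and why."""

    mother_id: str
    reason: str


def ga_at_date(anchor: UltrasoundAnchor, query_date: dt.date) -> GA:
    """GA at ``query_date`` implied by ``anchor``: 1 GA-week per 7 days."""
    weeks = anchor.ega_weeks + (query_date - anchor.anchor_date).days / DAYS_PER_WEEK
    if weeks <= 0:
        raise ValueError(
            f"query date {query_date} is before conception implied by the "
            f"anchor ({anchor.ega_weeks} weeks at {anchor.anchor_date})"
        )
    return GA(weeks)


def edd_from_ga(
    ga: GA, at_date: dt.date, term_weeks: float = DEFAULT_TERM_WEEKS
) -> dt.date:
    """Expected date of delivery: the date at which GA reaches ``term_weeks``.

    Rounded to the nearest whole day, half-days rounding forward.
    """
    if ga.weeks > term_weeks + 10:
        raise ValueError(
            f"GA {ga.weeks} weeks is implausibly far beyond term ({term_weeks} weeks)"
        )
    days = (term_weeks - ga.weeks) * DAYS_PER_WEEK
    return at_date + dt.timedelta(days=math.floor(days + 0.5))


def validate_series(record: MotherRecord) -> list[str]:
    """Diagnose a measurement series; an empty list means valid.

    Reports non-increasing / duplicate dates, non-positive heights and
    heights at or above the sanity ceiling.
    """
    issues: list[str] = []
    prev: Optional[Measurement] = None
    for i, m in enumerate(record.measurements):
        if m.height <= 0:
            issues.append(f"measurement {i + 1}: non-positive height {m.height}")
        elif m.height >= SFH_CEILING_CM:
            issues.append(
                f"measurement {i + 1}: height {m.height} cm at or above the "
                f"{SFH_CEILING_CM:.0f} cm sanity ceiling"
            )
        if prev is not None:
            if m.date == prev.date:
                issues.append(f"measurement {i + 1}: duplicate date {m.date}")
            elif m.date < prev.date:
                issues.append(
                    f"measurement {i + 1}: date {m.date} not after {prev.date}"
                )
        prev = m
    return issues


def apply_exclusions(
    cohort: Cohort,
    min_measures: int = DEFAULT_MIN_MEASURES,
    min_gap_days: int = DEFAULT_MIN_GAP_DAYS,
) -> tuple[Cohort, list[Exclusion]]:
    """Apply the cohort inclusion rules, returning the kept cohort and a log.

    A mother is excluded if she has fewer than ``min_measures`` serial SFH
    measurements, or if ANY adjacent pair of her measurements is less than
    ``min_gap_days`` apart (exactly ``min_gap_days`` is retained).  The
    whole mother is removed, never individual measurements.
    """
    kept: list[MotherRecord] = []
    log: list[Exclusion] = []
    for mother in cohort:
        if mother.n_measurements < min_measures:
            log.append(
                Exclusion(
                    mother.mother_id,
                    f"fewer than {min_measures} SFH measurements "
                    f"(n={mother.n_measurements})",
                )
            )
            continue
        gaps = [
            (b.date - a.date).days
            for a, b in zip(mother.measurements, mother.measurements[1:])
        ]
        short = [g for g in gaps if g < min_gap_days]
        if short:
            log.append(
                Exclusion(
                    mother.mother_id,
                    f"measurements less than {min_gap_days} days apart "
                    f"(shortest gap {min(short)} days)",
                )
            )
            continue
        kept.append(mother)
    return Cohort(tuple(kept)), log
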