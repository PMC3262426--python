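"""The three SFH → gestational-age prediction models.

Model 1 (linear, single measure)
    G = a1 + a2·H — the classical linear calibration of GA on fundal
    height (about one week of gestation per centimetre mid-pregnancy).

Model 2 (nonlinear plateau, single measure)
    Fundal height grows roughly linearly with gestation and then
    plateaus near term.  The package parameterises that shape as a
    logistic curve H(G) = b1 / (1 + exp(−b2·(G − b3))) and predicts by
    inversion:

        G = b3 + ln(H / (b1 − H)) / b2

    b1 is the SFH saturation asymptote (cm), b3 the gestational age at
    the curve's inflection (weeks) and b2 the steepness (per cm); the
    model is only defined where the inverse is real and the resulting
    GA positive.

Model 3 (multiple measures)
    For every "set of three" measurements of a mother — all index
    triples (i, i+1, j) with j > i+1 — GA at the triple's last date is
    predicted two ways:

    * eq. "3a", the mean of three projected linear estimates
      G = mean_i [ cL0 + cL1·H_i + (t3 − t_i)/7 ];
    * eq. "3b", a combination of the three heights and the three
      pairwise SFH gradients (cm/week)
      G = c0 + c1·H1 + c2·H2 + c3·H3 + k12·s12 + k13·s13 + k23·s23.

    The 3b value is used when it falls inside the closed interval
    [Gmin, Gmax]; otherwise the 3a value is the fallback.  The mother's
    prediction is the mean over all her triples, each projected to her
    final measurement date at one GA-week per calendar week.
"""

from __future__ import annotations

import datetime as dt
import itertools
import math
from dataclasses import dataclass
from typing import Callable, Literal, Optional, Sequence

from .core import (
    DAYS_PER_WEEK,
    DEFAULT_MIN_GAP_DAYS,
    DEFAULT_MIN_MEASURES,
    GA,
    Cohort,
    Measurement,
    MotherRecord,
    edd_from_ga,
)

# ---------------------------------------------------------------------------
# Parameter vectors


@dataclass(frozen=True)
class Model1Params:
    """Linear model: G = a1 + a2·H (a1 weeks, a2 weeks/cm)."""

    a1: float
    a2: float

    def as_vector(self) -> tuple[float, ...]:
        return (self.a1, self.a2)

    @classmethod
    def from_vector(cls, v: Sequence[float]) -> "Model1Params":
        return cls(*map(float, v))


@dataclass(frozen=True)
class Model2Params:
    """Plateau model: G = b3 + ln(H/(b1−H))/b2.

    b1: SFH asymptote (cm); b2: steepness (1/cm); b3: inflection GA
    (weeks).
    """

    b1: float
    b2: float
    b3: float

    def as_vector(self) -> tuple[float, ...]:
        return (self.b1, self.b2, self.b3)

    @classmethod
    def from_vector(cls, v: Sequence[float]) -> "Model2Params":
        return cls(*map(float, v))

    @property
    def h_floor(self) -> float:
        """SFH below which the predicted GA is non-positive."""
        return self.b1 / (1.0 + math.exp(self.b2 * self.b3))


@dataclass(frozen=True)
class Model3Params:
    """The 11 parameters of the multiple-measures model.

    cL0/cL1 parameterise the linear fallback (3a); c0..c3 weight the
    three heights and k12/k13/k23 the three pairwise gradients in the
    combined equation (3b); Gmin/Gmax bound the region in which 3b is
    trusted.
    """

    cL0: float
    cL1: float
    c0: float
    c1: float
    c2: float
    c3: float
    k12: float
    k13: float
    k23: float
    Gmin: float
    Gmax: float

    FIELDS = ("cL0", "cL1", "c0", "c1", "c2", "c3", "k12", "k13", "k23", "Gmin", "Gmax")

    def as_vector(self) -> tuple[float, ...]:
        return tuple(getattr(self, f) for f in self.FIELDS)

    @classmethod
    def from_vector(cls, v: Sequence[float]) -> "Model3Params":
        if len(v) != len(cls.FIELDS):
            raise ValueError(f"expected {len(cls.FIELDS)} parameters, got {len(v)}")
        return cls(**{f: float(x) for f, x in zip(cls.FIELDS, v)})


#: Packaged default parameter sets (estimated on a large ultrasound-dated
#: antenatal cohort; re-fit to local data with :mod:`sfhga.fitting` before
#: relying on them for a different population).
DEFAULT_MODEL1 = Model1Params(a1=4.5, a2=1.0)
DEFAULT_MODEL2 = Model2Params(b1=53.96, b2=0.055, b3=24.82)
DEFAULT_MODEL3 = Model3Params(
    cL0=4.1,
    cL1=0.95,
    c0=12.0,
    c1=1.1,
    c2=0.24,
    c3=-0.7,
    k12=0.09,
    k13=7.0,
    k23=-0.1,
    Gmin=33.0,
    Gmax=42.0,
)


# ---------------------------------------------------------------------------
# Single-measure models


def predict_model1(h: float, params: Model1Params = DEFAULT_MODEL1) -> GA:
    """Linear prediction G = a1 + a2·H for a single SFH of ``h`` cm."""
    if h <= 0:
        raise ValueError(f"SFH must be positive, got {h}")
    return GA(params.a1 + params.a2 * h)


def predict_model2(h: float, params: Model2Params = DEFAULT_MODEL2) -> GA:
    """Plateau-model prediction for a single SFH of ``h`` cm.

    Defined for ``h`` strictly between the positive-GA floor and the
    saturation asymptote ``b1``; outside that range a domain error
    naming the offending bound is raised.
    """
    if h >= params.b1:
        raise ValueError(
            f"SFH {h} cm is at or beyond the model's saturation asymptote "
            f"b1 = {params.b1} cm"
        )
    if h <= 0:
        raise ValueError(f"SFH must be positive, got {h}")
    weeks = params.b3 + math.log(h / (params.b1 - h)) / params.b2
    if weeks <= 0:
        raise ValueError(
            f"SFH {h} cm is below {params.h_floor:.2f} cm, where the model's "
            f"predicted gestational age is non-positive"
        )
    return GA(weeks)


MultiMeasureMode = Literal["first", "mid", "mean"]


def multi_measure_mean(
    record: MotherRecord,
    single_measure_model: Callable[[float], GA],
    mode: MultiMeasureMode = "mean",
) -> GA:
    """Turn a single-measure model into a series prediction.

    Each selected measurement's prediction is projected to the last
    measurement date at 1 GA-week per elapsed calendar week.  ``mode``
    selects the first measurement, the middle one (earlier of the two
    central measurements for even counts), or the mean over all.
    """
    ms = record.measurements
    if not ms:
        raise ValueError(f"mother {record.mother_id} has an empty series")
    last = ms[-1].date

    def projected(m: Measurement) -> float:
        g = single_measure_model(m.height).weeks
        return g + (last - m.date).days / DAYS_PER_WEEK

    if mode == "first":
        return GA(projected(ms[0]))
    if mode == "mid":
        return GA(projected(ms[(len(ms) - 1) // 2]))
    if mode == "mean":
        return GA(sum(projected(m) for m in ms) / len(ms))
    raise ValueError(f"unknown mode {mode!r}; expected first|mid|mean")


# ---------------------------------------------------------------------------
# Model 3 machinery


@dataclass(frozen=True)
class Triple:
    """1-based, strictly increasing indices of a 'set of three'."""

    indices: tuple[int, int, int]

    def __post_init__(self) -> None:
        i, j, k = self.indices
        if not i < j < k:
            raise ValueError(f"triple indices must be strictly increasing: {self.indices}")


TripleVariant = Literal["consecutive", "all"]


def enumerate_triples(n: int, variant: TripleVariant = "consecutive") -> list[Triple]:
    """All 'sets of three' of an n-measurement series, lexicographically.

    The default ``consecutive`` variant takes the triples whose first two
    indices are adjacent, {(i, i+1, j) : j > i+1} — (n−1)(n−2)/2 of them;
    for five measures these are (1,2,3), (1,2,4), (1,2,5), (2,3,4),
    (2,3,5), (3,4,5).  ``variant="all"`` enumerates every 3-subset
    instead, for sensitivity analysis.
    """
    if n < 3:
        raise ValueError(f"need at least 3 measurements, got {n}")
    if variant == "consecutive":
        return [
            Triple((i, i + 1, j))
            for i in range(1, n - 1)
            for j in range(i + 2, n + 1)
        ]
    if variant == "all":
        return [Triple(t) for t in itertools.combinations(range(1, n + 1), 3)]
    raise ValueError(f"unknown triple variant {variant!r}")


def sfh_gradient(m_a: Measurement, m_b: Measurement) -> float:
    """Pairwise SFH slope between two dated measurements, cm per week."""
    days = (m_b.date - m_a.date).days
    if days <= 0:
        raise ValueError(
            f"gradient needs strictly increasing dates ({m_a.date} -> {m_b.date})"
        )
    return (m_b.height - m_a.height) / (days / DAYS_PER_WEEK)


def _check_triple_dates(ms: Sequence[Measurement]) -> None:
    if len(ms) != 3:
        raise ValueError(f"expected exactly 3 measurements, got {len(ms)}")
    if not ms[0].date < ms[1].date < ms[2].date:
        raise ValueError(
            "triple dates must be strictly increasing: "
            + ", ".join(str(m.date) for m in ms)
        )


def predict_triple_linear(
    measurements: Sequence[Measurement], params: Model3Params = DEFAULT_MODEL3
) -> GA:
    """Eq. 3a: mean of three linear estimates projected to the last date."""
    _check_triple_dates(measurements)
    t3 = measurements[2].date
    vals = [
        params.cL0 + params.cL1 * m.height + (t3 - m.date).days / DAYS_PER_WEEK
        for m in measurements
    ]
    return GA(sum(vals) / 3.0)


def _triple_combined_value(
    measurements: Sequence[Measurement], params: Model3Params
) -> float:
    m1, m2, m3 = measurements
    s12 = sfh_gradient(m1, m2)
    s13 = sfh_gradient(m1, m3)
    s23 = sfh_gradient(m2, m3)
    return (
        params.c0
        + params.c1 * m1.height
        + params.c2 * m2.height
        + params.c3 * m3.height
        + params.k12 * s12
        + params.k13 * s13
        + params.k23 * s23
    )


def predict_triple_combined(
    measurements: Sequence[Measurement], params: Model3Params = DEFAULT_MODEL3
) -> GA:
    """Eq. 3b: combination of the three heights and three gradients."""
    _check_triple_dates(measurements)
    return GA(_triple_combined_value(measurements, params))


@dataclass(frozen=True)
class TriplePrediction:
    """GA at a triple's last measurement date and which equation fired."""

    triple: Triple
    ga_at_last: GA
    equation_used: Literal["combined_3b", "fallback_3a"]


def predict_triple(
    measurements: Sequence[Measurement],
    params: Model3Params = DEFAULT_MODEL3,
    triple: Optional[Triple] = None,
) -> TriplePrediction:
    """Predict GA at the triple's last date with the 3b/3a fallback rule.

    The combined (3b) value is used iff it lies in the closed interval
    [Gmin, Gmax]; otherwise the linear-mean (3a) value is used.  The 3a
    value itself is never clamped to the interval.
    """
    _check_triple_dates(measurements)
    if triple is None:
        triple = Triple((1, 2, 3))
    value_3b = _triple_combined_value(measurements, params)
    if params.Gmin <= value_3b <= params.Gmax:
        return TriplePrediction(triple, GA(value_3b), "combined_3b")
    return TriplePrediction(triple, predict_triple_linear(measurements, params), "fallback_3a")


@dataclass(frozen=True)
class MotherPrediction:
    """Model-3 output for one mother.

    ``ga_at_last`` is the mean over triples of each triple's prediction
    projected to ``last_date``; ``edd`` the implied expected date of
    delivery; ``triples``/``projected_ga`` the per-triple detail.
    """

    mother_id: str
    ga_at_last: GA
    last_date: dt.date
    edd: dt.date
    n_measurements: int
    triples: tuple[TriplePrediction, ...] = ()
    projected_ga: tuple[float, ...] = ()

    @property
    def equation_counts(self) -> dict[str, int]:
        counts = {"combined_3b": 0, "fallback_3a": 0}
        for tp in self.triples:
            counts[tp.equation_used] += 1
        return counts


def predict_mother_model3(
    record: MotherRecord,
    params: Model3Params = DEFAULT_MODEL3,
    term_weeks: float = 40.0,
    min_measures: int = DEFAULT_MIN_MEASURES,
    min_gap_days: int = DEFAULT_MIN_GAP_DAYS,
    variant: TripleVariant = "consecutive",
) -> MotherPrediction:
    """Multiple-measures prediction for one mother.

    Enumerates the mother's triples, applies the 3b/3a rule to each,
    projects every triple's GA to the final measurement date at one
    GA-week per calendar week, and averages.  The record must satisfy
    the inclusion rules (≥ ``min_measures`` measurements, adjacent gaps
    ≥ ``min_gap_days``).
    """
    ms = record.measurements
    if len(ms) < min_measures:
        raise ValueError(
            f"mother {record.mother_id}: a minimum of {min_measures} SFH "
            f"measurements is required (got {len(ms)})"
        )
    gaps = [(b.date - a.date).days for a, b in zip(ms, ms[1:])]
    if any(g < min_gap_days for g in gaps):
        raise ValueError(
            f"mother {record.mother_id}: measurements must be at least "
            f"{min_gap_days} days apart (shortest gap {min(gaps)} days)"
        )
    last = ms[-1].date
    triple_preds: list[TriplePrediction] = []
    projected: list[float] = []
    for tr in enumerate_triples(len(ms), variant=variant):
        i, j, k = tr.indices
        sub = (ms[i - 1], ms[j - 1], ms[k - 1])
        tp = predict_triple(sub, params, triple=tr)
        triple_preds.append(tp)
        projected.append(tp.ga_at_last.weeks + (last - sub[2].date).days / DAYS_PER_WEEK)
    ga = GA(sum(projected) / len(projected))
    return MotherPrediction(
        mother_id=record.mother_id,
        ga_at_last=ga,
        last_date=last,
        edd=edd_from_ga(ga, last, term_weeks),
        n_measurements=len(ms),
        triples=tuple(triple_preds),
        projected_ga=tuple(projected),
    )


def predict_cohort_model3(
    cohort: Cohort,
    params: Model3Params = DEFAULT_MODEL3,
    term_weeks: float = 40.0,
    **kwargs,
) -> dict[str, MotherPrediction]:
    """`predict_mother_model3` over a cohort, keyed by mother_id."""
    return {
        m.mother_id: predict_mother_model3(m, params, term_weeks, **kwargs)
        for m in cohort
    }


def predict_cohort_single(
    cohort: Cohort,
    single_measure_model: Callable[[float], GA],
    mode: MultiMeasureMode = "mean",
    term_weeks: float = 40.0,
) -> dict[str, MotherPrediction]:
    """Single-measure model (1 or 2) applied per mother, keyed by mother_id."""
    out: dict[str, MotherPrediction] = {}
    for m in cohort:
        ga = multi_measure_mean(m, single_measure_model, mode)
        out[m.mother_id] = MotherPrediction(
            mother_id=m.mother_id,
            ga_at_last=ga,
            last_date=m.last_date,
            edd=edd_from_ga(ga, m.last_date, term_weeks),
            n_measurements=m.n_measurements,
        )
    return out
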