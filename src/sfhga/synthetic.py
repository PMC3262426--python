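"""Synthetic antenatal cohort simulator.

Generates cohorts with the statistical structure of a serial-SFH
antenatal programme: mother-level heterogeneous fundal-height growth
curves (initially linear, then plateauing), integer-cm measurements on
a visit schedule, an error-free early-ultrasound anchor at the first
visit, and deliveries concentrated at 37–42 weeks with an induction
ceiling near 42 weeks that some mothers refuse.

The latent per-mother curve is the saturating exponential

    H(g) = P · (1 − exp(−r · (g − g0)))   for g > g0, else 0

with mother-level random plateau P (cm), rate r (1/week) and onset g0
(weeks).  This is deliberately a *different* family from the package's
predictive models, so that fitting them to simulated cohorts is a
genuine misspecified-model exercise.  Default heterogeneity is set so
that mothers measuring SFH = 20 cm span roughly ten weeks of
gestational age (90th − 10th percentile), the signature feature of
real serial-SFH data.

Recorded heights are rounded to the nearest centimetre (half-up) and
floored at 1 cm.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .core import (
    DAYS_PER_WEEK,
    Cohort,
    Measurement,
    MotherRecord,
    UltrasoundAnchor,
)

#: Calendar date assigned to gestational day 0 of the first simulated
#: mother; conception dates are spread over the two following years.
_BASE_DATE = dt.date(2002, 4, 1)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for :func:`simulate_cohort`.

    Curve family: plateau (cm), growth rate (1/week) and onset (weeks)
    are drawn per mother from independent normals; ``rate_sd_frac`` is
    the coefficient of variation of the rate.  Visits start uniformly
    in ``first_visit_ga`` weeks, repeat every ``visit_interval_days``
    until 34 weeks and every ``visit_interval_late_days`` after, and
    stop at delivery.  Delivery GA is normal, capped at the induction
    ceiling except for mothers who refuse induction.
    """

    n_mothers: int = 500
    seed: int = 0
    plateau_mean_cm: float = 35.0
    plateau_sd_cm: float = 4.0
    rate_mean: float = 0.105
    rate_sd_frac: float = 0.20
    onset_mean_weeks: float = 6.0
    onset_sd_weeks: float = 1.5
    noise_sd_cm: float = 1.5
    anchor_noise_sd_weeks: float = 0.0
    first_visit_ga: tuple[float, float] = (8.0, 14.0)
    visit_interval_days: int = 28
    visit_interval_late_days: int = 14
    late_schedule_from_weeks: float = 34.0
    delivery_mean_weeks: float = 39.5
    delivery_sd_weeks: float = 1.5
    induction_ceiling_weeks: float = 42.0
    refusal_probability: float = 0.1
    min_measurements: int = 3
    max_measurements: int = 16
    #: Optional injected covariate effects: weeks of true-GA offset per
    #: standard deviation of the covariate (e.g. {"weight_kg": 0.5}).
    #: The covariate shifts the mother's true (ultrasound) gestational
    #: age relative to what her fundal-height trajectory suggests, the
    #: kind of growth-status confounding a risk-factor adjustment is
    #: meant to detect.
    covariate_effects: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("plateau_sd_cm", "rate_sd_frac", "onset_sd_weeks",
                     "noise_sd_cm", "anchor_noise_sd_weeks", "delivery_sd_weeks"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        lo, hi = self.first_visit_ga
        if not (6.0 < lo < hi < 30.0):
            raise ValueError("first_visit_ga range must lie within (6, 30) weeks")
        if self.n_mothers < 1:
            raise ValueError("n_mothers must be at least 1")


def _latent_height(g: float, plateau: float, rate: float, onset: float) -> float:
    if g <= onset:
        return 0.0
    return plateau * (1.0 - math.exp(-rate * (g - onset)))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _draw_covariates(rng: np.random.Generator) -> dict[str, float]:
    weight = float(np.clip(rng.normal(48.0, 7.0), 30.0, 90.0))
    height = float(np.clip(rng.normal(1.51, 0.053), 1.30, 1.68))
    gravida = 1 + int(rng.poisson(2.0))
    parity = int(np.clip(gravida - 1 - rng.binomial(1, 0.2), 0, None))
    return {
        "weight_kg": round(weight, 1),
        "height_m": round(height, 2),
        "bmi": round(weight / height**2, 1),
        "age": float(int(np.clip(rng.normal(26.5, 6.6), 15, 48))),
        "gravida": float(gravida),
        "parity": float(parity),
        "smoker": float(rng.random() < 0.3),
        "pf": float(rng.random() < 0.04),
        "pv": float(rng.random() < 0.09),
    }


def _simulate_mother(
    idx: int, config: SimConfig, rng: np.random.Generator
) -> tuple[MotherRecord, dict]:
    """One mother; retried by the caller if she yields too few visits."""
    covs = _draw_covariates(rng)
    plateau = max(float(rng.normal(config.plateau_mean_cm, config.plateau_sd_cm)), 22.0)
    rate = max(
        float(rng.normal(config.rate_mean, config.rate_mean * config.rate_sd_frac)),
        0.02,
    )
    onset = float(rng.normal(config.onset_mean_weeks, config.onset_sd_weeks))
    # Injected covariate effects offset the true (ultrasound) GA from
    # the GA the fundal-height curve would suggest.
    _COV_SCALE = {"weight_kg": 7.0, "height_m": 0.053, "bmi": 2.8, "age": 6.6,
                  "gravida": 1.7, "parity": 1.6, "smoker": 0.46, "pf": 0.2, "pv": 0.29}
    _COV_MEAN = {"weight_kg": 48.0, "height_m": 1.51, "bmi": 21.0, "age": 26.5,
                 "gravida": 3.0, "parity": 1.8, "smoker": 0.3, "pf": 0.04, "pv": 0.09}
    ga_offset = 0.0
    for name, effect in config.covariate_effects.items():
        z = (covs[name] - _COV_MEAN[name]) / _COV_SCALE[name]
        ga_offset += effect * z

    delivery_ga = float(rng.normal(config.delivery_mean_weeks, config.delivery_sd_weeks))
    refused = bool(rng.random() < config.refusal_probability)
    if not refused:
        delivery_ga = min(delivery_ga, config.induction_ceiling_weeks)

    lmp = _BASE_DATE + dt.timedelta(days=int(rng.integers(0, 730)))
    first_ga = float(rng.uniform(*config.first_visit_ga))
    day = _round_half_up(first_ga * DAYS_PER_WEEK)
    delivery_day = _round_half_up(delivery_ga * DAYS_PER_WEEK)

    visit_days: list[int] = []
    while day <= delivery_day and len(visit_days) < config.max_measurements:
        visit_days.append(day)
        if day / DAYS_PER_WEEK < config.late_schedule_from_weeks:
            day += config.visit_interval_days
        else:
            day += config.visit_interval_late_days

    measurements = []
    for d in visit_days:
        g = d / DAYS_PER_WEEK
        mu = _latent_height(g, plateau, rate, onset)
        h = max(_round_half_up(mu + rng.normal(0.0, config.noise_sd_cm)), 1)
        measurements.append(Measurement(lmp + dt.timedelta(days=d), float(h)))

    anchor_ga = visit_days[0] / DAYS_PER_WEEK if visit_days else first_ga
    anchor_ga = max(anchor_ga + ga_offset, 1.0)
    if config.anchor_noise_sd_weeks > 0:
        anchor_ga = max(anchor_ga + rng.normal(0.0, config.anchor_noise_sd_weeks), 1.0)
    anchor = UltrasoundAnchor(
        anchor_date=lmp + dt.timedelta(days=visit_days[0] if visit_days else 0),
        ega_weeks=anchor_ga,
        method="CRL" if anchor_ga < 11.0 else "BPD",
    )
    record = MotherRecord(
        mother_id=f"m{idx:05d}",
        measurements=tuple(measurements),
        anchor=anchor,
        delivery_date=lmp + dt.timedelta(days=delivery_day),
        covariates=covs,
    )
    truth = {
        "mother_id": record.mother_id,
        "plateau_cm": plateau,
        "rate_per_week": rate,
        "onset_weeks": onset,
        "ga_offset_weeks": ga_offset,
        "delivery_ga_weeks": delivery_ga,
        "refused_induction": refused,
        "lmp_date": lmp.isoformat(),
    }
    return record, truth


def simulate_cohort(config: SimConfig) -> tuple[Cohort, pd.DataFrame]:
    """Simulate a cohort; returns (observable cohort, latent truth table).

    The cohort carries anchors, delivery dates and covariates; the
    truth table the latent curve parameters, true delivery GA and
    refusal flags.  Deterministic for a given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    mothers: list[MotherRecord] = []
    truths: list[dict] = []
    for idx in range(config.n_mothers):
        for attempt in range(100):
            record, truth = _simulate_mother(idx, config, rng)
            if record.n_measurements >= config.min_measurements:
                break
        else:
            raise RuntimeError(
                f"could not simulate ≥{config.min_measurements} visits for "
                f"mother {idx} in 100 attempts; check the visit schedule "
                "against the delivery distribution"
            )
        mothers.append(record)
        truths.append(truth)
    return Cohort(tuple(mothers)), pd.DataFrame(truths)


def simulate_single_measure_cohort(
    predictor,
    n_mothers: int,
    h_range: tuple[float, float],
    noise_sd_weeks: float,
    seed: int,
) -> Cohort:
    """Cohort for parameter-recovery studies of the single-measure models.

    Each mother contributes one SFH drawn uniformly from ``h_range``
    (whole centimetres are *not* enforced here: recovery studies probe
    the estimator, not the recording process) and an ultrasound anchor
    whose GA is ``predictor(h)`` plus Gaussian noise — i.e. the data are
    generated from the model relationship itself.
    """
    rng = np.random.default_rng(seed)
    mothers = []
    anchor_date = dt.date(2003, 1, 1)
    for i in range(n_mothers):
        h = float(rng.uniform(*h_range))
        ga = predictor(h).weeks + float(rng.normal(0.0, noise_sd_weeks))
        ga = max(ga, 0.5)
        # Encode the observed GA as an early anchor (EGA ≈ 8 weeks) plus
        # a whole-day date offset, with the anchor EGA absorbing the
        # rounding so the GA at the measurement date is exactly ``ga``.
        offset = _round_half_up((ga - 8.0) * DAYS_PER_WEEK)
        ega = ga - offset / DAYS_PER_WEEK
        date = anchor_date + dt.timedelta(days=offset)
        mothers.append(
            MotherRecord(
                mother_id=f"p{i:05d}",
                measurements=(Measurement(date, h),),
                anchor=UltrasoundAnchor(anchor_date=anchor_date, ega_weeks=ega),
            )
        )
    return Cohort(tuple(mothers))


@dataclass(frozen=True)
class CohortSummary:
    """Per-GA-week SFH profile plus the GA-spread diagnostic."""

    table: pd.DataFrame
    ga_spread_at_20cm: Optional[float]


def cohort_summary(cohort: Cohort, spread_sfh_cm: float = 20.0) -> CohortSummary:
    """Mean SFH and 10th/90th percentiles per integer GA week.

    Also reports the 90th − 10th percentile range of gestational age
    among measurements recording exactly ``spread_sfh_cm`` (the
    within-cohort GA spread at a fixed fundal height — about ten weeks
    in real serial-SFH data).
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    rows = []
    for mother in cohort:
        if mother.anchor is None:
            continue
        for m in mother.measurements:
            ga = mother.anchor.ega_weeks + (
                (m.date - mother.anchor.anchor_date).days / DAYS_PER_WEEK
            )
            rows.append((int(math.floor(ga)), ga, m.height))
    if not rows:
        raise ValueError("no anchored measurements to summarise")
    df = pd.DataFrame(rows, columns=["ga_week", "ga", "sfh_cm"])
    table = (
        df.groupby("ga_week")["sfh_cm"]
        .agg(
            mean_sfh="mean",
            p10=lambda s: s.quantile(0.10),
            p90=lambda s: s.quantile(0.90),
            n="count",
        )
        .reset_index()
    )
    at_h = df.loc[df["sfh_cm"] == spread_sfh_cm, "ga"]
    spread = (
        float(at_h.quantile(0.90) - at_h.quantile(0.10)) if len(at_h) >= 10 else None
    )
    return CohortSummary(table=table, ga_spread_at_20cm=spread)
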