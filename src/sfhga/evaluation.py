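"""Evaluation of gestational-age predictions against the ultrasound standard.

Implements the seven comparison criteria used to judge the models:

A. relative percentages of predicted premature / term / post-term births
   (model vs ultrasound);
B. 2×2 classification of premature birth (TP/TN/FP/FN, sensitivity,
   specificity, PPV, NPV);
C. the same for post-term birth;
D. histogram of predicted GA at birth (1-week bins);
E. histogram of residual error (predicted EDD − ultrasound EDD, days);
F. mean residual error;
G. percentage born within two weeks (|residual| ≤ 14 days, closed).

Plus the empirical 95% prediction interval of the residuals grouped by
the number of SFH measurements per mother, and a sweep of the premature
cutoff showing the sensitivity/specificity trade-off.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import DAYS_PER_WEEK, GA, Cohort, edd_from_ga, ga_at_date
from .models import MotherPrediction

logger = logging.getLogger(__name__)

PREMATURE = "premature"
TERM = "term"
POST_TERM = "post_term"
CATEGORIES = (PREMATURE, TERM, POST_TERM)

#: Default sweep of the premature-birth cutoff, weeks.
DEFAULT_CUTOFFS = tuple(np.round(np.arange(37.0, 39.0 + 1e-9, 0.2), 1))

#: Residual-group labels: by measurement count, pooling ten or more.
PI_GROUP_MAX = 10


def categorize_birth(ga_at_birth: GA) -> str:
    """Premature (<37), term (37 to <42) or post-term (≥42 weeks)."""
    w = ga_at_birth.weeks
    if w < 37.0:
        return PREMATURE
    if w < 42.0:
        return TERM
    return POST_TERM


@dataclass(frozen=True)
class ClassificationTable:
    """2×2 classification counts with the usual derived percentages.

    Undefined ratios (zero denominator) are ``None``, never 0.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    @staticmethod
    def _pct(num: int, den: int) -> Optional[float]:
        return 100.0 * num / den if den > 0 else None

    @property
    def sensitivity(self) -> Optional[float]:
        return self._pct(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Optional[float]:
        return self._pct(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> Optional[float]:
        return self._pct(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> Optional[float]:
        return self._pct(self.tn, self.tn + self.fn)

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def classification_table(
    truth: Sequence[str], predicted: Sequence[str], positive: str
) -> ClassificationTable:
    """Count a 2×2 table against the designated positive class."""
    if len(truth) != len(predicted):
        raise ValueError(f"length mismatch: {len(truth)} truth vs {len(predicted)} predicted")
    tp = tn = fp = fn = 0
    for t, p in zip(truth, predicted):
        if t == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ClassificationTable(tp=tp, tn=tn, fp=fp, fn=fn)


def cutoff_sweep(
    predicted_ga_birth: Sequence[float],
    true_ga_birth: Sequence[float],
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    true_cutoff: float = 37.0,
) -> pd.DataFrame:
    """Premature-cutoff sweep: PPV/NPV/sensitivity/specificity per cutoff.

    Truth-positive is an ultrasound GA at birth below ``true_cutoff``;
    predicted-positive a model GA at birth below the swept cutoff.
    """
    if len(cutoffs) == 0:
        raise ValueError("cutoffs must be non-empty")
    pred = np.asarray(predicted_ga_birth, float)
    true = np.asarray(true_ga_birth, float)
    if pred.shape != true.shape:
        raise ValueError("predicted and true GA arrays must have equal length")
    truth_pos = true < true_cutoff
    rows = []
    for c in cutoffs:
        pred_pos = pred < c
        tp = int(np.sum(pred_pos & truth_pos))
        fp = int(np.sum(pred_pos & ~truth_pos))
        fn = int(np.sum(~pred_pos & truth_pos))
        tn = int(np.sum(~pred_pos & ~truth_pos))
        t = ClassificationTable(tp=tp, tn=tn, fp=fp, fn=fn)
        rows.append(
            {
                "cutoff": float(c),
                "tp": tp,
                "tn": tn,
                "fp": fp,
                "fn": fn,
                "ppv": t.ppv,
                "npv": t.npv,
                "sensitivity": t.sensitivity,
                "specificity": t.specificity,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ResidualRecord:
    """Per-mother prediction error (model EDD − ultrasound EDD, days)."""

    mother_id: str
    residual_days: float
    n_measurements: int
    predicted_ga_at_birth: float
    us_ga_at_birth: float


def _pi_group(n_measurements: int, group_max: int = PI_GROUP_MAX) -> str:
    return f"≥{group_max}" if n_measurements >= group_max else str(n_measurements)


def prediction_interval_table(
    residuals: Sequence[ResidualRecord],
    group_max: int = PI_GROUP_MAX,
    percentile_rule: str = "linear",
) -> pd.DataFrame:
    """Empirical 95% prediction interval of residuals per measurement count.

    Groups are measurement counts 3..group_max−1 plus a pooled
    ``≥group_max`` group.  Bounds are the empirical 2.5th and 97.5th
    percentiles (linear interpolation between order statistics by
    default; ``percentile_rule="nearest-rank"`` for the alternative).
    Empty groups are omitted with a warning.
    """
    if percentile_rule not in ("linear", "nearest-rank"):
        raise ValueError(f"unknown percentile rule {percentile_rule!r}")
    method = "linear" if percentile_rule == "linear" else "closest_observation"
    by_group: dict[str, list[float]] = {}
    for r in residuals:
        by_group.setdefault(_pi_group(r.n_measurements, group_max), []).append(
            r.residual_days
        )
    rows = []
    labels = [str(n) for n in range(3, group_max)] + [f"≥{group_max}"]
    for label in labels:
        vals = by_group.get(label)
        if not vals:
            logger.warning("no residuals for measurement-count group %s; omitted", label)
            continue
        arr = np.asarray(vals, float)
        lo, hi = np.percentile(arr, [2.5, 97.5], method=method)
        rows.append(
            {
                "n_measurements": label,
                "lower_days": float(lo),
                "upper_days": float(hi),
                "n_mothers": int(arr.size),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EvaluationReport:
    """All seven criteria plus the interval and cutoff tables."""

    category_percentages: pd.DataFrame  # A
    premature_table: ClassificationTable  # B
    postterm_table: ClassificationTable  # C
    ga_histogram: pd.DataFrame  # D
    residual_histogram: pd.DataFrame  # E
    mean_residual_days: float  # F
    pct_within_two_weeks: float  # G
    prediction_interval_table: pd.DataFrame
    cutoff_table: pd.DataFrame
    residuals: tuple[ResidualRecord, ...]
    skipped: tuple[str, ...]

    @property
    def n_evaluated(self) -> int:
        return len(self.residuals)


def _week_histogram(values: np.ndarray, width: float) -> pd.DataFrame:
    lo = math.floor(values.min() / width) * width
    hi = math.ceil(values.max() / width) * width
    edges = np.arange(lo, hi + width, width)
    if len(edges) < 2:
        edges = np.array([lo, lo + width])
    counts, edges = np.histogram(values, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def evaluate(
    test: Cohort,
    predictions: Mapping[str, MotherPrediction],
    term_weeks: float = 40.0,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    percentile_rule: str = "linear",
) -> EvaluationReport:
    """Assemble the full evaluation report on a held-out cohort.

    Mothers without an ultrasound anchor, a delivery date or a
    prediction are skipped and logged.  Residuals are in days between
    the model EDD and the ultrasound-anchored EDD (equivalently GA
    differences at delivery); "within two weeks" is |residual| ≤ 14
    days, closed.
    """
    residuals: list[ResidualRecord] = []
    skipped: list[str] = []
    model_cats: list[str] = []
    us_cats: list[str] = []
    for mother in test:
        pred = predictions.get(mother.mother_id)
        if mother.anchor is None or mother.delivery_date is None or pred is None:
            if mother.anchor is None:
                reason = "missing ultrasound anchor"
            elif mother.delivery_date is None:
                reason = "missing delivery date"
            else:
                reason = "no prediction"
            logger.warning("skipping mother %s: %s", mother.mother_id, reason)
            skipped.append(mother.mother_id)
            continue
        us_ga_birth = ga_at_date(mother.anchor, mother.delivery_date)
        us_edd = edd_from_ga(us_ga_birth, mother.delivery_date, term_weeks)
        pred_ga_birth = pred.ga_at_last.weeks + (
            (mother.delivery_date - pred.last_date).days / DAYS_PER_WEEK
        )
        residual = float((pred.edd - us_edd).days)
        residuals.append(
            ResidualRecord(
                mother_id=mother.mother_id,
                residual_days=residual,
                n_measurements=mother.n_measurements,
                predicted_ga_at_birth=pred_ga_birth,
                us_ga_at_birth=us_ga_birth.weeks,
            )
        )
        model_cats.append(categorize_birth(GA(pred_ga_birth)))
        us_cats.append(categorize_birth(us_ga_birth))

    if not residuals:
        raise ValueError("no mothers could be evaluated (all skipped)")

    res_days = np.asarray([r.residual_days for r in residuals])
    pred_ga = np.asarray([r.predicted_ga_at_birth for r in residuals])
    us_ga = np.asarray([r.us_ga_at_birth for r in residuals])

    pct = {
        "category": list(CATEGORIES),
        "model_pct": [100.0 * model_cats.count(c) / len(model_cats) for c in CATEGORIES],
        "us_pct": [100.0 * us_cats.count(c) / len(us_cats) for c in CATEGORIES],
    }

    return EvaluationReport(
        category_percentages=pd.DataFrame(pct),
        premature_table=classification_table(us_cats, model_cats, PREMATURE),
        postterm_table=classification_table(us_cats, model_cats, POST_TERM),
        ga_histogram=_week_histogram(pred_ga, 1.0),
        residual_histogram=_week_histogram(res_days, 7.0),
        mean_residual_days=float(res_days.mean()),
        pct_within_two_weeks=float(100.0 * np.mean(np.abs(res_days) <= 14.0)),
        prediction_interval_table=prediction_interval_table(
            residuals, percentile_rule=percentile_rule
        ),
        cutoff_table=cutoff_sweep(pred_ga, us_ga, cutoffs),
        residuals=tuple(residuals),
        skipped=tuple(skipped),
    )


def plot_report(report: EvaluationReport, path: str) -> None:
    """Save the GA and residual histograms as a PNG (criteria D and E)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    h = report.ga_histogram
    ax1.bar(h["bin_left"], h["count"], width=h["bin_right"] - h["bin_left"],
            align="edge", edgecolor="k")
    ax1.set_xlabel("predicted GA at birth (weeks)")
    ax1.set_ylabel("mothers")
    r = report.residual_histogram
    ax2.bar(r["bin_left"], r["count"], width=r["bin_right"] - r["bin_left"],
            align="edge", edgecolor="k")
    ax2.set_xlabel("residual (model EDD − US EDD, days)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
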