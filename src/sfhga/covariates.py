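"""Risk-factor adjustment of the multiple-measures model.

Each mother-level factor (weight, height, BMI, age, gravidity, parity,
smoking, P. falciparum / P. vivax slide positivity) is tested one at a
time: the model-3 prediction is augmented with a single additive,
mean-centred linear term coefficient·(x − x̄), the coefficient is
refit with the base parameters held fixed, and the improvement in the
chi-squared fit is referred to the χ² distribution with one added
degree of freedom.

The comparison operates at the mother level — one observation per
mother, the ultrasound GA at her last measurement date against her
model-3 mean prediction — because a mother's triples share her growth
curve and are far from independent.  Because the residual variance of
GA predictions (weeks²) is much smaller than the predicted mean
(weeks), the raw chi-squared difference is not χ²₁-calibrated; the
significance test therefore uses the dispersion-scaled statistic

    Δχ² / (χ²_with / (N − 1))   ~  χ²₁ under the null,

the standard quasi-likelihood correction.  Both raw χ² values and the
scaled statistic are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2 as chi2_dist

from .core import COVARIATE_NAMES, Cohort, ga_at_date
from .fitting import CHI2_FLOOR_WEEKS
from .models import Model3Params, predict_mother_model3

#: Minimum fraction of mothers that must carry the covariate.
MIN_COVERAGE = 0.9

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class CovariateAdjustment:
    """Outcome of testing one risk factor."""

    covariate: str
    coefficient: float  # weeks per covariate unit
    chi2_without: float
    chi2_with: float
    delta_chi2: float
    scaled_delta: float
    dof_added: int
    significant: bool
    n_mothers: int


def adjust_for_covariate(
    train: Cohort,
    base: Model3Params,
    covariate: str,
    alpha: float = SIGNIFICANCE_LEVEL,
    floor: float = CHI2_FLOOR_WEEKS,
) -> CovariateAdjustment:
    """Fit and test a single additive covariate term on model-3 predictions.

    Mothers missing the covariate are dropped for this comparison; the
    covariate must be present for at least 90% of the anchored mothers.
    A constant covariate is not identifiable and raises.
    """
    if covariate not in COVARIATE_NAMES:
        raise ValueError(
            f"unknown covariate {covariate!r}; recognised risk factors are "
            f"{COVARIATE_NAMES}"
        )
    obs: list[float] = []
    pred: list[float] = []
    xs: list[float] = []
    n_eligible = 0
    for mother in train:
        if mother.anchor is None or mother.n_measurements < 3:
            continue
        n_eligible += 1
        if mother.covariates is None or covariate not in mother.covariates:
            continue
        mp = predict_mother_model3(mother, base)
        obs.append(ga_at_date(mother.anchor, mp.last_date).weeks)
        pred.append(mp.ga_at_last.weeks)
        xs.append(float(mother.covariates[covariate]))
    if n_eligible == 0:
        raise ValueError("no eligible mothers (need an anchor and ≥3 measurements)")
    if len(xs) < MIN_COVERAGE * n_eligible:
        raise ValueError(
            f"covariate {covariate!r} present for only {len(xs)}/{n_eligible} "
            f"mothers; at least {MIN_COVERAGE:.0%} coverage is required"
        )
    o = np.asarray(obs)
    p = np.asarray(pred)
    z = np.asarray(xs)
    z = z - z.mean()
    if np.allclose(z, 0.0):
        raise ValueError(
            f"covariate {covariate!r} is constant; its coefficient is not "
            "identifiable"
        )

    def chi2_of(beta: float) -> float:
        adj = p + beta * z
        return float(np.sum((o - adj) ** 2 / np.maximum(adj, floor)))

    chi2_without = chi2_of(0.0)
    # data-scaled search box: the optimal slope cannot exceed the ratio of
    # residual spread to covariate spread by much
    bound = 10.0 * (float(np.std(o - p)) / float(np.std(z)) + 1.0)
    res = minimize_scalar(chi2_of, bounds=(-bound, bound), method="bounded",
                          options={"xatol": 1e-8})
    beta = float(res.x)
    chi2_with = float(res.fun)
    if chi2_with > chi2_without:  # optimizer never beats beta = 0
        beta, chi2_with = 0.0, chi2_without
    delta = chi2_without - chi2_with
    n = o.size
    dispersion = chi2_with / max(n - 1, 1)
    scaled = delta / dispersion if dispersion > 0 else np.inf
    threshold = chi2_dist.ppf(1.0 - alpha, df=1)
    return CovariateAdjustment(
        covariate=covariate,
        coefficient=beta,
        chi2_without=chi2_without,
        chi2_with=chi2_with,
        delta_chi2=delta,
        scaled_delta=float(scaled),
        dof_added=1,
        significant=bool(scaled > threshold),
        n_mothers=int(n),
    )


def adjust_all_covariates(
    train: Cohort, base: Model3Params, alpha: float = SIGNIFICANCE_LEVEL
) -> list[CovariateAdjustment]:
    """Test every recognised risk factor, one at a time."""
    return [adjust_for_covariate(train, base, name, alpha) for name in COVARIATE_NAMES]
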