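"""Chi-squared objective, simplex fitting and the mother-level data split.

Goodness of fit is the Pearson-style chi-squared

    chi2 = sum_i (obs_i − pred_i)² / max(pred_i, ε),   ε = 0.5 weeks

— a weighted least squares in which the predicted mean stands proxy for
the variability; the floor ε guards against division blow-ups when a
candidate parameter vector predicts a near-zero GA.  Minimisation is by
the Nelder–Mead simplex (derivative-free; matches the switching rule of
model 3, which is not differentiable at the Gmin/Gmax boundaries).

The train/test protocol is mother-level: half the mothers (by default)
are randomly selected for fitting and the remainder held out for
evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize

from .core import DAYS_PER_WEEK, GA, Cohort, ga_at_date
from .models import (
    DEFAULT_MODEL1,
    DEFAULT_MODEL2,
    DEFAULT_MODEL3,
    Model1Params,
    Model2Params,
    Model3Params,
    enumerate_triples,
)

#: Floor on the chi-squared weighting denominator, weeks.
CHI2_FLOOR_WEEKS = 0.5

#: Large value returned for parameter vectors outside a model's domain,
#: scaled by the size of the violation so the simplex can walk back in.
_PENALTY = 1e12

_DEFAULTS = {1: DEFAULT_MODEL1, 2: DEFAULT_MODEL2, 3: DEFAULT_MODEL3}
_PARAM_TYPES = {1: Model1Params, 2: Model2Params, 3: Model3Params}

AnyParams = Union[Model1Params, Model2Params, Model3Params]


def chi2_objective(
    observed: Sequence[Union[float, GA]],
    predicted: Sequence[Union[float, GA]],
    floor: float = CHI2_FLOOR_WEEKS,
) -> float:
    """Σ (obs − pred)² / max(pred, floor) over paired GA values (weeks)."""
    obs = np.asarray([v.weeks if isinstance(v, GA) else v for v in observed], float)
    pred = np.asarray([v.weeks if isinstance(v, GA) else v for v in predicted], float)
    if obs.size == 0:
        raise ValueError("chi2_objective needs at least one observation pair")
    if obs.shape != pred.shape:
        raise ValueError(
            f"length mismatch: {obs.size} observed vs {pred.size} predicted"
        )
    return float(np.sum((obs - pred) ** 2 / np.maximum(pred, floor)))


def split_cohort(
    cohort: Cohort, fraction: float = 0.5, seed: int = 0
) -> tuple[Cohort, Cohort]:
    """Mother-level random train/test partition.

    ``round(fraction·N)`` mothers (half-up) go to the training half.
    Deterministic for a given seed; no mother appears in both halves.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    n = len(cohort)
    if n < 2:
        raise ValueError(f"cannot split a cohort of {n} mother(s)")
    rng = np.random.default_rng(seed)
    ids = list(cohort.ids)
    rng.shuffle(ids)
    n_train = int(np.floor(fraction * n + 0.5))
    train_ids, test_ids = ids[:n_train], ids[n_train:]
    return cohort.subset(train_ids), cohort.subset(test_ids)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a simplex fit."""

    model: int
    params: AnyParams
    objective_value: float
    n_iterations: int
    converged: bool
    n_obs: int
    train_ids: tuple[str, ...] = ()
    test_ids: tuple[str, ...] = ()
    notes: Mapping[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Observation extraction


def _pair_arrays(cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    """(SFH, ultrasound GA at that date) for every measurement."""
    hs: list[float] = []
    obs: list[float] = []
    for mother in cohort:
        if mother.anchor is None:
            raise ValueError(
                f"mother {mother.mother_id} has no ultrasound anchor; fitting "
                "requires an observed GA for every measurement"
            )
        for m in mother.measurements:
            hs.append(m.height)
            obs.append(ga_at_date(mother.anchor, m.date).weeks)
    return np.asarray(hs), np.asarray(obs)


def _triple_arrays(cohort: Cohort) -> dict[str, np.ndarray]:
    """Design arrays for the per-triple model-3 observations.

    For each triple: the three heights, the three pairwise gradients,
    the mean height and mean time-to-last-date (for eq. 3a), and the
    ultrasound GA at the triple's last measurement date.
    """
    cols: dict[str, list[float]] = {
        k: [] for k in ("h1", "h2", "h3", "s12", "s13", "s23", "mean_h", "mean_dt", "obs")
    }
    for mother in cohort:
        if mother.anchor is None:
            raise ValueError(
                f"mother {mother.mother_id} has no ultrasound anchor; fitting "
                "requires an observed GA for every triple"
            )
        ms = mother.measurements
        if len(ms) < 3:
            continue
        days = [(m.date - ms[0].date).days for m in ms]
        for tr in enumerate_triples(len(ms)):
            i, j, k = (x - 1 for x in tr.indices)
            h = (ms[i].height, ms[j].height, ms[k].height)
            t = (days[i], days[j], days[k])
            cols["h1"].append(h[0])
            cols["h2"].append(h[1])
            cols["h3"].append(h[2])
            cols["s12"].append((h[1] - h[0]) / ((t[1] - t[0]) / DAYS_PER_WEEK))
            cols["s13"].append((h[2] - h[0]) / ((t[2] - t[0]) / DAYS_PER_WEEK))
            cols["s23"].append((h[2] - h[1]) / ((t[2] - t[1]) / DAYS_PER_WEEK))
            cols["mean_h"].append(sum(h) / 3.0)
            cols["mean_dt"].append((2 * t[2] - t[0] - t[1]) / 3.0 / DAYS_PER_WEEK)
            cols["obs"].append(ga_at_date(mother.anchor, ms[k].date).weeks)
    if not cols["obs"]:
        raise ValueError("no triples available for fitting (need ≥3 measurements)")
    return {k: np.asarray(v) for k, v in cols.items()}


def model3_triple_predictions(arrays: Mapping[str, np.ndarray], p: Model3Params) -> np.ndarray:
    """Vectorised per-triple model-3 prediction (3b with 3a fallback)."""
    v3b = (
        p.c0
        + p.c1 * arrays["h1"]
        + p.c2 * arrays["h2"]
        + p.c3 * arrays["h3"]
        + p.k12 * arrays["s12"]
        + p.k13 * arrays["s13"]
        + p.k23 * arrays["s23"]
    )
    v3a = p.cL0 + p.cL1 * arrays["mean_h"] + arrays["mean_dt"]
    return np.where((v3b >= p.Gmin) & (v3b <= p.Gmax), v3b, v3a)


# ---------------------------------------------------------------------------
# Objectives over raw parameter vectors


def _objective_model1(v: np.ndarray, h: np.ndarray, obs: np.ndarray, floor: float) -> float:
    pred = v[0] + v[1] * h
    return float(np.sum((obs - pred) ** 2 / np.maximum(pred, floor)))


def _objective_model2(v: np.ndarray, h: np.ndarray, obs: np.ndarray, floor: float) -> float:
    b1, b2, b3 = v
    hmax = float(h.max())
    if b1 <= hmax:  # every height must sit below the saturation asymptote
        return _PENALTY * (1.0 + hmax - b1)
    if abs(b2) < 1e-8:
        return _PENALTY
    pred = b3 + np.log(h / (b1 - h)) / b2
    return float(np.sum((obs - pred) ** 2 / np.maximum(pred, floor)))


def _objective_model3(
    v: np.ndarray,
    arrays: Mapping[str, np.ndarray],
    floor: float,
    frozen_bounds: Optional[tuple[float, float]],
) -> float:
    if frozen_bounds is not None:
        params = Model3Params.from_vector(tuple(v) + frozen_bounds)
    else:
        params = Model3Params.from_vector(v)
    pred = model3_triple_predictions(arrays, params)
    return float(np.sum((arrays["obs"] - pred) ** 2 / np.maximum(pred, floor)))


def fit_model(
    train: Cohort,
    model: int,
    init: Optional[AnyParams] = None,
    options: Optional[Mapping[str, Any]] = None,
) -> FitResult:
    """Fit a model to a training cohort by chi-squared simplex.

    For models 1 and 2 the observation unit is each (SFH, ultrasound GA
    at that date) pair; for model 3 it is each triple's prediction
    against the ultrasound GA at the triple's last date.  ``options``:

    maxiter (default 5000), fatol (1e-6), xatol (1e-4), floor (chi2
    denominator floor, 0.5), freeze_bounds (model 3 only: hold Gmin and
    Gmax at their initial values and optimise the other 9 parameters).

    Non-convergence within the iteration cap is flagged on the result,
    not raised.
    """
    if model not in (1, 2, 3):
        raise ValueError(f"model must be 1, 2 or 3, got {model}")
    if len(train) == 0:
        raise ValueError("training cohort is empty")
    opts = dict(options or {})
    maxiter = int(opts.pop("maxiter", 5000))
    fatol = float(opts.pop("fatol", 1e-6))
    xatol = float(opts.pop("xatol", 1e-4))
    floor = float(opts.pop("floor", CHI2_FLOOR_WEEKS))
    freeze_bounds = bool(opts.pop("freeze_bounds", False))
    if opts:
        raise ValueError(f"unknown fit options: {sorted(opts)}")

    p0 = init if init is not None else _DEFAULTS[model]
    if not isinstance(p0, _PARAM_TYPES[model]):
        raise TypeError(
            f"init for model {model} must be {_PARAM_TYPES[model].__name__}"
        )

    notes: dict[str, Any] = {"floor": floor, "maxiter": maxiter}
    if model in (1, 2):
        h, obs = _pair_arrays(train)
        n_obs = obs.size
        if model == 1:
            fun = lambda v: _objective_model1(v, h, obs, floor)  # noqa: E731
        else:
            fun = lambda v: _objective_model2(v, h, obs, floor)  # noqa: E731
        x0 = np.asarray(p0.as_vector(), float)
    else:
        arrays = _triple_arrays(train)
        n_obs = arrays["obs"].size
        full = np.asarray(p0.as_vector(), float)
        if freeze_bounds:
            frozen = (float(full[-2]), float(full[-1]))
            x0 = full[:-2]
            notes["freeze_bounds"] = frozen
            fun = lambda v: _objective_model3(v, arrays, floor, frozen)  # noqa: E731
        else:
            x0 = full
            fun = lambda v: _objective_model3(v, arrays, floor, None)  # noqa: E731

    res = minimize(
        fun,
        x0,
        method="Nelder-Mead",
        options={
            "maxiter": maxiter,
            "maxfev": 4 * maxiter,
            "fatol": fatol,
            "xatol": xatol,
        },
    )
    vec = tuple(float(x) for x in res.x)
    if model == 3 and freeze_bounds:
        vec = vec + notes["freeze_bounds"]
    fitted = _PARAM_TYPES[model].from_vector(vec)
    return FitResult(
        model=model,
        params=fitted,
        objective_value=float(res.fun),
        n_iterations=int(res.nit),
        converged=bool(res.success),
        n_obs=int(n_obs),
        train_ids=train.ids,
        notes=notes,
    )
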