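"""CSV readers/writers, parameter-config parsing and the calculator core.

File formats (all plain text, dates ISO-8601):

* measurements CSV — ``mother_id,date,sfh_cm`` (one row per dated SFH;
  heights are whole centimetres);
* truth CSV — ``mother_id,anchor_date,ega_weeks,method,delivery_date``
  (method CRL or BPD; delivery_date may be blank);
* covariates CSV — ``mother_id,weight_kg,height_m,bmi,age,gravida,
  parity,smoker,pf,pv`` (flags 0/1; blanks allowed);
* parameter config — ``symbol = value`` lines, ``#`` comments.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .core import (
    COVARIATE_NAMES,
    Cohort,
    Measurement,
    MotherRecord,
    UltrasoundAnchor,
)
from .models import (
    Model1Params,
    Model2Params,
    Model3Params,
    MotherPrediction,
    predict_mother_model3,
)

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ("mother_id", "date", "sfh_cm")
TRUTH_COLUMNS = ("mother_id", "anchor_date", "ega_weeks", "method", "delivery_date")
COVARIATE_COLUMNS = ("mother_id",) + COVARIATE_NAMES

#: Template 95% prediction-interval lookup by number of measurements,
#: (lower, upper) days.  SYNTHETIC: produced by this package's own
#: pipeline — model 3 refit on one half of a simulated cohort
#: (SimConfig(n_mothers=3000, seed=0, first_visit_ga=(8, 28)), the wide
#: enrolment window populating every measurement-count group) and the
#: residual 95% interval evaluated on the held-out half, rounded to
#: whole days.  NOT from any real cohort: replace with the
#: prediction_intervals table from an evaluation run on your own data
#: before quoting accuracy bands to users.
SYNTHETIC_INTERVAL_TEMPLATE: dict[str, tuple[float, float]] = {
    "3": (-43.0, 37.0),
    "4": (-31.0, 41.0),
    "5": (-27.0, 40.0),
    "6": (-22.0, 40.0),
    "7": (-30.0, 28.0),
    "8": (-31.0, 23.0),
    "9": (-27.0, 21.0),
    "≥10": (-17.0, 20.0),
}


def _parse_date(value: str, where: str) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise ValueError(f"{where}: unparseable ISO-8601 date {value!r}") from exc


def _parse_float(value, where: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{where}: not a number: {value!r}") from exc


def _read_csv(path: Union[str, Path], required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    unknown = set(df.columns) - set(required)
    if unknown:
        raise ValueError(f"{path}: unknown column(s) {sorted(unknown)}")
    return df


def read_cohort(
    measurements_path: Union[str, Path],
    truth_path: Optional[Union[str, Path]] = None,
    covariates_path: Optional[Union[str, Path]] = None,
) -> Cohort:
    """Read a cohort from the long-format CSVs, joined on mother_id.

    Measurement series are sorted by date.  Malformed rows raise errors
    naming the row; truth/covariate rows without a matching mother are
    ignored with a warning.
    """
    mdf = _read_csv(measurements_path, MEASUREMENT_COLUMNS)
    series: dict[str, list[Measurement]] = {}
    seen: set[tuple[str, dt.date]] = set()
    for row in mdf.itertuples():
        where = f"{measurements_path} row {row.Index + 2}"  # 1-based + header
        mid = str(row.mother_id).strip()
        if not mid:
            raise ValueError(f"{where}: empty mother_id")
        date = _parse_date(row.date, where)
        h = _parse_float(row.sfh_cm, where)
        if h <= 0:
            raise ValueError(f"{where}: non-positive SFH {h}")
        if abs(h - round(h)) > 1e-9:
            raise ValueError(
                f"{where}: SFH {h} is not a whole number of centimetres "
                "(recorded fundal heights are rounded to the nearest cm)"
            )
        if (mid, date) in seen:
            raise ValueError(f"{where}: duplicate measurement for {mid} on {date}")
        seen.add((mid, date))
        series.setdefault(mid, []).append(Measurement(date, h))

    anchors: dict[str, UltrasoundAnchor] = {}
    deliveries: dict[str, dt.date] = {}
    if truth_path is not None:
        tdf = _read_csv(truth_path, TRUTH_COLUMNS)
        for row in tdf.itertuples():
            where = f"{truth_path} row {row.Index + 2}"
            mid = str(row.mother_id).strip()
            if mid not in series:
                logger.warning("%s: no measurements for mother %s; row ignored", where, mid)
                continue
            anchors[mid] = UltrasoundAnchor(
                anchor_date=_parse_date(row.anchor_date, where),
                ega_weeks=_parse_float(row.ega_weeks, where),
                method=str(row.method).strip(),
            )
            if str(row.delivery_date).strip():
                deliveries[mid] = _parse_date(row.delivery_date, where)

    covariates: dict[str, dict[str, float]] = {}
    if covariates_path is not None:
        cdf = _read_csv(covariates_path, COVARIATE_COLUMNS)
        for row in cdf.itertuples():
            where = f"{covariates_path} row {row.Index + 2}"
            mid = str(row.mother_id).strip()
            if mid not in series:
                logger.warning("%s: no measurements for mother %s; row ignored", where, mid)
                continue
            covariates[mid] = {
                name: _parse_float(getattr(row, name), where)
                for name in COVARIATE_NAMES
                if str(getattr(row, name)).strip() != ""
            }

    mothers = tuple(
        MotherRecord(
            mother_id=mid,
            measurements=tuple(sorted(ms, key=lambda m: m.date)),
            anchor=anchors.get(mid),
            delivery_date=deliveries.get(mid),
            covariates=covariates.get(mid),
        )
        for mid, ms in series.items()
    )
    return Cohort(mothers)


def write_cohort(
    cohort: Cohort,
    measurements_path: Union[str, Path],
    truth_path: Optional[Union[str, Path]] = None,
    covariates_path: Optional[Union[str, Path]] = None,
) -> None:
    """Write a cohort back to the three CSVs (inverse of read_cohort)."""
    mrows = [
        {"mother_id": m.mother_id, "date": meas.date.isoformat(),
         "sfh_cm": int(round(meas.height))}
        for m in cohort
        for meas in m.measurements
    ]
    pd.DataFrame(mrows, columns=list(MEASUREMENT_COLUMNS)).to_csv(
        measurements_path, index=False
    )
    if truth_path is not None:
        trows = [
            {
                "mother_id": m.mother_id,
                "anchor_date": m.anchor.anchor_date.isoformat(),
                "ega_weeks": repr(m.anchor.ega_weeks),
                "method": m.anchor.method,
                "delivery_date": m.delivery_date.isoformat() if m.delivery_date else "",
            }
            for m in cohort
            if m.anchor is not None
        ]
        pd.DataFrame(trows, columns=list(TRUTH_COLUMNS)).to_csv(truth_path, index=False)
    if covariates_path is not None:
        crows = []
        for m in cohort:
            if m.covariates is None:
                continue
            row = {"mother_id": m.mother_id}
            for name in COVARIATE_NAMES:
                row[name] = repr(m.covariates[name]) if name in m.covariates else ""
            crows.append(row)
        pd.DataFrame(crows, columns=list(COVARIATE_COLUMNS)).to_csv(
            covariates_path, index=False
        )


# ---------------------------------------------------------------------------
# Parameter configs

_PARAM_FIELDS = {
    1: ("a1", "a2"),
    2: ("b1", "b2", "b3"),
    3: Model3Params.FIELDS,
}
_PARAM_TYPES = {1: Model1Params, 2: Model2Params, 3: Model3Params}


def read_params_config(path: Union[str, Path], model: int):
    """Read a ``symbol = value`` config into the model's parameter set."""
    if model not in _PARAM_FIELDS:
        raise ValueError(f"model must be 1, 2 or 3, got {model}")
    values: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path} line {lineno}: expected 'symbol = value'")
        key, _, val = line.partition("=")
        values[key.strip()] = _parse_float(val.strip(), f"{path} line {lineno}")
    fields = _PARAM_FIELDS[model]
    missing = set(fields) - set(values)
    if missing:
        raise ValueError(f"{path}: missing parameter(s) {sorted(missing)} for model {model}")
    extra = set(values) - set(fields)
    if extra:
        raise ValueError(f"{path}: unknown parameter(s) {sorted(extra)} for model {model}")
    return _PARAM_TYPES[model](**{f: values[f] for f in fields})


def write_params_config(params, path: Union[str, Path]) -> None:
    """Write a parameter set as ``symbol = value`` lines."""
    for model, typ in _PARAM_TYPES.items():
        if isinstance(params, typ):
            fields = _PARAM_FIELDS[model]
            break
    else:
        raise TypeError(f"not a parameter set: {type(params).__name__}")
    lines = [f"{f} = {getattr(params, f)!r}" for f in fields]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# The calculator


@dataclass(frozen=True)
class CalculatorInput:
    """At least three dated SFH values, ≥14 days apart, dates increasing."""

    entries: tuple[tuple[dt.date, float], ...]

    def __post_init__(self) -> None:
        if len(self.entries) < 3:
            raise ValueError(
                f"a minimum of three SFH measurements with dates is required "
                f"(got {len(self.entries)})"
            )
        dates = [d for d, _ in self.entries]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("measurement dates must be strictly increasing")
        gaps = [(b - a).days for a, b in zip(dates, dates[1:])]
        if any(g < 14 for g in gaps):
            raise ValueError(
                f"measurements must be at least two weeks (14 days) apart "
                f"(shortest gap {min(gaps)} days)"
            )
        for d, h in self.entries:
            if h <= 0:
                raise ValueError(f"non-positive SFH {h} on {d}")


@dataclass(frozen=True)
class CalculatorResult:
    """EDD, GA at the last measurement, accuracy band and triple detail."""

    prediction: MotherPrediction
    interval_days: Optional[tuple[float, float]]

    @property
    def edd(self) -> dt.date:
        return self.prediction.edd


def calculate(
    inp: CalculatorInput,
    params: Model3Params = None,
    interval_table: Optional[Mapping[str, tuple[float, float]]] = None,
    term_weeks: float = 40.0,
) -> CalculatorResult:
    """Run the multiple-measures model on one mother's inputs.

    The accuracy band is looked up by measurement count from
    ``interval_table`` (default: the packaged synthetic-derived
    template; supply the table from an evaluation run on your own
    cohort for meaningful bands).
    """
    from .models import DEFAULT_MODEL3

    if params is None:
        params = DEFAULT_MODEL3
    if interval_table is None:
        interval_table = SYNTHETIC_INTERVAL_TEMPLATE
    record = MotherRecord(
        mother_id="calculator",
        measurements=tuple(Measurement(d, h) for d, h in inp.entries),
    )
    pred = predict_mother_model3(record, params, term_weeks=term_weeks)
    n = pred.n_measurements
    key = "≥10" if n >= 10 else str(n)
    interval = interval_table.get(key)
    return CalculatorResult(prediction=pred, interval_days=interval)
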