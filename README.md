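# sfhga — gestational age from serial fundal-height measurements

Many pregnant women in resource-poor settings reach antenatal care
without a reliable last menstrual period and without access to
ultrasound dating, so the expected date of delivery (EDD) has to be
inferred from what routine care does record: serial symphysis-pubis
fundal height (SFH) measurements, the distance in centimetres from the
pubic symphysis to the top of the uterine fundus. `sfhga` implements
and evaluates three SFH → gestational-age (GA) models, for midwives'
programme analysts, epidemiologists working with antenatal cohorts, and
anyone who needs a transparent, re-fittable SFH dating formula.

## The models

With `H` the fundal height (cm) and `G` the gestational age (weeks)
at the measurement date:

* **Model 1 (linear):** `G = a1 + a2·H` — the classical ≈1 cm/week
  calibration (defaults `a1 = 4.5`, `a2 = 1.0`).
* **Model 2 (nonlinear plateau):** fundal growth is initially linear
  and then plateaus near term; the package parameterises the curve as
  a logistic `H(G) = b1 / (1 + e^(−b2(G−b3)))` and predicts by
  inversion `G = b3 + ln(H/(b1−H))/b2` (defaults `b1 = 53.96`,
  `b2 = 0.055`, `b3 = 24.82`).
* **Model 3 (multiple measures):** for every "set of three" of a
  mother's measurements — index triples `(i, i+1, j)`, `j > i+1` — GA
  at the triple's last date is predicted either by the mean of three
  projected linear estimates
  `G = mean_i [cL0 + cL1·H_i + (t3−t_i)/7]` (eq. 3a) or by a
  combination of the three heights and the three pairwise SFH
  gradients `s_jk` (cm/week)
  `G = c0 + c1·H1 + c2·H2 + c3·H3 + k12·s12 + k13·s13 + k23·s23`
  (eq. 3b), the latter used whenever it falls inside `[Gmin, Gmax]`.
  The mother's prediction is the mean over her triples, each projected
  to her last measurement date; 11 parameters in all.

Models are fitted by minimising the Pearson-style chi-squared
`Σ (obs − pred)²/pred` with a Nelder–Mead simplex, on a random
mother-level half of the cohort, and evaluated on the other half:
premature/term/post-term classification, residual histograms and
95% prediction intervals by measurement count, and a sweep of the
prematurity cutoff. A synthetic antenatal-cohort simulator (mother-level
heterogeneous growth curves, integer-centimetre recording, realistic
visit schedules, a 42-week induction ceiling) stands in for real data
in all tests.

## Worked example

Predict an EDD from four dated measurements:

```sh
cat > series.csv <<EOF
date,sfh_cm
2024-01-05,28
2024-02-02,32
2024-03-01,34
2024-03-29,35
EOF
sfhga predict --input series.csv
```

```json
{
  "edd": "2024-04-07",
  "ga_at_last_measurement_weeks": 38.74,
  "last_measurement_date": "2024-03-29",
  "n_measurements": 4,
  "interval_days": [-31.0, 41.0],
  "equation_counts": {"combined_3b": 1, "fallback_3a": 2},
  "per_triple": [
    {"indices": [1, 2, 3], "ga_weeks": 37.87, "equation": "fallback_3a"},
    {"indices": [1, 2, 4], "ga_weeks": 40.85, "equation": "fallback_3a"},
    {"indices": [2, 3, 4], "ga_weeks": 33.51, "equation": "combined_3b"}
  ]
}
```

The four measurements yield three sets of three. Two land below the
`[Gmin, Gmax] = [33, 42]` trust window of the combined equation and
fall back to the linear mean; averaging the three projected estimates
puts this mother at 38.7 weeks on 29 March, an EDD of 7 April. The
accuracy band (−31 to +41 days here, for n = 4) comes from a packaged
*synthetic-data* template — replace it with the
`prediction_intervals.csv` of an evaluation run on your own cohort
before quoting bands clinically. A series with fewer than three
measurements, or with measurements under two weeks apart, is refused
rather than extrapolated.

The same pipeline is scriptable end to end:

```sh
sfhga simulate --n 500 --seed 1 --out-dir sim/
sfhga fit --model 3 --measurements sim/measurements.csv --truth sim/truth.csv \
          --seed 1 --out-params fitted.cfg
sfhga evaluate --measurements sim/measurements.csv --truth sim/truth.csv \
               --params fitted.cfg --out-dir eval/
sfhga covariates --measurements sim/measurements.csv --truth sim/truth.csv \
                 --covariates sim/covariates.csv --out cov.csv
```

## Layout

- `src/sfhga/core.py` — domain types, exclusion rules, GA/date arithmetic
- `src/sfhga/models.py` — the three models and the triple machinery
- `src/sfhga/fitting.py` — chi-squared objective, simplex, cohort split
- `src/sfhga/evaluation.py` — the seven criteria, intervals, cutoff sweep
- `src/sfhga/covariates.py` — mother-level risk-factor adjustment
- `src/sfhga/synthetic.py` — synthetic cohort simulator
- `src/sfhga/io.py`, `src/sfhga/cli.py` — CSV/config formats and the CLI

The default parameter sets are also shipped as editable plain-text
configs under `docs/params/` (`symbol = value` lines, accepted by every
`--params`/`--init` flag).

See `docs/methods.md` for the modelling assumptions, numerical choices
and known limitations.
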