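"""Shared fixtures: hand-built mothers and a small simulated cohort."""

from __future__ import annotations

import datetime as dt

import pytest

from sfhga import (
    Cohort,
    Measurement,
    MotherRecord,
    UltrasoundAnchor,
)
from sfhga.synthetic import SimConfig, simulate_cohort

D0 = dt.date(2003, 6, 1)


def make_mother(
    heights,
    days,
    mother_id="m1",
    anchor_ega=None,
    anchor_day=None,
    delivery_day=None,
    covariates=None,
    start=D0,
):
    """Build a MotherRecord from parallel height/day lists."""
    measurements = tuple(
        Measurement(start + dt.timedelta(days=d), float(h))
        for h, d in zip(heights, days)
    )
    anchor = None
    if anchor_ega is not None:
        anchor = UltrasoundAnchor(
            anchor_date=start + dt.timedelta(days=anchor_day or 0),
            ega_weeks=anchor_ega,
        )
    delivery = (
        start + dt.timedelta(days=delivery_day) if delivery_day is not None else None
    )
    return MotherRecord(
        mother_id=mother_id,
        measurements=measurements,
        anchor=anchor,
        delivery_date=delivery,
        covariates=covariates,
    )


@pytest.fixture
def simple_mother():
    """Three equally spaced measurements growing 1 cm/week."""
    return make_mother([20, 24, 28], [0, 28, 56], anchor_ega=20.0, anchor_day=0)


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-mother simulated cohort with anchors and deliveries."""
    cohort, truth = simulate_cohort(SimConfig(n_mothers=200, seed=11))
    return cohort


@pytest.fixture(scope="session")
def small_cohort_truth():
    cohort, truth = simulate_cohort(SimConfig(n_mothers=200, seed=11))
    return cohort, truth
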