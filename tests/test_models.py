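"""The three prediction models, triple enumeration and the fallback rule."""

from __future__ import annotations

import datetime as dt
import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from sfhga import (
    DEFAULT_MODEL1,
    DEFAULT_MODEL2,
    DEFAULT_MODEL3,
    Measurement,
    Model3Params,
    enumerate_triples,
    multi_measure_mean,
    predict_model1,
    predict_model2,
    predict_mother_model3,
    predict_triple,
    predict_triple_combined,
    predict_triple_linear,
    sfh_gradient,
)

from conftest import D0, make_mother


class TestModel1:
    def test_default_calibration(self):
        assert predict_model1(20.0).weeks == pytest.approx(24.5)
        assert predict_model1(35.5).weeks == pytest.approx(40.0)

    def test_non_positive_height_errors(self):
        with pytest.raises(ValueError):
            predict_model1(0.0)

    @given(h=st.floats(1.0, 44.0), dh=st.floats(0.1, 10.0))
    @settings(max_examples=50, derandomize=True)
    def test_strictly_increasing(self, h, dh):
        assert predict_model1(h + dh).weeks > predict_model1(h).weeks


class TestModel2:
    def test_matches_independent_inversion_of_forward_curve(self):
        """Oracle: numerically invert the forward plateau curve H(G)."""
        p = DEFAULT_MODEL2

        def forward(g):  # H as a function of G
            return p.b1 / (1.0 + math.exp(-p.b2 * (g - p.b3)))

        for h in (12.0, 20.0, 27.0, 35.0, 44.0):
            g_oracle = brentq(lambda g: forward(g) - h, 1e-6, 80.0, xtol=1e-12)
            assert predict_model2(h).weeks == pytest.approx(g_oracle, abs=1e-9)

    def test_monotone_over_valid_domain(self):
        grid = [12 + 0.5 * i for i in range(67)]  # 12 .. 45 cm
        values = [predict_model2(h).weeks for h in grid]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_asymptote_domain_error_names_bound(self):
        with pytest.raises(ValueError, match="53.96"):
            predict_model2(54.0)

    def test_low_height_domain_error(self):
        with pytest.raises(ValueError, match="non-positive"):
            predict_model2(5.0)


class TestEnumerateTriples:
    def test_five_measures_give_the_six_printed_triples(self):
        expected = [(1, 2, 3), (1, 2, 4), (1, 2, 5), (2, 3, 4), (2, 3, 5), (3, 4, 5)]
        assert [t.indices for t in enumerate_triples(5)] == expected

    def test_three_measures_single_triple(self):
        assert [t.indices for t in enumerate_triples(3)] == [(1, 2, 3)]

    @pytest.mark.parametrize("n", range(3, 17))
    def test_matches_brute_force_pattern_oracle(self, n):
        """Oracle: filter all 3-subsets for 'first two indices adjacent'."""
        oracle = [
            c
            for c in itertools.combinations(range(1, n + 1), 3)
            if c[1] == c[0] + 1
        ]
        got = [t.indices for t in enumerate_triples(n)]
        assert got == oracle
        assert len(got) == (n - 1) * (n - 2) // 2

    def test_too_few_measures_errors(self):
        with pytest.raises(ValueError):
            enumerate_triples(2)

    def test_all_subsets_variant(self):
        assert len(enumerate_triples(6, variant="all")) == 20


class TestGradient:
    def test_one_cm_per_week(self):
        a = Measurement(D0, 20.0)
        b = Measurement(D0 + dt.timedelta(days=28), 24.0)
        assert sfh_gradient(a, b) == pytest.approx(1.0)

    def test_flat_series_zero(self):
        a = Measurement(D0, 20.0)
        b = Measurement(D0 + dt.timedelta(days=21), 20.0)
        assert sfh_gradient(a, b) == 0.0

    def test_same_date_errors(self):
        a = Measurement(D0, 20.0)
        with pytest.raises(ValueError):
            sfh_gradient(a, Measurement(D0, 24.0))


def _triple(heights=(20, 24, 28), days=(0, 28, 56), start=D0):
    return tuple(
        Measurement(start + dt.timedelta(days=d), float(h))
        for h, d in zip(heights, days)
    )


class TestTripleEquations:
    def test_linear_mean_hand_value(self):
        # mean of (4.1 + 0.95·H_i + Δt_i/7): (31.1 + 30.9 + 30.7)/3
        assert predict_triple_linear(_triple()).weeks == pytest.approx(30.9)

    def test_combined_hand_value(self):
        # 12 + 1.1·20 + 0.24·24 − 0.7·28 + 0.09·1 + 7·1 − 0.1·1
        assert predict_triple_combined(_triple()).weeks == pytest.approx(27.15)

    def test_combined_reduces_to_height_terms_when_flat(self):
        ms = _triple(heights=(20, 20, 20))
        p = DEFAULT_MODEL3
        expected = p.c0 + (p.c1 + p.c2 + p.c3) * 20.0
        assert predict_triple_combined(ms).weeks == pytest.approx(expected)

    @pytest.mark.parametrize("shift", [-70, 7, 365])
    def test_date_shift_invariance(self, shift):
        base = _triple()
        moved = _triple(start=D0 + dt.timedelta(days=shift))
        assert predict_triple_linear(moved).weeks == predict_triple_linear(base).weeks
        assert (
            predict_triple_combined(moved).weeks == predict_triple_combined(base).weeks
        )

    def test_duplicate_dates_error(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            predict_triple_linear(_triple(days=(0, 28, 28)))


class TestFallbackRule:
    @staticmethod
    def _params_with_constant_3b(c0):
        return Model3Params(
            cL0=4.1, cL1=0.95, c0=c0, c1=0, c2=0, c3=0, k12=0, k13=0, k23=0,
            Gmin=33.0, Gmax=42.0,
        )

    def test_in_interval_uses_combined(self):
        tp = predict_triple(_triple(), self._params_with_constant_3b(36.0))
        assert tp.equation_used == "combined_3b"
        assert tp.ga_at_last.weeks == pytest.approx(36.0)

    def test_outside_interval_falls_back_unclamped(self):
        params = self._params_with_constant_3b(45.0)
        tp = predict_triple(_triple(), params)
        assert tp.equation_used == "fallback_3a"
        assert tp.ga_at_last.weeks == pytest.approx(
            predict_triple_linear(_triple(), params).weeks
        )

    def test_boundary_is_closed(self):
        tp = predict_triple(_triple(), self._params_with_constant_3b(33.0))
        assert tp.equation_used == "combined_3b"

    @given(
        h1=st.integers(10, 40),
        dh2=st.integers(-3, 6),
        dh3=st.integers(-3, 6),
        gap=st.integers(14, 42),
    )
    @settings(max_examples=100, derandomize=True)
    def test_fallback_invariant(self, h1, dh2, dh3, gap):
        """Equation choice ⇔ whether the combined value lies in [Gmin, Gmax]."""
        ms = _triple(heights=(h1, h1 + dh2, h1 + dh2 + dh3), days=(0, gap, 2 * gap))
        tp = predict_triple(ms)
        p = DEFAULT_MODEL3
        h = [m.height for m in ms]
        wk = gap / 7.0
        v3b = (p.c0 + p.c1 * h[0] + p.c2 * h[1] + p.c3 * h[2]
               + p.k12 * (h[1] - h[0]) / wk
               + p.k13 * (h[2] - h[0]) / (2 * wk)
               + p.k23 * (h[2] - h[1]) / wk)
        inside = p.Gmin <= v3b <= p.Gmax
        assert (tp.equation_used == "combined_3b") == inside
        if not inside:
            assert tp.ga_at_last.weeks == pytest.approx(
                predict_triple_linear(ms).weeks
            )


class TestMultiMeasureMean:
    def test_first_mode_projection_arithmetic(self):
        m = make_mother([20, 25, 30], [0, 35, 70])
        ga = multi_measure_mean(m, predict_model1, mode="first")
        assert ga.weeks == pytest.approx(24.5 + 10.0)

    def test_mid_of_five_uses_third(self):
        m = make_mother([10, 15, 20, 25, 30], [0, 28, 56, 84, 112])
        ga = multi_measure_mean(m, predict_model1, mode="mid")
        # third measurement: 4.5 + 20 projected 56 days = 8 weeks
        assert ga.weeks == pytest.approx(24.5 + 8.0)

    def test_mid_of_even_count_uses_earlier_central(self):
        m = make_mother([10, 15, 20, 25], [0, 28, 56, 84])
        ga = multi_measure_mean(m, predict_model1, mode="mid")
        assert ga.weeks == pytest.approx(4.5 + 15 + 8.0)

    def test_identical_projections_agree_across_modes(self):
        # heights grow exactly 1 cm/week so every projected estimate equals
        m = make_mother([20, 24, 28], [0, 28, 56])
        vals = {
            mode: multi_measure_mean(m, predict_model1, mode).weeks
            for mode in ("first", "mid", "mean")
        }
        assert vals["first"] == pytest.approx(vals["mid"])
        assert vals["first"] == pytest.approx(vals["mean"])

    def test_empty_series_errors(self):
        with pytest.raises(ValueError, match="empty"):
            multi_measure_mean(make_mother([], []), predict_model1)


class TestPredictMotherModel3:
    def test_three_measure_series_equals_single_triple(self, simple_mother):
        pred = predict_mother_model3(simple_mother)
        tp = predict_triple(simple_mother.measurements)
        assert pred.ga_at_last.weeks == pytest.approx(tp.ga_at_last.weeks)
        assert len(pred.triples) == 1

    def test_five_measure_series_matches_brute_force_oracle(self):
        """Oracle: plain-arithmetic re-derivation of all six triples."""
        heights = [14, 19, 23, 26, 28]
        days = [0, 28, 56, 84, 112]
        m = make_mother(heights, days)
        p = DEFAULT_MODEL3

        def oracle():
            total = 0.0
            trips = [(0, 1, 2), (0, 1, 3), (0, 1, 4), (1, 2, 3), (1, 2, 4), (2, 3, 4)]
            for i, j, k in trips:
                h = (heights[i], heights[j], heights[k])
                t = (days[i], days[j], days[k])
                s12 = (h[1] - h[0]) / ((t[1] - t[0]) / 7)
                s13 = (h[2] - h[0]) / ((t[2] - t[0]) / 7)
                s23 = (h[2] - h[1]) / ((t[2] - t[1]) / 7)
                v3b = (p.c0 + p.c1 * h[0] + p.c2 * h[1] + p.c3 * h[2]
                       + p.k12 * s12 + p.k13 * s13 + p.k23 * s23)
                if p.Gmin <= v3b <= p.Gmax:
                    v = v3b
                else:
                    v = sum(p.cL0 + p.cL1 * h[x] + (t[2] - t[x]) / 7
                            for x in range(3)) / 3
                total += v + (days[-1] - t[2]) / 7
            return total / 6

        pred = predict_mother_model3(m)
        assert pred.ga_at_last.weeks == pytest.approx(oracle(), abs=1e-12)

    def test_exclusion_rules_enforced(self):
        with pytest.raises(ValueError, match="minimum of 3"):
            predict_mother_model3(make_mother([20, 24], [0, 28]))
        with pytest.raises(ValueError, match="14 days apart"):
            predict_mother_model3(make_mother([20, 22, 24], [0, 10, 30]))

    @pytest.mark.parametrize("shift", [-30, 90])
    def test_date_shift_equivariance(self, shift):
        heights, days = [14, 19, 23, 26, 28], [0, 28, 56, 84, 112]
        base = predict_mother_model3(make_mother(heights, days))
        moved = predict_mother_model3(
            make_mother(heights, days, start=D0 + dt.timedelta(days=shift))
        )
        assert moved.ga_at_last.weeks == pytest.approx(base.ga_at_last.weeks)
        assert moved.edd == base.edd + dt.timedelta(days=shift)
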