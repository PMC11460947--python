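"""Windward-area model: projections, periods, accumulation, efficiency, stability."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from seedwind.windward import (
    DiasporeRotor,
    EvaluationMethod,
    InvalidParameterError,
    UnsupportedClosedFormError,
    accumulated_windward,
    control_accumulated,
    efficiency_report,
    fundamental_period,
    relative_efficiency,
    windward_area,
    windward_range,
    windward_series,
    windward_stability,
    wing_projection_angles,
)

SQRT2 = math.sqrt(2.0)
SQRT3 = math.sqrt(3.0)


def gauss_legendre_D(n: int, order: int = 60) -> float:
    """Independent quadrature oracle: per-piece Gauss-Legendre on the sorted-projection rule."""
    x, w = np.polynomial.legendre.leggauss(order)
    breakpoints = np.linspace(0.0, 2.0 * math.pi, 4 * n + 1)
    total = 0.0
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        t = 0.5 * (b - a) * x + 0.5 * (a + b)
        vals = []
        for theta in t:
            p = sorted(abs(math.sin(theta + 2 * math.pi * k / n)) for k in range(n))
            vals.append(p[0] if n == 1 else p[-1] + p[-2])
        total += 0.5 * (b - a) * float(np.dot(w, vals))
    return total


class TestWingProjectionAngles:
    @pytest.mark.parametrize(
        "n, theta, expected",
        [
            (1, 0.5, [0.5]),
            (3, 0.0, [0.0, 2 * math.pi / 3, 4 * math.pi / 3]),
            (4, math.pi / 4, [math.pi / 4, 3 * math.pi / 4, 5 * math.pi / 4, 7 * math.pi / 4]),
        ],
    )
    def test_symmetric_azimuths(self, n, theta, expected):
        assert wing_projection_angles(n, theta) == pytest.approx(expected)

    def test_reduced_mod_two_pi(self):
        angles = wing_projection_angles(3, 10.0)
        assert all(0.0 <= a < 2 * math.pi for a in angles)

    @pytest.mark.parametrize("bad_n", [0, -2])
    def test_nonpositive_wing_count_rejected(self, bad_n):
        with pytest.raises(InvalidParameterError):
            wing_projection_angles(bad_n, 0.0)

    def test_nonfinite_theta_rejected(self):
        with pytest.raises(InvalidParameterError):
            wing_projection_angles(2, math.inf)


class TestWindwardArea:
    @pytest.mark.parametrize(
        "n, theta, expected",
        [
            (2, math.pi / 2, 2.0),       # maximum of 2*|sin|
            (3, math.pi / 6, 1.5),       # lower end of the three-wing range
            (3, math.pi / 3, SQRT3),     # upper end of the three-wing range
            (4, math.pi / 4, SQRT2),     # four-wing domain endpoint
            (1, 0.0, 0.0),               # single wing edge-on
        ],
    )
    def test_printed_cases(self, n, theta, expected):
        rotor = DiasporeRotor(n=n, swing=1.0)
        assert windward_area(rotor, theta) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_for_five_wings(self, brute_force_windward):
        rotor = DiasporeRotor(n=5, swing=1.0)
        assert windward_area(rotor, 0.3) == pytest.approx(brute_force_windward(5, 0.3), abs=1e-12)

    @pytest.mark.parametrize("n", range(1, 9))
    def test_matches_brute_force_on_grid(self, n, brute_force_windward):
        rotor = DiasporeRotor(n=n, swing=1.0)
        thetas = np.linspace(-1.0, 7.0, 211)
        expected = [brute_force_windward(n, t) for t in thetas]
        np.testing.assert_allclose(windward_area(rotor, thetas), expected, atol=1e-12)

    def test_three_wing_closed_form_on_fundamental_domain(self):
        # sqrt(3)*cos(pi/3 - theta) on [pi/6, pi/3]
        rotor = DiasporeRotor(n=3, swing=1.0)
        thetas = np.linspace(math.pi / 6, math.pi / 3, 101)
        expected = SQRT3 * np.cos(math.pi / 3 - thetas)
        np.testing.assert_allclose(windward_area(rotor, thetas), expected, atol=1e-12)

    def test_four_wing_closed_form_everywhere(self):
        rotor = DiasporeRotor(n=4, swing=1.0)
        thetas = np.linspace(0.0, 2 * math.pi, 401)
        expected = 2.0 * np.maximum(np.abs(np.sin(thetas)), np.abs(np.cos(thetas)))
        np.testing.assert_allclose(windward_area(rotor, thetas), expected, atol=1e-12)

    @pytest.mark.parametrize(
        "n, lo, hi",
        [(1, 0.0, 1.0), (2, 0.0, 2.0), (3, 1.5, SQRT3), (4, SQRT2, 2.0)],
    )
    def test_bounds_per_wing_count(self, n, lo, hi):
        rotor = DiasporeRotor(n=n, swing=1.0)
        values = windward_area(rotor, np.linspace(0.0, 2 * math.pi, 2001))
        assert values.min() >= lo - 1e-12
        assert values.max() <= hi + 1e-12

    def test_series_container_carries_rotor(self):
        rotor = DiasporeRotor(n=3, swing=2.0)
        thetas = np.linspace(0.0, 2 * math.pi, 16, endpoint=False)
        series = windward_series(rotor, thetas)
        assert series.rotor is rotor
        assert np.all(series.values >= 0.0)
        assert np.all(series.values <= 2.0 * rotor.swing)

    @pytest.mark.parametrize(
        "kwargs", [dict(n=0), dict(n=2, swing=0.0), dict(n=2, swing=-1.0), dict(n=2, r=-3.0)]
    )
    def test_invalid_rotor_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            DiasporeRotor(**{"swing": 1.0, **kwargs})

    def test_tip_radius_never_enters_computation(self):
        with_r = DiasporeRotor(n=3, swing=1.0, r=15.0)
        without_r = DiasporeRotor(n=3, swing=1.0)
        assert windward_area(with_r, 0.7) == windward_area(without_r, 0.7)
        assert relative_efficiency(with_r).er == relative_efficiency(without_r).er


class TestFundamentalPeriod:
    @pytest.mark.parametrize(
        "n, expected",
        [(1, math.pi), (2, math.pi), (3, math.pi / 3), (4, math.pi / 2), (5, math.pi / 5), (6, math.pi / 3)],
    )
    def test_values(self, n, expected):
        assert fundamental_period(n) == pytest.approx(expected)

    @pytest.mark.parametrize("n", range(1, 9))
    def test_periodicity_on_dense_grid(self, n):
        rotor = DiasporeRotor(n=n, swing=1.0)
        period = fundamental_period(n)
        thetas = np.linspace(0.0, 2 * math.pi, 1000)
        np.testing.assert_allclose(
            windward_area(rotor, thetas), windward_area(rotor, thetas + period), atol=1e-12
        )

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_no_shorter_period(self, n):
        # half the fundamental period must NOT be a period
        rotor = DiasporeRotor(n=n, swing=1.0)
        half = fundamental_period(n) / 2.0
        thetas = np.linspace(0.0, 2 * math.pi, 1000)
        diff = np.abs(windward_area(rotor, thetas) - windward_area(rotor, thetas + half))
        assert diff.max() > 1e-3

    def test_invalid_count_rejected(self):
        with pytest.raises(InvalidParameterError):
            fundamental_period(0)


class TestAccumulatedWindward:
    @pytest.mark.parametrize(
        "n, expected",
        [(1, 4.0), (2, 8.0), (3, 6.0 * SQRT3), (4, 8.0 * SQRT2)],
    )
    def test_closed_forms(self, n, expected):
        rotor = DiasporeRotor(n=n, swing=1.0)
        assert accumulated_windward(rotor, "closed_form") == pytest.approx(expected, rel=1e-15)

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_quadrature_matches_closed_form(self, n):
        rotor = DiasporeRotor(n=n, swing=1.0)
        closed = accumulated_windward(rotor, "closed_form")
        quad = accumulated_windward(rotor, "quadrature")
        assert quad == pytest.approx(closed, rel=1e-9)

    @pytest.mark.parametrize("n", [5, 6, 7, 8])
    def test_quadrature_matches_independent_oracle_beyond_closed_forms(self, n):
        rotor = DiasporeRotor(n=n, swing=1.0)
        assert accumulated_windward(rotor, "quadrature") == pytest.approx(
            gauss_legendre_D(n), rel=1e-9
        )

    def test_closed_form_unavailable_above_four_wings(self):
        with pytest.raises(UnsupportedClosedFormError):
            accumulated_windward(DiasporeRotor(n=5, swing=1.0), "closed_form")

    def test_scales_linearly_with_swing(self):
        base = accumulated_windward(DiasporeRotor(n=3, swing=1.0), "closed_form")
        assert accumulated_windward(DiasporeRotor(n=3, swing=37.5), "closed_form") == pytest.approx(
            37.5 * base
        )


class TestControlAccumulated:
    @pytest.mark.parametrize(
        "n, swing, expected",
        [(2, 1.0, 4 * math.pi), (1, 1.0, 2 * math.pi), (3, 1.0, 4 * math.pi), (7, 2.0, 8 * math.pi)],
    )
    def test_two_wing_cap(self, n, swing, expected):
        assert control_accumulated(n, swing) == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            control_accumulated(0, 1.0)
        with pytest.raises(InvalidParameterError):
            control_accumulated(2, 0.0)


class TestRelativeEfficiency:
    @pytest.mark.parametrize(
        "n, expected",
        [
            (1, 2.0 / math.pi),
            (2, 2.0 / math.pi),
            (3, 3.0 * SQRT3 / (2.0 * math.pi)),
            (4, 2.0 * SQRT2 / math.pi),
        ],
    )
    def test_exact_fractions(self, n, expected):
        res = relative_efficiency(DiasporeRotor(n=n, swing=1.0))
        assert res.er == pytest.approx(expected, rel=1e-12)
        assert res.er == pytest.approx(res.d_rotating / res.d_control, rel=1e-15)

    @pytest.mark.parametrize(
        "n, percent", [(1, 63.66), (2, 63.66), (3, 82.70), (4, 90.03)]
    )
    def test_printed_percentages(self, n, percent):
        res = relative_efficiency(DiasporeRotor(n=n, swing=1.0))
        assert round(res.er_percent, 2) == pytest.approx(percent)

    def test_ordering_across_wing_counts(self):
        er = {n: relative_efficiency(DiasporeRotor(n=n, swing=1.0)).er for n in (1, 2, 3, 4)}
        assert er[4] > er[3] > er[2]
        assert er[1] == pytest.approx(er[2], rel=1e-12)

    @pytest.mark.parametrize("n", range(1, 9))
    def test_er_is_a_fraction_in_unit_interval(self, n):
        res = relative_efficiency(DiasporeRotor(n=n, swing=1.0))
        assert 0.0 < res.er <= 1.0

    def test_extrapolation_flagged_beyond_four_wings(self):
        assert not relative_efficiency(DiasporeRotor(n=4, swing=1.0)).extrapolated
        res5 = relative_efficiency(DiasporeRotor(n=5, swing=1.0))
        assert res5.extrapolated and res5.method is EvaluationMethod.QUADRATURE

    @given(st.sampled_from([0.1, 1.0, 37.5]), st.integers(min_value=1, max_value=6))
    def test_scale_invariance_in_swing(self, swing, n):
        unit = relative_efficiency(DiasporeRotor(n=n, swing=1.0))
        scaled = relative_efficiency(DiasporeRotor(n=n, swing=swing))
        assert scaled.er == pytest.approx(unit.er, rel=1e-9)


class TestWindwardStability:
    @pytest.mark.parametrize(
        "n, expected",
        [(1, 0.0), (2, 0.0), (3, SQRT3 / 2.0), (4, SQRT2 / 2.0)],
    )
    def test_known_ratios(self, n, expected):
        assert windward_stability(DiasporeRotor(n=n, swing=1.0)) == pytest.approx(
            expected, abs=1e-9
        )

    def test_three_wings_most_stable(self):
        s = {n: windward_stability(DiasporeRotor(n=n, swing=1.0)) for n in (1, 2, 3, 4)}
        assert s[3] > s[4] > s[2] == pytest.approx(0.0, abs=1e-12)
        assert s[1] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("swing", [0.1, 1.0, 37.5])
    def test_scale_invariant(self, swing):
        assert windward_stability(DiasporeRotor(n=3, swing=swing)) == pytest.approx(
            SQRT3 / 2.0, abs=1e-9
        )

    @pytest.mark.parametrize(
        "n, lo, hi",
        [(3, 1.5, SQRT3), (4, SQRT2, 2.0)],
    )
    def test_range_endpoints_match_printed_bounds(self, n, lo, hi):
        got_lo, got_hi = windward_range(DiasporeRotor(n=n, swing=1.0))
        assert got_lo == pytest.approx(lo, abs=1e-9)
        assert got_hi == pytest.approx(hi, abs=1e-9)


def test_efficiency_report_schema():
    report = efficiency_report(DiasporeRotor(n=3, swing=1.0))
    assert set(report) == {"n", "D_rotating", "D_control", "Er_percent", "method", "stability"}
    assert report["n"] == 3
    assert report["Er_percent"] == pytest.approx(82.6993, abs=1e-3)
    assert report["method"] == "closed_form"
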