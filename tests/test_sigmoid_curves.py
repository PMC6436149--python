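import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from hydrotraits.errors import InsufficientDataError, InvalidInputError, NonIdentifiableError
from hydrotraits.sigmoid_curves import (
    LN_22_3,
    ResponsePoint,
    SigmoidFit,
    Thresholds,
    fit_sigmoid,
    percent_at,
    pressure_at_percent,
    thresholds_of,
)

from conftest import GROUP_PARAMS


def model_points(a, p50, pressures):
    fit = SigmoidFit(a=a, p50=p50)
    return [ResponsePoint(p, percent_at(fit, p)) for p in pressures]


def grid_search_fit(points, a_range=(0.1, 4.0), p_range=(-9.0, -0.5), n=241):
    """Independent exhaustive-search oracle for the least-squares optimum."""
    pressures = np.array([p.pressure for p in points])
    percents = np.array([p.percent for p in points])
    a_grid = np.linspace(*a_range, n)
    p_grid = np.linspace(*p_range, n)
    best = (math.inf, None, None)
    for a in a_grid:
        pred = 100.0 / (1.0 + np.exp(a * (pressures[None, :] - p_grid[:, None])))
        sse = np.sum((pred - percents[None, :]) ** 2, axis=1)
        i = int(np.argmin(sse))
        if sse[i] < best[0]:
            best = (float(sse[i]), float(a), float(p_grid[i]))
    return best[1], best[2]


class TestPercentAt:
    def test_midpoint_is_50(self, golden_control_fit):
        assert percent_at(golden_control_fit, -5.00) == pytest.approx(50.0)

    def test_published_p12_consistent(self, golden_control_fit):
        # the printed P12 of the same group corresponds to ~12% response
        assert percent_at(golden_control_fit, -2.90) == pytest.approx(12.0, abs=0.2)

    def test_direct_evaluation_at_zero(self, golden_control_fit):
        # 100 / (1 + e^{0.95 * 5.00})
        assert percent_at(golden_control_fit, 0.0) == pytest.approx(
            100.0 / (1.0 + math.exp(4.75)), rel=1e-12
        )
        assert percent_at(golden_control_fit, 0.0) == pytest.approx(0.857, abs=1e-3)

    def test_rejects_non_finite_pressure(self, golden_control_fit):
        with pytest.raises(InvalidInputError):
            percent_at(golden_control_fit, math.nan)

    @given(st.floats(-10.0, 0.0), st.floats(-10.0, 0.0))
    def test_strictly_decreasing(self, p1, p2):
        assume(abs(p1 - p2) > 1e-9)  # below float resolution of exp()
        fit = SigmoidFit(a=1.2, p50=-4.0)
        if p1 < p2:
            assert percent_at(fit, p1) > percent_at(fit, p2)
        else:
            assert percent_at(fit, p1) < percent_at(fit, p2)

    @given(st.floats(-50.0, 10.0))
    def test_bounded(self, p):
        fit = SigmoidFit(a=0.7, p50=-3.3)
        assert 0.0 < percent_at(fit, p) < 100.0


class TestPressureAtPercent:
    def test_level_50_is_p50(self, golden_control_fit):
        assert pressure_at_percent(golden_control_fit, 50) == pytest.approx(-5.00)

    @pytest.mark.parametrize(
        "group,level,col",
        [("golden_fertilized", 12, 2), ("red_control", 88, 3)],
    )
    def test_published_thresholds(self, group, level, col):
        a, p50, p12, p88 = GROUP_PARAMS[group]
        expected = p12 if level == 12 else p88
        fit = SigmoidFit(a=a, p50=p50)
        assert pressure_at_percent(fit, level) == pytest.approx(expected, abs=0.01)

    @pytest.mark.parametrize("level", [0.0, 100.0, -3.0, 120.0])
    def test_domain_error(self, golden_control_fit, level):
        with pytest.raises(InvalidInputError):
            pressure_at_percent(golden_control_fit, level)

    @given(
        st.floats(0.3, 3.0),
        st.floats(-8.0, -1.0),
        st.floats(-12.0, -0.01),
    )
    @settings(max_examples=200)
    def test_inversion_round_trip(self, a, p50, pressure):
        # deep in the tails (|a*(P-p50)| >> 10) the level is within float
        # epsilon of 0 or 100 and the log inversion loses precision
        assume(abs(a * (pressure - p50)) < 10.0)
        fit = SigmoidFit(a=a, p50=p50)
        level = percent_at(fit, pressure)
        assert pressure_at_percent(fit, level) == pytest.approx(pressure, abs=1e-9)


class TestThresholdsOf:
    def test_published_red_fertilized(self):
        a, p50, p12, p88 = GROUP_PARAMS["red_fertilized"]
        thr = thresholds_of(SigmoidFit(a=a, p50=p50))
        assert thr.p12 == pytest.approx(p12, abs=0.01)
        assert thr.p88 == pytest.approx(p88, abs=0.01)

    def test_hand_arithmetic(self):
        thr = thresholds_of(SigmoidFit(a=2.0, p50=-3.0))
        assert thr.p12 == pytest.approx(-3.0 + LN_22_3 / 2.0, rel=1e-12)
        assert thr.p12 == pytest.approx(-2.004, abs=1e-3)
        assert thr.p88 == pytest.approx(-3.996, abs=1e-3)

    @given(st.floats(0.3, 3.0), st.floats(-8.0, -1.0))
    def test_symmetry(self, a, p50):
        thr = thresholds_of(SigmoidFit(a=a, p50=p50))
        assert thr.p12 - thr.p50 == pytest.approx(thr.p50 - thr.p88, rel=1e-12)
        assert thr.p12 + thr.p88 == pytest.approx(2 * thr.p50, rel=1e-12)

    def test_ordering_enforced(self):
        with pytest.raises(InvalidInputError):
            Thresholds(p12=-5.0, p50=-4.0, p88=-3.0)


class TestFitSigmoid:
    def test_noiseless_self_consistency(self):
        pts = model_points(0.95, -5.00, np.arange(-1.0, -8.5, -1.0))
        fit = fit_sigmoid(pts)
        assert fit.a == pytest.approx(0.95, rel=1e-6)
        assert fit.p50 == pytest.approx(-5.00, rel=1e-6)
        assert fit.residual_sse == pytest.approx(0.0, abs=1e-12)

    def test_three_anchor_points_plus_midpoint(self):
        # 12/50/88 anchors force the closed-form symmetric solution
        pts = [
            ResponsePoint(-2.0, 12.0),
            ResponsePoint(-3.0, 50.0),
            ResponsePoint(-4.0, 88.0),
            ResponsePoint(-3.0, 50.0),
        ]
        fit = fit_sigmoid(pts)
        assert fit.a == pytest.approx(LN_22_3, rel=1e-6)  # ln(22/3)/1 MPa spacing
        assert fit.a == pytest.approx(1.9924, abs=1e-4)
        assert fit.p50 == pytest.approx(-3.0, rel=1e-6)

    def test_grid_search_oracle_agreement(self, rng):
        a_true, p50_true = 1.3, -3.7
        pts = model_points(a_true, p50_true, np.arange(-0.5, -8.0, -0.75))
        noisy = [
            ResponsePoint(p.pressure, p.percent + rng.normal(0, 4.0)) for p in pts
        ]
        fit = fit_sigmoid(noisy)
        a_grid, p50_grid = grid_search_fit(noisy)
        # agreement to grid resolution
        assert fit.a == pytest.approx(a_grid, abs=(4.0 - 0.1) / 240)
        assert fit.p50 == pytest.approx(p50_grid, abs=(9.0 - 0.5) / 240)

    def test_insufficient_points(self):
        pts = model_points(1.0, -4.0, [-1.0, -4.0, -7.0])
        with pytest.raises(InsufficientDataError):
            fit_sigmoid(pts)

    def test_degenerate_constant_percent(self):
        pts = [ResponsePoint(p, 50.0) for p in (-1.0, -2.0, -3.0, -4.0)]
        with pytest.raises(NonIdentifiableError):
            fit_sigmoid(pts)

    def test_one_sided_percents(self):
        pts = [ResponsePoint(p, v) for p, v in [(-1, 55), (-2, 70), (-3, 85), (-4, 95)]]
        with pytest.raises(NonIdentifiableError):
            fit_sigmoid(pts)

    def test_zero_pressure_spread(self):
        pts = [ResponsePoint(-3.0, v) for v in (10.0, 40.0, 60.0, 90.0)]
        with pytest.raises(NonIdentifiableError):
            fit_sigmoid(pts)

    def test_accepts_bare_pairs_and_unclipped_percents(self):
        pts = [(-1.0, -2.5), (-3.0, 30.0), (-4.0, 70.0), (-6.0, 103.0)]
        fit = fit_sigmoid(pts)
        assert fit.a > 0 and fit.p50 < 0

    @pytest.mark.parametrize("a_true,p50_true", [(0.3, -8.0), (3.0, -1.0), (1.0, -4.5)])
    def test_noiseless_recovery_extremes(self, a_true, p50_true):
        pressures = np.linspace(-0.25, -10.0, 14)
        fit = fit_sigmoid(model_points(a_true, p50_true, pressures))
        assert fit.a == pytest.approx(a_true, rel=1e-6)
        assert fit.p50 == pytest.approx(p50_true, rel=1e-6)


class TestValidation:
    def test_positive_pressure_rejected(self):
        with pytest.raises(InvalidInputError, match="negative-MPa"):
            ResponsePoint(pressure=2.5, percent=50.0)

    def test_invalid_fit_parameters(self):
        with pytest.raises(InvalidInputError):
            SigmoidFit(a=-1.0, p50=-4.0)
        with pytest.raises(InvalidInputError):
            SigmoidFit(a=1.0, p50=1.0)
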