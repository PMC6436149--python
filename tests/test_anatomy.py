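import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydrotraits.anatomy import (
    ConduitSet,
    PitGeometry,
    diameter_from_area,
    diameter_histogram,
    hierarchical_mean,
    hydraulic_diameter,
    ring_width,
    wall_reinforcement,
)
from hydrotraits.errors import InsufficientDataError, InvalidInputError


def brute_force_dh(diameters):
    """Independent oracle: plain Python loop over sum(d^5)/sum(d^4)."""
    num = sum(d**5 for d in diameters)
    den = sum(d**4 for d in diameters)
    return num / den


class TestDiameterFromArea:
    def test_unit_circle(self):
        assert diameter_from_area(math.pi) == pytest.approx(2.0, rel=1e-12)

    def test_hand_arithmetic(self):
        assert diameter_from_area(100.0) == pytest.approx(11.284, abs=1e-3)

    def test_scaling_law(self):
        assert diameter_from_area(50.0) * math.sqrt(2) == pytest.approx(
            diameter_from_area(100.0), rel=1e-12
        )

    @given(st.floats(1e-6, 1e6))
    def test_round_trip_with_circle_area(self, area):
        d = diameter_from_area(area)
        assert math.pi * (d / 2.0) ** 2 == pytest.approx(area, rel=1e-9)

    def test_non_positive_rejected(self):
        with pytest.raises(InvalidInputError):
            diameter_from_area(0.0)


class TestHydraulicDiameter:
    def test_equal_diameters(self):
        assert hydraulic_diameter([17.0] * 6) == pytest.approx(17.0)

    def test_hand_arithmetic_pair(self):
        # (10^5 + 20^5) / (10^4 + 20^4)
        assert hydraulic_diameter([10.0, 20.0]) == pytest.approx(19.412, abs=1e-3)

    def test_singleton(self):
        assert hydraulic_diameter([22.0]) == pytest.approx(22.0)

    @given(st.lists(st.floats(1.0, 100.0), min_size=1, max_size=50))
    @settings(max_examples=100)
    def test_oracle_equivalence_and_mean_bound(self, diams):
        dh = hydraulic_diameter(diams)
        assert dh == pytest.approx(brute_force_dh(diams), rel=1e-12)
        assert dh >= np.mean(diams) - 1e-9

    def test_strictly_above_mean_when_varying(self):
        assert hydraulic_diameter([10.0, 30.0]) > np.mean([10.0, 30.0])

    def test_upper_tail_widening_raises_dh_at_fixed_mean(self):
        # same arithmetic mean (20), wider upper tail -> larger d_h
        narrow = [18.0, 20.0, 22.0]
        wide = [14.0, 20.0, 26.0]
        assert np.mean(narrow) == np.mean(wide)
        assert hydraulic_diameter(wide) > hydraulic_diameter(narrow)

    def test_empty_errors(self):
        with pytest.raises(InsufficientDataError):
            hydraulic_diameter([])


class TestWallReinforcement:
    def test_t_equals_b(self):
        assert wall_reinforcement([(3.0, 3.0)]) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        assert wall_reinforcement([(1.5, 22.0)]) == pytest.approx(4.65e-3, abs=5e-5)

    def test_scale_invariance(self):
        assert wall_reinforcement([(1.5, 22.0)]) == pytest.approx(
            wall_reinforcement([(3.0, 44.0)]), rel=1e-12
        )

    def test_mean_of_pairs(self):
        pairs = [(1.0, 10.0), (2.0, 10.0)]
        assert wall_reinforcement(pairs) == pytest.approx((0.01 + 0.04) / 2)

    def test_near_dh_filter(self):
        pairs = [(1.0, 10.0), (1.0, 30.0)]
        # only the b=30 pair is within 10% of d_h=30
        val = wall_reinforcement(pairs, d_h=30.0, near_dh=0.1)
        assert val == pytest.approx((1.0 / 30.0) ** 2)

    def test_near_dh_requires_dh(self):
        with pytest.raises(InvalidInputError):
            wall_reinforcement([(1.0, 10.0)], near_dh=0.1)

    def test_invalid_pairs(self):
        with pytest.raises(InvalidInputError):
            wall_reinforcement([(0.0, 10.0)])
        with pytest.raises(InsufficientDataError):
            wall_reinforcement([])


class TestDiameterHistogram:
    def test_basic_binning(self):
        hist = diameter_histogram([5.0, 5.0, 15.0], bin_width=10.0)
        assert hist == {(0.0, 10.0): 2, (10.0, 20.0): 1}

    def test_left_closed_right_open(self):
        hist = diameter_histogram([10.0], bin_width=10.0)
        assert hist == {(10.0, 20.0): 1}

    def test_empty_input(self):
        assert diameter_histogram([], bin_width=5.0) == {}

    def test_relative_frequencies_sum_to_one(self, rng):
        d = rng.uniform(5, 60, size=200)
        hist = diameter_histogram(d, bin_width=5.0, relative=True)
        assert sum(hist.values()) == pytest.approx(1.0)

    def test_invalid_bin_width(self):
        with pytest.raises(InvalidInputError):
            diameter_histogram([5.0], bin_width=0.0)


class TestHierarchicalMean:
    def test_weighting_rule(self):
        # hierarchical: (10 + 20) / 2 = 15; pooled would be 18
        mean, se = hierarchical_mean([[10.0], [20.0, 20.0, 20.0, 20.0]])
        assert mean == pytest.approx(15.0)

    def test_single_sample_se_none(self):
        mean, se = hierarchical_mean([[4.0, 6.0]])
        assert mean == pytest.approx(5.0)
        assert se is None

    def test_balanced_equals_pooled(self, rng):
        samples = [list(rng.uniform(10, 30, size=5)) for _ in range(4)]
        mean, _ = hierarchical_mean(samples)
        pooled = np.mean([v for s in samples for v in s])
        assert mean == pytest.approx(pooled)

    def test_mapping_input(self):
        mean, _ = hierarchical_mean({"s1": [1.0, 3.0], "s2": [5.0]})
        assert mean == pytest.approx((2.0 + 5.0) / 2)

    def test_empty_errors(self):
        with pytest.raises(InsufficientDataError):
            hierarchical_mean([])
        with pytest.raises(InsufficientDataError):
            hierarchical_mean([[1.0], []])


class TestRingWidth:
    def test_constant_positions(self):
        mean, se = ring_width([[500.0] * 5])
        assert mean == pytest.approx(500.0)

    def test_hand_arithmetic(self):
        mean, _ = ring_width([[400.0, 500.0, 600.0, 500.0, 510.0]])
        assert mean == pytest.approx(502.0)

    def test_single_position_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            mean, _ = ring_width([[480.0]])
        assert mean == pytest.approx(480.0)
        assert "single position" in caplog.text


class TestConduitSet:
    def test_diameters_from_areas(self):
        cs = ConduitSet(sample_id="s1", lumen_areas=(math.pi, 4 * math.pi))
        assert cs.diameters == pytest.approx((2.0, 4.0))

    def test_dh_ge_dmean_property(self, rng):
        for _ in range(20):
            d = tuple(rng.uniform(5, 60, size=30))
            cs = ConduitSet(sample_id="x", diameters=d)
            assert cs.d_h >= cs.d_mean

    def test_summary_stats(self):
        cs = ConduitSet(sample_id="s", diameters=(10.0, 20.0, 30.0))
        assert cs.d_mean == pytest.approx(20.0)
        assert cs.d_max == pytest.approx(30.0)
        assert cs.d_h == pytest.approx(brute_force_dh([10.0, 20.0, 30.0]))

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            ConduitSet(sample_id="s", diameters=())


class TestPitGeometry:
    def test_per_pit_averaging(self):
        pit = PitGeometry(t_m_readings=(400.0, 450.0, 500.0), l_p_readings=(300.0, 340.0))
        assert pit.t_m == pytest.approx(450.0)
        assert pit.l_p == pytest.approx(320.0)

    def test_positive_required(self):
        with pytest.raises(InvalidInputError):
            PitGeometry(t_m_readings=(400.0, -1.0), l_p_readings=(300.0,))
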