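"""Fracture-mechanics model: loads, intervals, ratios, bite-force scaling."""

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crownct.biomech import (Interval, ShapeCoefficientCurve,
                             ToothMechanicsInput, as_interval,
                             critical_load_range, extrapolate_bite_force,
                             geometry_from_measurements, margin_crack_load,
                             radial_crack_load, resistance_ratio,
                             shape_coefficient)

positive = st.floats(0.01, 100.0, allow_nan=False, allow_infinity=False)


class TestMarginCrackLoad:
    @pytest.mark.parametrize("c,kc,t,r,expected", [
        (17, 0.21, 0.20, 2.0, 101.0),   # fossil-crown low corner
        (36, 0.32, 0.20, 2.0, 325.8),   # fossil-crown high corner
        (17, 0.21, 0.11, 0.88, 33.0),   # extant-reference low corner
    ])
    def test_published_worked_examples(self, c, kc, t, r, expected):
        assert margin_crack_load(c, kc, t, r) == pytest.approx(expected,
                                                               rel=0.01)

    def test_unit_conversion_matches_explicit_si_evaluation(self):
        # dimensional oracle: convert inputs to SI by hand and evaluate
        c, kc, t_mm, r_mm = 23.0, 0.27, 0.17, 1.4
        si = c * (kc * 1e6) * math.sqrt(t_mm * 1e-3) * (r_mm * 1e-3)
        assert margin_crack_load(c, kc, t_mm, r_mm) == pytest.approx(si,
                                                                     rel=1e-12)

    def test_linear_in_toughness(self):
        assert margin_crack_load(17, 0.42, 0.2, 2.0) == pytest.approx(
            2 * margin_crack_load(17, 0.21, 0.2, 2.0))

    @given(c=positive, kc=positive, t=positive, r=positive)
    def test_radial_is_exactly_half_of_margin(self, c, kc, t, r):
        assert radial_crack_load(c, kc, t, r) == \
            pytest.approx(0.5 * margin_crack_load(c, kc, t, r), rel=1e-12)

    def test_radial_margin_ratio_independent_of_toughness(self):
        r1 = radial_crack_load(17, 0.21, 0.2, 2.0) / margin_crack_load(17, 0.21, 0.2, 2.0)
        r2 = radial_crack_load(17, 0.32, 0.2, 2.0) / margin_crack_load(17, 0.32, 0.2, 2.0)
        assert r1 == r2 == 0.5

    @given(c=positive, kc=positive, t=positive, r=positive,
           factor=st.floats(1.01, 3.0))
    def test_strictly_increasing_in_every_parameter(self, c, kc, t, r, factor):
        base = margin_crack_load(c, kc, t, r)
        assert margin_crack_load(c * factor, kc, t, r) > base
        assert margin_crack_load(c, kc * factor, t, r) > base
        assert margin_crack_load(c, kc, t * factor, r) > base
        assert margin_crack_load(c, kc, t, r * factor) > base

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            margin_crack_load(0, 0.21, 0.2, 2.0)
        with pytest.raises(ValueError):
            margin_crack_load(17, 0.21, -0.2, 2.0)

    def test_thickness_sensitivity_near_ten_percent(self):
        # thickness 0.11 vs 0.13 mm changes the load by sqrt(13/11) - 1
        lo = margin_crack_load(17, 0.21, 0.11, 2.0)
        hi = margin_crack_load(17, 0.21, 0.13, 2.0)
        assert 0.08 <= hi / lo - 1 <= 0.11


class TestShapeCoefficient:
    def test_bunodont_band(self):
        c = shape_coefficient(0.5)
        assert c.low == 6 and c.high == 8

    def test_hypsodont_plateau(self):
        c = shape_coefficient(3.5)
        assert (c.low, c.high) == (50, 55)

    def test_fossil_crown_aspect_interval(self):
        c = shape_coefficient((1.9, 2.1))
        assert c.low <= 17 and c.high >= 36

    def test_monotone_in_aspect_ratio(self):
        grid = np.linspace(0.1, 4.0, 40)
        lows = [shape_coefficient(x).low for x in grid]
        highs = [shape_coefficient(x).high for x in grid]
        assert all(b >= a for a, b in zip(lows, lows[1:]))
        assert all(b >= a for a, b in zip(highs, highs[1:]))

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            shape_coefficient(0.0)

    def test_bad_anchor_sets_rejected(self):
        with pytest.raises(ValueError):
            ShapeCoefficientCurve(((1.0, 10, 12), (2.0, 8, 9)))
        with pytest.raises(ValueError):
            ShapeCoefficientCurve(((2.0, 10, 12), (1.0, 11, 13)))


class TestCriticalLoadRange:
    def test_fossil_crown_range_endpoints(self):
        geo = ToothMechanicsInput.create(2.0, 4.2, 0.20, (0.21, 0.32))
        rng = critical_load_range(geo, (17, 36))
        assert rng.low == pytest.approx(101.0, rel=0.01)
        assert rng.high == pytest.approx(325.0, rel=0.01)
        assert rng.corner_low == {"c": 17, "K_c": 0.21, "t": 0.20, "R": 2.0}

    def test_degenerate_box_collapses(self):
        geo = ToothMechanicsInput.create(2.0, 4.2, 0.2, 0.21)
        rng = critical_load_range(geo, 17)
        assert rng.low == rng.high

    def test_corners_match_exhaustive_grid_oracle(self):
        geo = ToothMechanicsInput.create((1.8, 2.2), (4.0, 4.4),
                                         (0.15, 0.25), (0.21, 0.32))
        c = Interval(17.0, 36.0)
        rng = critical_load_range(geo, c)
        axes = [np.linspace(iv.low, iv.high, 5)
                for iv in (c, geo.toughness_mpa_sqrt_m,
                           geo.thickness_mm, geo.radius_mm)]
        grid = [margin_crack_load(cc, kk, tt, rr)
                for cc, kk, tt, rr in product(*axes)]
        assert rng.low == pytest.approx(min(grid), rel=1e-12)
        assert rng.high == pytest.approx(max(grid), rel=1e-12)

    def test_radial_mode_halves_range(self):
        geo = ToothMechanicsInput.create(2.0, 4.2, 0.20, (0.21, 0.32))
        m = critical_load_range(geo, (17, 36), mode="margin")
        r = critical_load_range(geo, (17, 36), mode="radial")
        assert r.low == pytest.approx(0.5 * m.low)
        assert r.high == pytest.approx(0.5 * m.high)


class TestRatiosAndBiteForce:
    def test_published_resistance_ratios(self):
        target = Interval(margin_crack_load(17, 0.21, 0.20, 2.0),
                          margin_crack_load(36, 0.32, 0.20, 2.0))
        reference = Interval(margin_crack_load(17, 0.21, 0.11, 0.88), 143.0)
        lo, hi = resistance_ratio(target, reference)
        assert lo == pytest.approx(3.1, abs=0.05)
        assert hi == pytest.approx(2.3, abs=0.05)

    def test_identical_ranges_give_unit_ratios(self):
        assert resistance_ratio((10, 20), (10, 20)) == (1.0, 1.0)

    def test_ratio_scales_linearly_with_target(self):
        base = resistance_ratio((10, 20), (5, 8))
        scaled = resistance_ratio((30, 60), (5, 8))
        assert scaled[0] == pytest.approx(3 * base[0])
        assert scaled[1] == pytest.approx(3 * base[1])

    def test_bite_force_extrapolation_endpoints(self):
        target = Interval(margin_crack_load(17, 0.21, 0.20, 2.0),
                          margin_crack_load(36, 0.32, 0.20, 2.0))
        reference = Interval(margin_crack_load(17, 0.21, 0.11, 0.88), 143.0)
        pred = extrapolate_bite_force(275.0, reference, target)
        assert pred.ratio_to_highest == pytest.approx(1.9, abs=0.05)
        assert pred.ratio_to_lowest == pytest.approx(8.35, abs=0.05)
        assert pred.predicted.low == pytest.approx(625.0, rel=0.01)
        assert pred.predicted.high == pytest.approx(843.0, rel=0.01)

    def test_identity_when_target_equals_reference(self):
        pred = extrapolate_bite_force(275.0, (33.0, 143.0), (33.0, 143.0))
        assert pred.predicted.low == pytest.approx(275.0)
        assert pred.predicted.high == pytest.approx(275.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_bite_force(275.0, (0.0, 143.0), (10.0, 20.0))


class TestGeometry:
    def test_crown_dimensions_give_radius_2_and_aspect_2p1(self):
        g = geometry_from_measurements(4.7, 3.3, 4.2)
        assert g["radius_mm"].low == pytest.approx(2.0)
        assert g["h_over_r"].high == pytest.approx(2.1)

    def test_symmetric_crown_radius(self):
        g = geometry_from_measurements(2 * 1.3, 2 * 1.3, 3.0)
        assert g["radius_mm"].low == pytest.approx(1.3)

    def test_radius_interval_widens_aspect_interval(self):
        g = geometry_from_measurements(4.7, 3.3, 4.2, radius_mm=(2.0, 2.2))
        assert g["h_over_r"].low == pytest.approx(4.2 / 2.2)
        assert g["h_over_r"].high == pytest.approx(2.1)
        assert g["h_over_r"].low < 1.95

    def test_non_positive_dimension_rejected(self):
        with pytest.raises(ValueError):
            geometry_from_measurements(-4.7, 3.3, 4.2)


class TestInterval:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            Interval(2.0, 1.0)

    @given(lo=positive, width=st.floats(0.0, 10.0), k=st.floats(-3.0, 3.0))
    def test_scaling(self, lo, width, k):
        iv = Interval(lo, lo + width).scaled(k)
        assert iv.low <= iv.high

    def test_as_interval_accepts_scalars_and_pairs(self):
        assert as_interval(3.0) == Interval(3.0, 3.0)
        assert as_interval((1, 2)) == Interval(1.0, 2.0)
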