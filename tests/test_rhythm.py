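"""Rhythm-function representation, interpolation, evaluation, validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cyclorhythm as cr
from cyclorhythm.exceptions import (
    AnnotationError,
    InsufficientCyclesError,
    RhythmDomainError,
)


def random_annotation_strategy():
    """Strictly increasing boundary sequences with 2..6 cycles."""
    return st.integers(2, 6).flatmap(
        lambda m: st.lists(
            st.floats(0.05, 3.0), min_size=2 * m, max_size=2 * m
        ).map(lambda d: cr.CycleZoneAnnotation(np.concatenate(([0.0], np.cumsum(d)))))
    )


class TestAnnotation:
    def test_cycle_and_zone_bookkeeping(self, simple_annotation):
        ann = simple_annotation
        assert ann.cycle_count == 2
        assert ann.zones_per_cycle == 2
        assert ann.zone_interval(1, 1) == (0.0, 0.5)
        assert ann.zone_interval(2, 2) == (1.75, 2.5)
        assert ann.cycle_interval(2) == (1.0, 2.5)

    @pytest.mark.parametrize(
        "boundaries",
        [
            [0.0, 1.0, 0.5, 2.0, 3.0],  # non-monotone
            [0.0, 1.0],  # even count
            [0.0, 1.0, 1.0, 2.0, 3.0],  # tie
        ],
    )
    def test_invalid_boundaries_rejected(self, boundaries):
        with pytest.raises(AnnotationError):
            cr.CycleZoneAnnotation(np.array(boundaries))


class TestDiscreteRhythm:
    def test_one_step_readings_are_successor_differences(self, simple_annotation):
        assert cr.discrete_rhythm(simple_annotation, 1) == [
            (0.0, 1.0),
            (0.5, 1.25),
            (1.0, 1.5),
        ]

    def test_zero_step_is_identically_zero(self, simple_annotation):
        assert all(v == 0.0 for _, v in cr.discrete_rhythm(simple_annotation, 0))

    def test_regular_rhythm_collapses_to_n_times_period(self, regular_annotation):
        vals = [v for _, v in cr.discrete_rhythm(regular_annotation, 3)]
        assert vals and all(v == pytest.approx(6.0, abs=1e-12) for v in vals)

    def test_negative_step_readings_are_negative(self, regular_annotation):
        vals = [v for _, v in cr.discrete_rhythm(regular_annotation, -1)]
        assert vals and all(v < 0 for v in vals)


class TestInterpolant:
    def test_hand_computed_slopes_and_intercepts(self, simple_annotation):
        rf = cr.build_rhythm_interpolant(simple_annotation)
        assert len(rf.segments) == 2
        s11, s12 = rf.segments
        assert (s11.start, s11.end) == (0.0, 0.5)
        assert s11.slope == pytest.approx(0.5)
        assert s11.intercept == pytest.approx(1.0)
        assert s12.slope == pytest.approx(0.5)
        assert s12.intercept == pytest.approx(1.0)

    def test_regular_rhythm_yields_constant_interpolant(self, regular_annotation):
        rf = cr.build_rhythm_interpolant(regular_annotation)
        assert all(s.slope == pytest.approx(0.0, abs=1e-12) for s in rf.segments)
        assert all(s.intercept == pytest.approx(2.0) for s in rf.segments)

    def test_single_cycle_is_insufficient(self):
        ann = cr.CycleZoneAnnotation(np.array([0.0, 1.0, 2.0]))
        with pytest.raises(InsufficientCyclesError):
            cr.build_rhythm_interpolant(ann)


class TestEvaluation:
    def test_interior_point_maps_to_same_zone_fraction(self, simple_annotation):
        rf = cr.build_rhythm_interpolant(simple_annotation)
        # 50% point of zone 1 of cycle 1 -> 50% point of zone 1 of cycle 2
        assert cr.evaluate_rhythm(rf, 0.25, 1) == pytest.approx(1.125)
        assert rf.shift_times(0.25, 1) == pytest.approx(1.375)

    def test_knots_map_to_knots_exactly(self, simple_annotation):
        rf = cr.build_rhythm_interpolant(simple_annotation)
        b = simple_annotation.boundaries
        for j in range(3):
            assert rf.evaluate(b[j], 1) == b[j + 2] - b[j]

    def test_zero_shift_is_zero_everywhere(self, simple_annotation):
        rf = cr.build_rhythm_interpolant(simple_annotation)
        for t in (0.0, 0.3, 0.99):
            assert rf.evaluate(t, 0) == 0.0

    def test_multi_step_matches_recursive_composition(self, regular_annotation):
        rf = cr.build_rhythm_interpolant(regular_annotation)
        t = 0.37
        one = rf.evaluate(t, 1)
        two = one + rf.evaluate(t + one, 1)
        assert rf.evaluate(t, 2) == pytest.approx(two, rel=1e-12)

    def test_negative_shift_inverts_forward_map(self, simple_annotation):
        rf = cr.build_rhythm_interpolant(simple_annotation)
        t = 0.25
        forward = rf.shift_times(t, 1)
        assert rf.shift_times(forward, -1) == pytest.approx(t, abs=1e-12)
        assert rf.evaluate(forward, -1) < 0

    def test_out_of_domain_raises(self, simple_annotation):
        rf = cr.build_rhythm_interpolant(simple_annotation)
        with pytest.raises(RhythmDomainError):
            rf.evaluate(2.0, 1)  # inside last cycle: no successor zone
        with pytest.raises(RhythmDomainError):
            rf.evaluate(-0.1, 1)
        with pytest.raises(RhythmDomainError):
            rf.evaluate(0.25, 5)  # target cycle beyond annotation


class TestValidation:
    def test_valid_interpolant_passes_all_checks(self, simple_annotation):
        rf = cr.build_rhythm_interpolant(simple_annotation)
        report = cr.validate_rhythm(rf)
        assert report.passed
        assert report.check("minimality").passed

    def test_corrupted_slope_is_detected_and_located(self, regular_annotation):
        rf = cr.build_rhythm_interpolant(regular_annotation)
        bad = cr.RhythmSegment(
            cycle=1, zone=1, start=rf.segments[0].start, end=rf.segments[0].end,
            slope=-1.2, intercept=rf.segments[0].intercept,
        )
        corrupted = cr.RhythmFunction(
            annotation=rf.annotation, segments=(bad,) + rf.segments[1:]
        )
        report = cr.validate_rhythm(corrupted)
        assert not report.passed
        assert 0 in report.check("slope_gt_minus_one").offending_segments

    def test_regular_interpolant_passes_with_zero_slopes(self, regular_annotation):
        rf = cr.build_rhythm_interpolant(regular_annotation)
        assert cr.validate_rhythm(rf).passed


class TestRandomAnnotationProperties:
    @settings(derandomize=True, max_examples=60)
    @given(ann=random_annotation_strategy())
    def test_knot_reproduction_slopes_and_monotonicity(self, ann):
        """Interpolants of any valid annotation reproduce the discrete rhythm
        at the knots exactly, keep all slopes above -1, and shift times
        strictly monotonically."""
        rf = cr.build_rhythm_interpolant(ann)
        b = ann.boundaries
        for j in range(b.size - 2):
            assert rf.evaluate(b[j], 1) == b[j + 2] - b[j]
        assert all(s.slope > -1 for s in rf.segments)
        lo, hi = rf.domain
        t = np.linspace(lo, hi, 101)
        shifted = rf.shift_times(t, 1)
        assert np.all(np.diff(shifted) > 0)
        assert cr.validate_rhythm(rf).passed
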