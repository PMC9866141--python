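"""Cycle-aligned moment estimators: zone decomposition, alignment, moments."""

import numpy as np
import pytest

import cyclorhythm as cr
from cyclorhythm.exceptions import AlignmentError, ParameterError, ValidationError

FS = 250.0


def constant_recording(ann, value, fs=FS, n_channels=1):
    L = int(np.floor(ann.boundaries[-1] * fs))
    return cr.MultichannelRecording(np.full((n_channels, L), float(value)), fs)


class TestZoneDecomposition:
    def test_partition_reconstructs_signal_exactly(self, simple_annotation):
        rng = np.random.default_rng(1)
        rec = cr.MultichannelRecording(rng.standard_normal((1, 625)), FS)
        comps = cr.zone_components(rec, simple_annotation, channel=0)
        total = sum(comps.values())
        on_support = rec.times < simple_annotation.boundaries[-1]
        assert np.array_equal(total[on_support], rec.samples[0][on_support])

    def test_indicator_is_one_inside_zero_outside(self, simple_annotation):
        ind = cr.zone_indicator(simple_annotation, 1, 1, [0.0, 0.25, 0.5, 2.0])
        assert ind.tolist() == [1.0, 1.0, 0.0, 0.0]

    def test_zone_support_sample_count(self, simple_annotation):
        rec = constant_recording(simple_annotation, 1.0)
        comp = cr.zone_component(rec, simple_annotation, 0, cycle=2, zone=1)
        assert int(np.count_nonzero(comp)) == 188

    def test_unknown_zone_raises(self, simple_annotation):
        rec = constant_recording(simple_annotation, 1.0)
        with pytest.raises((ParameterError, cr.AnnotationError)):
            cr.zone_component(rec, simple_annotation, 0, cycle=9, zone=1)


class TestAlignment:
    def test_constant_signal_fills_matrix(self, simple_annotation):
        rec = constant_recording(simple_annotation, 3.25)
        rf = cr.build_rhythm_interpolant(simple_annotation)
        grid = cr.PhaseGrid.from_recording(rec, simple_annotation, "zone1")
        mat = cr.align(rec, rf, grid, 0)
        assert mat.values.shape == (2, grid.size)
        assert np.all(mat.values == 3.25)

    def test_regular_rhythm_matrix_is_reshape(self, small_regular_sim):
        rec, ann, gt, cfg = small_regular_sim
        rf = cr.build_rhythm_interpolant(ann)
        grid = cr.PhaseGrid.from_recording(rec, ann, "full_cycle")
        mat = cr.align(rec, rf, grid, 0)
        per_cycle = int(sum(cfg.zone_durations) * cfg.fs)
        reshaped = rec.samples[0][: ann.cycle_count * per_cycle].reshape(
            ann.cycle_count, per_cycle
        )
        assert np.array_equal(mat.values, reshaped)
        assert not mat.interpolated.any()

    def test_row_zero_is_recording_on_grid(self, default_sim):
        rec, ann, gt, cfg = default_sim
        rf = cr.build_rhythm_interpolant(ann)
        grid = cr.PhaseGrid.from_recording(rec, ann, "zone2", max_points=40)
        mat = cr.align(rec, rf, grid, 0)
        direct = np.interp(grid.times, rec.times, rec.samples[0])
        assert np.allclose(mat.values[0], direct)

    def test_zone_start_column_tracks_knots(self, default_sim):
        rec, ann, gt, cfg = default_sim
        rf = cr.build_rhythm_interpolant(ann)
        t12 = ann.zone_interval(1, 2)[0]
        grid = cr.PhaseGrid(np.array([t12]), "zone2", ann)
        mat = cr.align(rec, rf, grid, 0)
        for n in range(ann.cycle_count):
            knot = ann.zone_interval(n + 1, 2)[0]
            expect = np.interp(knot, rec.times, rec.samples[0])
            assert mat.values[n, 0] == pytest.approx(expect, rel=1e-9)

    def test_aligned_time_beyond_recording_raises(self, simple_annotation):
        # recording much shorter than the annotated support
        rec = cr.MultichannelRecording(np.zeros((1, 100)), FS)
        rf = cr.build_rhythm_interpolant(simple_annotation)
        grid = cr.PhaseGrid(np.array([0.25]), "zone1", simple_annotation)
        with pytest.raises(AlignmentError):
            cr.align(rec, rf, grid, 0)


class TestSingleArgumentMoments:
    def test_constant_signal_moments(self, simple_annotation):
        rec = constant_recording(simple_annotation, 2.0)
        rf = cr.build_rhythm_interpolant(simple_annotation)
        grid = cr.PhaseGrid.from_recording(rec, simple_annotation, "zone1")
        assert np.all(cr.estimate_mean(rec, rf, grid, 0).values == 2.0)
        assert np.all(cr.estimate_dispersion(rec, rf, grid, 0).values == 0.0)
        assert np.all(
            cr.estimate_initial_moment(rec, rf, grid, 0, 3).values == 8.0
        )

    def test_zero_noise_simulation_has_zero_dispersion(self):
        specs = tuple(
            (
                cr.ChannelZoneSpec(cr.HarmonicProfile(1.0, ((0.5, 1.0, 0.0),)),
                                   cr.HarmonicProfile(0.0)),
                cr.ChannelZoneSpec(cr.HarmonicProfile(2.0), cr.HarmonicProfile(0.0)),
            )
            for _ in range(1)
        )
        cfg = cr.SimulationConfig(
            n_channels=1, n_cycles=6, jitter=0.0, channel_specs=tuple(specs),
            zone_durations=(0.4, 0.4),
        )
        rec, ann, gt = cr.simulate(cfg, 3)
        rf = cr.build_rhythm_interpolant(ann)
        grid = cr.PhaseGrid.from_recording(rec, ann, "full_cycle")
        disp = cr.estimate_dispersion(rec, rf, grid, 0)
        assert np.max(np.abs(disp.values)) < 1e-24

    def test_dispersion_vs_central2_normalization_identity(self, default_sim):
        rec, ann, gt, cfg = default_sim
        rf = cr.build_rhythm_interpolant(ann)
        grid = cr.PhaseGrid.from_recording(rec, ann, "zone1", max_points=100)
        d = cr.estimate_dispersion(rec, rf, grid, 1)
        c2 = cr.estimate_central_moment(rec, rf, grid, 1, 2)
        M = ann.cycle_count
        assert np.allclose(d.values, (M - 1) / M * c2.values, rtol=1e-12)

    def test_first_initial_moment_equals_mean(self, default_sim):
        rec, ann, gt, cfg = default_sim
        rf = cr.build_rhythm_interpolant(ann)
        grid = cr.PhaseGrid.from_recording(rec, ann, "zone2", max_points=50)
        m = cr.estimate_mean(rec, rf, grid, 2)
        i1 = cr.estimate_initial_moment(rec, rf, grid, 2, 1)
        assert np.array_equal(m.values, i1.values)

    def test_third_central_moment_of_symmetric_noise_is_small(self):
        cfg = cr.SimulationConfig(
            n_channels=1, n_cycles=400, jitter=0.0, zone_durations=(0.4, 0.4)
        )
        rec, ann, gt = cr.simulate(cfg, 17)
        rf = cr.build_rhythm_interpolant(ann)
        grid = cr.PhaseGrid.from_recording(rec, ann, "zone1")
        c3 = cr.estimate_central_moment(rec, rf, grid, 0, 3)
        bound = 4 * np.sqrt(15 / cfg.n_cycles)
        assert abs(c3.values.mean()) < bound

    def test_estimate_metadata(self, default_sim):
        rec, ann, gt, cfg = default_sim
        rf = cr.build_rhythm_interpolant(ann)
        grid = cr.PhaseGrid.from_recording(rec, ann, "zone1", max_points=10)
        est = cr.estimate_central_moment(rec, rf, grid, 0, 4)
        assert est.kind == "central"
        assert est.order == 4
        assert est.units == "uV^4"
        assert est.n_cycles == ann.cycle_count


class TestMixedMoments:
    def test_single_argument_reduces_to_initial_moment(self, default_sim):
        rec, ann, gt, cfg = default_sim
        rf = cr.build_rhythm_interpolant(ann)
        grid = cr.PhaseGrid.from_recording(rec, ann, "zone1", max_points=30)
        mi = cr.estimate_mixed_initial(rec, rf, grid, (0,), (2,), m1=1)
        i2 = cr.estimate_initial_moment(rec, rf, grid, 0, 2)
        assert np.array_equal(mi.values, i2.values)

    def test_single_argument_central_reduces_to_central(self, default_sim):
        rec, ann, gt, cfg = default_sim
        rf = cr.build_rhythm_interpolant(ann)
        grid = cr.PhaseGrid.from_recording(rec, ann, "zone1", max_points=30)
        mc = cr.estimate_mixed_central(rec, rf, grid, (0,), (3,), m1=1)
        c3 = cr.estimate_central_moment(rec, rf, grid, 0, 3)
        assert np.allclose(mc.values, c3.values, rtol=1e-12)

    def test_constant_channels_product(self, simple_annotation):
        rec = constant_recording(simple_annotation, 3.0, n_channels=2)
        rf = cr.build_rhythm_interpolant(simple_annotation)
        grid = cr.PhaseGrid.from_recording(rec, simple_annotation, "zone1")
        mi = cr.estimate_mixed_initial(
            rec, rf, grid, (0, 1), (1, 1), lags=(cr.SamePhaseLag(0),), m1=1
        )
        assert np.all(mi.values == 9.0)

    def test_independent_channels_have_small_cross_moment(self):
        specs = tuple(
            (
                cr.ChannelZoneSpec(cr.HarmonicProfile(0.0), cr.HarmonicProfile(1.0)),
                cr.ChannelZoneSpec(cr.HarmonicProfile(0.0), cr.HarmonicProfile(1.0)),
            )
            for _ in range(2)
        )
        cfg = cr.SimulationConfig(
            n_channels=2, n_cycles=500, jitter=0.0, zone_durations=(0.4, 0.4),
            channel_specs=specs,
        )
        rec, ann, gt = cr.simulate(cfg, 3)
        rf = cr.build_rhythm_interpolant(ann)
        grid = cr.PhaseGrid.from_recording(rec, ann, "zone1", max_points=50)
        mi = cr.estimate_mixed_initial(
            rec, rf, grid, (0, 1), (1, 1), lags=(cr.SamePhaseLag(0),), m1=1
        )
        assert np.max(np.abs(mi.values)) <= 4 / np.sqrt(cfg.n_cycles)

    def test_shared_noise_component_recovered_as_covariance(self):
        cfg = cr.SimulationConfig(
            n_channels=2, n_cycles=500, jitter=0.0, shared_noise_variance=0.25,
            zone_durations=(0.4, 0.4),
        )
        rec, ann, gt = cr.simulate(cfg, 11)
        rf = cr.build_rhythm_interpolant(ann)
        grid = cr.PhaseGrid.from_recording(rec, ann, "zone1", max_points=50)
        mc = cr.estimate_mixed_central(
            rec, rf, grid, (0, 1), (1, 1), lags=(cr.SamePhaseLag(0),), m1=1
        )
        assert mc.values.mean() == pytest.approx(0.25, abs=0.08)

    def test_deterministic_signal_has_zero_mixed_central(self, simple_annotation):
        rec = constant_recording(simple_annotation, 5.0, n_channels=2)
        rf = cr.build_rhythm_interpolant(simple_annotation)
        grid = cr.PhaseGrid.from_recording(rec, simple_annotation, "zone1")
        mc = cr.estimate_mixed_central(
            rec, rf, grid, (0, 1), (1, 1), lags=(cr.SamePhaseLag(0),), m1=1
        )
        assert np.all(mc.values == 0.0)

    def test_m1_bounds_enforced(self, default_sim):
        rec, ann, gt, cfg = default_sim
        rf = cr.build_rhythm_interpolant(ann)
        grid = cr.PhaseGrid.from_recording(rec, ann, "zone1", max_points=5)
        with pytest.raises(ParameterError):
            cr.estimate_mixed_initial(
                rec, rf, grid, (0,), (1,), m1=ann.cycle_count
            )
        with pytest.raises(ParameterError):
            cr.estimate_mixed_initial(
                rec, rf, grid, (0, 1), (1, 1), lags=(cr.SamePhaseLag(3),), m1=2
            )

    def test_fixed_lag_outside_cycle_rejected(self, default_sim):
        rec, ann, gt, cfg = default_sim
        rf = cr.build_rhythm_interpolant(ann)
        grid = cr.PhaseGrid.from_recording(rec, ann, "zone1", max_points=5)
        with pytest.raises(ParameterError):
            cr.estimate_mixed_initial(
                rec, rf, grid, (0, 1), (1, 1), lags=(cr.FixedLag(1, 99.0),), m1=1
            )


class TestEstimatorInvariance:
    def test_reanchoring_grid_one_cycle_forward_is_consistent(self, default_sim):
        """Shifting the phase grid one cycle ahead (and the shift range one
        cycle back) must reproduce the same estimate: invariance of the
        aligned ensemble under the fitted rhythm."""
        rec, ann, gt, cfg = default_sim
        rf = cr.build_rhythm_interpolant(ann)
        grid = cr.PhaseGrid.from_recording(rec, ann, "zone1", max_points=40)
        M = ann.cycle_count
        base = cr.align(rec, rf, grid, 0).values.mean(axis=0)
        forward_times = rf.shift_times(grid.times, 1)
        mat2 = np.empty((M, grid.size))
        for row, n in enumerate(range(-1, M - 1)):
            aligned = rf.shift_times(forward_times, n)
            mat2[row] = np.interp(aligned, rec.times, rec.samples[0])
        assert np.allclose(mat2.mean(axis=0), base, rtol=1e-9, atol=1e-9)
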