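import numpy as np
import pytest

from conftest import single_saccade_trace
from saccfit.detection import (
    compute_velocity,
    detect_saccades,
    duration_quantization_error,
    filter_microsaccades,
    project_trajectory,
    select_horizontal,
    threshold_kinematics,
    analyze_trace,
)
from saccfit.errors import DataError, DegenerateSegmentError, FitError, ParameterError
from saccfit.trace_io import GazeTrace
from saccfit.trajectory import extract_kinematics


def trace_from(az, el=None, fs=250.0):
    az = np.asarray(az, dtype=float)
    el = np.zeros_like(az) if el is None else np.asarray(el, dtype=float)
    t = np.arange(len(az)) / fs
    return GazeTrace(t, az, el, sampling_frequency=fs)


class TestComputeVelocity:
    def test_first_difference_arithmetic(self):
        vel = compute_velocity(trace_from([0.0, 1.0, 3.0]), "first_difference")
        assert not vel.valid[0]
        assert vel.speed[1] == pytest.approx(250.0)
        assert vel.speed[2] == pytest.approx(500.0)

    def test_central_difference_arithmetic(self):
        vel = compute_velocity(trace_from([0.0, 1.0, 3.0]), "central_difference")
        assert not vel.valid[0] and not vel.valid[2]
        assert vel.speed[1] == pytest.approx(375.0)

    def test_constant_position_gives_zero_speed(self):
        vel = compute_velocity(trace_from(np.ones(50)))
        assert np.all(vel.speed[vel.valid] == 0.0)

    def test_speed_is_euclidean_over_both_axes(self):
        vel = compute_velocity(
            trace_from([0.0, 3.0, 6.0], el=[0.0, 4.0, 8.0]), "first_difference"
        )
        assert vel.speed[1] == pytest.approx(5.0 * 250.0)

    def test_too_short_trace_rejected(self):
        with pytest.raises(DataError):
            compute_velocity(trace_from([0.0, 1.0]))

    def test_unknown_method_rejected(self):
        with pytest.raises(ParameterError):
            compute_velocity(trace_from(np.zeros(10)), "savitzky")


class TestDetectSaccades:
    def test_single_step_yields_one_segment(self):
        trace, _ = single_saccade_trace(amplitude=10.0)
        segments = detect_saccades(trace)
        assert len(segments) == 1
        assert segments[0].nominal_amplitude == pytest.approx(10.0, abs=0.6)

    def test_noise_only_trace_yields_nothing(self):
        rng = np.random.default_rng(12345)
        n = 1000
        trace = GazeTrace(
            np.arange(n) / 250.0,
            rng.normal(0, 0.05, n),
            rng.normal(0, 0.05, n),
            sampling_frequency=250.0,
        )
        assert detect_saccades(trace) == []

    def test_two_steps_detected_in_order(self):
        trace1, _ = single_saccade_trace(amplitude=8.0)
        # concatenate two single-saccade traces 500 ms apart
        az = np.concatenate([trace1.azimuth, trace1.azimuth[-1] + trace1.azimuth])
        trace = trace_from(az)
        segments = detect_saccades(trace)
        assert len(segments) == 2
        assert segments[0].onset_index < segments[1].onset_index

    def test_detection_invariant_to_constant_offset(self):
        trace, _ = single_saccade_trace(amplitude=6.0, noise_sd=0.03, seed=5)
        shifted = GazeTrace(
            trace.timestamps,
            trace.azimuth + 12.0,
            trace.elevation - 7.0,
            sampling_frequency=trace.sampling_frequency,
        )
        assert len(detect_saccades(trace)) == len(detect_saccades(shifted))

    def test_threshold_must_be_positive(self):
        trace, _ = single_saccade_trace()
        with pytest.raises(ParameterError):
            detect_saccades(trace, velocity_threshold=0.0)


class TestProjection:
    def test_horizontal_saccade_projects_to_azimuth(self):
        trace, _ = single_saccade_trace(amplitude=10.0)
        seg = project_trajectory(detect_saccades(trace)[0], trace)
        sl = slice(seg.window_start_index, seg.window_end_index + 1)
        expected = trace.azimuth[sl] - seg.pre_fixation.azimuth
        np.testing.assert_allclose(seg.projected_position, expected, atol=1e-12)

    def test_oblique_saccade_projected_length_is_full_amplitude(self):
        trace, _ = single_saccade_trace(amplitude=10.0)
        oblique = GazeTrace(
            trace.timestamps,
            trace.azimuth / np.sqrt(2.0),
            trace.azimuth / np.sqrt(2.0),
            sampling_frequency=trace.sampling_frequency,
        )
        seg = project_trajectory(detect_saccades(oblique)[0], oblique)
        assert seg.projected_position[-1] == pytest.approx(10.0, abs=0.1)
        assert seg.direction_deg == pytest.approx(45.0, abs=1.0)

    def test_orthogonal_displacement_contributes_zero(self):
        trace, _ = single_saccade_trace(amplitude=10.0)
        seg = project_trajectory(detect_saccades(trace)[0], trace)
        mid = len(seg.projected_position) // 2
        bumped = trace.elevation.copy()
        bumped[seg.window_start_index + mid] += 0.5  # orthogonal to motion
        trace2 = GazeTrace(trace.timestamps, trace.azimuth, bumped,
                           sampling_frequency=trace.sampling_frequency)
        seg2 = project_trajectory(seg, trace2)
        assert seg2.projected_position[mid] == pytest.approx(seg.projected_position[mid])

    def test_coincident_centroids_rejected(self):
        trace, _ = single_saccade_trace(amplitude=10.0)
        seg = detect_saccades(trace)[0]
        seg.post_fixation.azimuth = seg.pre_fixation.azimuth
        seg.post_fixation.elevation = seg.pre_fixation.elevation
        with pytest.raises(DegenerateSegmentError):
            project_trajectory(seg, trace)


class TestFilters:
    def _seg(self, amplitude, direction=0.0):
        trace, _ = single_saccade_trace(amplitude=10.0)
        seg = detect_saccades(trace)[0]
        seg.nominal_amplitude = amplitude
        seg.direction_deg = direction
        return seg

    def test_microsaccade_filter_splits_by_amplitude(self):
        segs = [self._seg(a) for a in (0.5, 1.5, 8.0)]
        kept, discarded = filter_microsaccades(segs)
        assert [s.nominal_amplitude for s in kept] == [1.5, 8.0]
        assert [s.nominal_amplitude for s in discarded] == [0.5]

    def test_zero_threshold_keeps_all(self):
        segs = [self._seg(a) for a in (0.2, 0.9)]
        kept, discarded = filter_microsaccades(segs, amplitude_threshold=0.0)
        assert len(kept) == 2 and discarded == []

    def test_empty_input(self):
        assert filter_microsaccades([]) == ([], [])

    def test_horizontal_selection(self):
        segs = [self._seg(5.0, d) for d in (0.0, 10.0, 170.0, 90.0, -171.0)]
        kept = select_horizontal(segs)
        assert [s.direction_deg for s in kept] == [0.0, 10.0, 170.0, -171.0]

    def test_horizontal_boundary_inclusive(self):
        assert len(select_horizontal([self._seg(5.0, 15.0)])) == 1

    def test_half_angle_90_keeps_everything(self):
        segs = [self._seg(5.0, d) for d in (0.0, 45.0, 90.0, 135.0)]
        assert len(select_horizontal(segs, half_angle_deg=90.0)) == 4


class TestThresholdKinematics:
    def test_duration_systematically_underestimated(self):
        trace, params = single_saccade_trace(amplitude=10.0)
        true_duration = extract_kinematics(params).duration
        seg = project_trajectory(detect_saccades(trace)[0], trace)
        _, duration, _ = threshold_kinematics(seg, trace)
        assert duration < true_duration

    def test_sampled_peak_never_exceeds_analytic_peak(self):
        trace, params = single_saccade_trace(amplitude=10.0)
        true_pv = extract_kinematics(params).peak_velocity
        seg = project_trajectory(detect_saccades(trace)[0], trace)
        _, _, pv = threshold_kinematics(seg, trace, velocity_method="central_difference")
        assert pv <= true_pv + 1e-9

    def test_peak_velocity_non_increasing_with_downsampling(self):
        from saccfit.trace_io import downsample

        trace, _ = single_saccade_trace(amplitude=12.0)
        pvs = []
        for factor in (1, 2, 5):
            tr = downsample(trace, factor)
            seg = project_trajectory(detect_saccades(tr)[0], tr)
            pvs.append(threshold_kinematics(seg, tr, velocity_method="central_difference")[2])
        assert pvs[0] >= pvs[1] >= pvs[2]

    def test_no_supra_threshold_sample_rejected(self):
        trace, _ = single_saccade_trace(amplitude=10.0)
        seg = project_trajectory(detect_saccades(trace)[0], trace)
        with pytest.raises(FitError):
            threshold_kinematics(seg, trace, velocity_threshold=1e6)


class TestDurationQuantization:
    def test_worst_case_is_one_sampling_period(self):
        assert duration_quantization_error(200.0) == pytest.approx(0.005)
        assert duration_quantization_error(50.0) == pytest.approx(0.020)

    def test_rejects_nonpositive_frequency(self):
        with pytest.raises(ParameterError):
            duration_quantization_error(0.0)


class TestAnalyzeTrace:
    def test_noiseless_trace_recovers_truth(self, noiseless_trace):
        trace, truth = noiseless_trace
        df = analyze_trace(trace)
        assert len(df) == len(truth)
        np.testing.assert_allclose(
            df["fit_amplitude"], truth["amplitude"], rtol=5e-3
        )
        np.testing.assert_allclose(
            df["fit_peak_velocity"], truth["peak_velocity"], rtol=1e-2
        )

    def test_both_method_columns_present(self, noiseless_trace):
        df = analyze_trace(noiseless_trace[0])
        for col in ("fit_amplitude", "thr_amplitude", "fit_duration", "thr_duration",
                    "fit_peak_velocity", "thr_peak_velocity", "r_squared", "converged"):
            assert col in df.columns
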