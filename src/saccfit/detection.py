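"""Velocity-based saccade detection and threshold (baseline) kinematics.

Detection thresholds the 2-D gaze speed at 20 deg/s, merges supra-threshold
runs closer than the minimum intersaccadic interval, marks the flanking
fixations (per-axis median centroids of the sub-threshold intervals) and
projects the trajectory onto the straight line between the two fixation
centroids, which is the scalar signal the Hill fit consumes.

``threshold_kinematics`` implements the classical estimator the model-based
fit is compared against: endpoints at the first/last samples above an
absolute velocity threshold, peak velocity as the maximum numerical-velocity
sample. Its timing resolution is inherently limited to one sampling period
per endpoint (5 ms at 200 Hz, 20 ms at 50 Hz), the quantization bound
returned by :func:`duration_quantization_error`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import DataError, DegenerateSegmentError, FitError, ParameterError
from .trace_io import GazeTrace
from .trajectory import HillTrajectoryModel

logger = logging.getLogger(__name__)

__all__ = [
    "VelocityTrace",
    "SaccadeSegment",
    "compute_velocity",
    "detect_saccades",
    "project_trajectory",
    "filter_microsaccades",
    "select_horizontal",
    "threshold_kinematics",
    "duration_quantization_error",
    "analyze_trace",
]

DETECTION_THRESHOLD = 20.0  # deg/s
ENDPOINT_THRESHOLD = 50.0  # deg/s, baseline start/end marking
MICROSACCADE_AMPLITUDE = 1.0  # deg
HORIZONTAL_HALF_ANGLE = 15.0  # deg


@dataclass
class Fixation:
    """Sub-threshold interval flanking a saccade; centroid is the per-axis
    median of the gaze samples, robust to drift."""

    azimuth: float
    elevation: float
    start_index: int
    end_index: int  # inclusive


@dataclass
class VelocityTrace:
    timestamps: np.ndarray
    speed: np.ndarray  # deg/s, >= 0
    method: str
    valid: np.ndarray  # False where the difference stencil is undefined


@dataclass
class SaccadeSegment:
    """One detected saccadic episode on a gaze trace."""

    onset_index: int
    offset_index: int  # inclusive
    pre_fixation: Fixation
    post_fixation: Fixation
    window_start_index: int
    window_end_index: int  # inclusive
    nominal_amplitude: float  # deg, centroid-to-centroid
    direction_deg: float  # 0 = rightward, CCW positive
    projected_position: np.ndarray | None = None  # deg, over the window


def compute_velocity(trace: GazeTrace, method: str = "central_difference") -> VelocityTrace:
    """Numerical gaze speed in deg/s.

    ``first_difference``: |X(t) - X(t-1)| / dt (the classical two-point
    formula as usually printed); ``central_difference``:
    |X(t+1) - X(t-1)| / (2 dt), with less phase lag. Boundary samples where
    the stencil is undefined, or touching invalid samples, are flagged.
    """
    if method not in ("first_difference", "central_difference"):
        raise ParameterError(f"unknown velocity method {method!r}")
    n = len(trace)
    if n < 3 or int(np.sum(trace.validity_mask)) < 3:
        raise DataError("need at least 3 valid samples to compute velocity")
    az, el, dt = trace.azimuth, trace.elevation, trace.dt
    speed = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    vmask = trace.validity_mask
    if method == "first_difference":
        d = np.hypot(np.diff(az), np.diff(el))
        speed[1:] = d / dt
        valid[1:] = vmask[1:] & vmask[:-1]
    else:
        d = np.hypot(az[2:] - az[:-2], el[2:] - el[:-2])
        speed[1:-1] = d / (2.0 * dt)
        valid[1:-1] = vmask[2:] & vmask[:-2]
    speed = np.where(valid, speed, np.nan)
    return VelocityTrace(trace.timestamps, speed, method, valid)


def _boxcar(x: np.ndarray, valid: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width)
    num = np.convolve(np.where(valid, x, 0.0), kernel, mode="same")
    den = np.convolve(valid.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


def _detection_speed(trace: GazeTrace, method: str, smooth_ms: float) -> VelocityTrace:
    """Speed for thresholding, from boxcar-smoothed positions.

    Position noise must be attenuated *before* the magnitude is taken:
    the speed of an unsmoothed 250 Hz trace with 0.1 deg noise averages
    ~20 deg/s during fixation (the noise mean, not just its spread), so no
    amount of smoothing after the norm can recover a 20 deg/s threshold.
    Saccadic speeds are an order of magnitude above threshold, so the
    blurring does not cost detections; kinematics never use this signal.
    """
    width = max(1, int(round(smooth_ms * 1e-3 * trace.sampling_frequency)))
    if width % 2 == 0:
        width += 1
    if width == 1:
        return compute_velocity(trace, method)
    smoothed = GazeTrace(
        trace.timestamps,
        _boxcar(trace.azimuth, trace.validity_mask, width),
        _boxcar(trace.elevation, trace.validity_mask, width),
        sampling_frequency=trace.sampling_frequency,
        eye_label=trace.eye_label,
        validity_mask=trace.validity_mask.copy(),
    )
    return compute_velocity(smoothed, method)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, end) inclusive index pairs."""
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        return []
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts.tolist(), ends.tolist()))


def detect_saccades(
    trace: GazeTrace,
    velocity_threshold: float = DETECTION_THRESHOLD,
    min_intersaccadic_ms: float = 20.0,
    velocity_method: str = "central_difference",
    pad_samples: int = 5,
    pad_ms: float = 20.0,
    smooth_ms: float = 20.0,
) -> list[SaccadeSegment]:
    """Detect saccades by velocity thresholding.

    Supra-threshold runs separated by less than ``min_intersaccadic_ms``
    are merged (a noisy velocity dip must not split one saccade in two).
    Each segment's analysis window extends ``max(pad_samples, pad_ms)``
    beyond onset/offset — the Hill fit needs flanking plateau samples to
    anchor E0 and Emax — but never into a neighboring saccade.

    For thresholding only, the gaze positions are boxcar-smoothed over
    ``smooth_ms`` before differentiation (a no-op at low sampling rates
    where the window is one sample); see :func:`_detection_speed`. The
    raw trace is never altered for kinematics.
    """
    if velocity_threshold <= 0:
        raise ParameterError("velocity_threshold must be > 0")
    vel = _detection_speed(trace, velocity_method, smooth_ms)
    supra = vel.valid & (vel.speed > velocity_threshold)
    runs = _runs(supra)
    if not runs:
        return []

    # merge runs separated by a too-short sub-threshold gap
    min_gap = int(round(min_intersaccadic_ms * 1e-3 * trace.sampling_frequency))
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] - 1 < min_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    pad = max(int(pad_samples), int(round(pad_ms * 1e-3 * trace.sampling_frequency)))
    segments: list[SaccadeSegment] = []
    n = len(trace)
    for i, (onset, offset) in enumerate(merged):
        prev_end = merged[i - 1][1] if i > 0 else None
        next_start = merged[i + 1][0] if i + 1 < len(merged) else None
        pre_lo = (prev_end + 1) if prev_end is not None else 0
        pre_hi = onset - 1
        post_lo = offset + 1
        post_hi = (next_start - 1) if next_start is not None else n - 1
        if pre_hi < pre_lo:
            logger.warning(
                "saccade candidate at sample %d has no preceding fixation; dropped", onset
            )
            continue
        if post_hi < post_lo:
            logger.warning(
                "saccade candidate at sample %d has no following fixation; dropped", onset
            )
            continue
        pre = _fixation(trace, pre_lo, pre_hi)
        post = _fixation(trace, post_lo, post_hi)
        d_az = post.azimuth - pre.azimuth
        d_el = post.elevation - pre.elevation
        nominal = float(np.hypot(d_az, d_el))
        direction = float(np.degrees(np.arctan2(d_el, d_az)))
        w_lo = max(onset - pad, pre_lo)
        w_hi = min(offset + pad, post_hi)
        segments.append(
            SaccadeSegment(
                onset_index=int(onset),
                offset_index=int(offset),
                pre_fixation=pre,
                post_fixation=post,
                window_start_index=int(w_lo),
                window_end_index=int(w_hi),
                nominal_amplitude=nominal,
                direction_deg=direction,
            )
        )
    return segments


def _fixation(trace: GazeTrace, lo: int, hi: int) -> Fixation:
    sl = slice(lo, hi + 1)
    mask = trace.validity_mask[sl]
    az = trace.azimuth[sl]
    el = trace.elevation[sl]
    if mask.any():
        az, el = az[mask], el[mask]
    return Fixation(float(np.median(az)), float(np.median(el)), lo, hi)


def project_trajectory(segment: SaccadeSegment, trace: GazeTrace) -> SaccadeSegment:
    """Project window samples onto the fixation-to-fixation direction.

    The projected position is the signed scalar displacement (degrees)
    from the pre-fixation centroid along the unit vector toward the
    post-fixation centroid: ~0 at the start, ~nominal_amplitude at the end.
    """
    pre, post = segment.pre_fixation, segment.post_fixation
    d = np.array([post.azimuth - pre.azimuth, post.elevation - pre.elevation])
    norm = float(np.hypot(*d))
    if norm < 1e-12:
        raise DegenerateSegmentError("fixation centroids coincide: no projection axis")
    u = d / norm
    sl = slice(segment.window_start_index, segment.window_end_index + 1)
    rel_az = trace.azimuth[sl] - pre.azimuth
    rel_el = trace.elevation[sl] - pre.elevation
    projected = rel_az * u[0] + rel_el * u[1]
    return replace(segment, projected_position=projected)


def filter_microsaccades(
    segments: list[SaccadeSegment], amplitude_threshold: float = MICROSACCADE_AMPLITUDE
) -> tuple[list[SaccadeSegment], list[SaccadeSegment]]:
    """Split segments into (kept, discarded) by nominal amplitude.

    Discarded micro-saccades are returned for audit, never silently lost.
    """
    kept = [s for s in segments if s.nominal_amplitude >= amplitude_threshold]
    discarded = [s for s in segments if s.nominal_amplitude < amplitude_threshold]
    return kept, discarded


def select_horizontal(
    segments: list[SaccadeSegment], half_angle_deg: float = HORIZONTAL_HALF_ANGLE
) -> list[SaccadeSegment]:
    """Keep segments within ``half_angle_deg`` of horizontal (either way).

    The boundary is inclusive: a saccade at exactly the half angle is kept.
    """
    out = []
    for s in segments:
        d = abs(((s.direction_deg + 180.0) % 360.0) - 180.0)  # fold to [0, 180]
        if min(d, 180.0 - d) <= half_angle_deg:
            out.append(s)
    return out


def threshold_kinematics(
    segment: SaccadeSegment,
    trace: GazeTrace,
    velocity_threshold: float = ENDPOINT_THRESHOLD,
    velocity_method: str = "first_difference",
) -> tuple[float, float, float]:
    """Baseline estimator: absolute-threshold endpoints, sampled peak.

    Returns (amplitude deg, duration s, peak_velocity deg/s). Start/end are
    the first/last window samples whose numerical speed exceeds the
    threshold; duration is therefore quantized to the sampling period and
    systematically underestimates the true 2-98% duration, and the sampled
    peak can only underestimate the continuous peak. The default velocity
    is the classical backward two-point difference this estimator is
    historically built on.
    """
    if segment.projected_position is None:
        segment = project_trajectory(segment, trace)
    vel = compute_velocity(trace, velocity_method)
    sl = slice(segment.window_start_index, segment.window_end_index + 1)
    speed = vel.speed[sl]
    valid = vel.valid[sl]
    supra = np.nonzero(valid & (speed > velocity_threshold))[0]
    if len(supra) == 0:
        raise FitError(
            f"no sample above {velocity_threshold} deg/s in window: kinematics undefined"
        )
    start, end = int(supra[0]), int(supra[-1])
    proj = segment.projected_position
    amplitude = float(abs(proj[end] - proj[start]))
    t = trace.timestamps[sl]
    duration = float(t[end] - t[start])
    peak_velocity = float(np.nanmax(speed[valid])) if valid.any() else float("nan")
    return amplitude, duration, peak_velocity


def duration_quantization_error(sampling_frequency: float) -> float:
    """Worst-case timing error (s) of one threshold-marked endpoint.

    A threshold crossing can only be located at a sample instant, so each
    endpoint may be off by up to one sampling period: 1/fs seconds
    (5 ms at 200 Hz, 20 ms at 50 Hz).
    """
    if sampling_frequency <= 0:
        raise ParameterError("sampling_frequency must be > 0")
    return 1.0 / sampling_frequency


def analyze_trace(
    trace: GazeTrace,
    detection_threshold: float = DETECTION_THRESHOLD,
    endpoint_threshold: float = ENDPOINT_THRESHOLD,
    microsaccade_threshold: float = MICROSACCADE_AMPLITUDE,
    velocity_method: str = "central_difference",
    baseline_velocity_method: str = "first_difference",
):
    """Detect, project and fit every saccade on a trace.

    Returns a DataFrame with one row per kept saccade, carrying both the
    Hill-fit kinematics (``fit_*`` columns) and the threshold baseline
    (``thr_*`` columns), plus the fitted Hill parameters and diagnostics.
    Saccades whose fit or baseline is undefined get NaNs in the affected
    columns rather than being dropped.
    """
    import pandas as pd

    segments = detect_saccades(
        trace, velocity_threshold=detection_threshold, velocity_method=velocity_method
    )
    kept, _ = filter_microsaccades(segments, microsaccade_threshold)
    rows = []
    for seg in kept:
        seg = project_trajectory(seg, trace)
        sl = slice(seg.window_start_index, seg.window_end_index + 1)
        t_window = trace.timestamps[sl]
        row: dict = {
            "onset_time": float(trace.timestamps[seg.onset_index]),
            "offset_time": float(trace.timestamps[seg.offset_index]),
            "nominal_amplitude": seg.nominal_amplitude,
            "direction_deg": seg.direction_deg,
        }
        try:
            res = HillTrajectoryModel(
                seg.projected_position,
                t_window,
                onset_hint=float(trace.timestamps[seg.onset_index]),
            ).fit()
            k = res.kinematics
            window_origin = float(t_window[0]) - res.model._dt + res.onset_latency
            row.update(
                fit_amplitude=k.amplitude,
                fit_duration=k.duration,
                fit_peak_velocity=k.peak_velocity,
                fit_onset_time=window_origin + k.t_start,
                E0=res.params.E0,
                Emax=res.params.Emax,
                E50=res.params.E50,
                alpha=res.params.alpha,
                r_squared=res.r_squared,
                converged=res.converged,
            )
        except FitError as exc:
            logger.warning("Hill fit failed at t=%.3f s: %s", row["onset_time"], exc)
            row.update(
                fit_amplitude=np.nan, fit_duration=np.nan, fit_peak_velocity=np.nan,
                fit_onset_time=np.nan, E0=np.nan, Emax=np.nan, E50=np.nan,
                alpha=np.nan, r_squared=np.nan, converged=False,
            )
        try:
            amp, dur, pv = threshold_kinematics(
                seg, trace, velocity_threshold=endpoint_threshold,
                velocity_method=baseline_velocity_method,
            )
            row.update(thr_amplitude=amp, thr_duration=dur, thr_peak_velocity=pv)
        except FitError:
            row.update(thr_amplitude=np.nan, thr_duration=np.nan, thr_peak_velocity=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
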