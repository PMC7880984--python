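"""Synthetic gaze traces and main-sequence point sets with known truth.

The generator emulates a fixation/saccade recording: gaze holds still
(plus white measurement noise), then sweeps along a Hill sigmoid toward
the next target, whose peak velocity is dictated by a configurable
main-sequence law. Because every saccade's Hill parameters are known, the
ground truth for amplitude, duration, peak velocity and onset is exact,
which is what makes the detection / fitting / bootstrap stages testable
without recorded data.

Defaults: a fixed-sqrt law with VA = 40 deg/s at A_th = 1 deg and
V = 100 deg/s·deg^-1/2 (mid-range of typical adult values), Hill slope
alpha drawn uniformly from [1.6, 2.6], log-uniform amplitudes on
[1.1, 25] deg (natural viewing is dominated by short saccades), fixations
of 0.3-0.5 s, 250 Hz sampling and 0.05 deg position noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .mainseq import DEFAULT_A_TH, DEFAULT_VA, model_function
from .trace_io import GazeTrace
from .trajectory import (
    END_FRACTION,
    START_FRACTION,
    HillParams,
    extract_kinematics,
    hill_value,
)

__all__ = ["SynthConfig", "hill_params_for", "generate_trace", "generate_points"]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generator."""

    law_id: str = "fixed_sqrt"
    law_params: dict = field(default_factory=lambda: {"V": 100.0})
    law_constants: dict = field(
        default_factory=lambda: {"VA": DEFAULT_VA, "A_th": DEFAULT_A_TH}
    )
    alpha_range: tuple[float, float] = (1.6, 2.6)
    noise_sd: float = 0.05  # deg, additive white position noise
    sampling_frequency: float = 250.0  # Hz
    fixation_duration: tuple[float, float] = (0.3, 0.5)  # s, uniform
    amplitude_range: tuple[float, float] = (1.1, 25.0)  # deg, log-uniform
    n_saccades: int = 100
    relative_noise: float = 0.15  # velocity scatter for generate_points
    position_bound: float = 22.0  # deg, keep gaze within +/- this box
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.sampling_frequency <= 0:
            raise ParameterError("sampling_frequency must be > 0")
        if self.amplitude_range[0] <= 0:
            raise ParameterError("amplitudes must be > 0")

    def law(self, amplitude: np.ndarray) -> np.ndarray:
        """Evaluate the configured main-sequence law."""
        fn = model_function(self.law_id)
        return fn(np.asarray(amplitude, dtype=float), self.law_params, self.law_constants)


def _peak_gain(alpha: float) -> float:
    """h(alpha) in v_peak = (|Emax - E0| / E50) * h(alpha)."""
    c = ((alpha - 1.0) / (alpha + 1.0)) ** (1.0 / alpha)
    return alpha * c ** (alpha - 1.0) / (1.0 + c**alpha) ** 2


def hill_params_for(
    amplitude: float, target_peak_velocity: float, alpha: float
) -> HillParams:
    """Hill parameters realizing a requested amplitude and peak velocity.

    Inverts the closed forms: the velocity peak scales as
    v_peak = (|Emax - E0| / E50) * h(alpha), so E50 follows directly once
    the asymptotic displacement is chosen. Emax is inflated by 1/0.96 so
    that the 2-98% amplitude equals the requested amplitude exactly.
    """
    if amplitude <= 0 or target_peak_velocity <= 0:
        raise ParameterError("amplitude and target peak velocity must be > 0")
    if alpha <= 1:
        raise ParameterError("alpha must exceed 1")
    emax = amplitude / (END_FRACTION - START_FRACTION)
    e50 = emax * _peak_gain(alpha) / target_peak_velocity
    return HillParams(E0=0.0, Emax=emax, E50=e50, alpha=alpha)


def generate_trace(config: SynthConfig) -> tuple[GazeTrace, pd.DataFrame]:
    """Simulate a gaze trace of alternating fixations and saccades.

    Each saccade event starts a Hill trajectory toward the next target;
    the sigmoid keeps relaxing toward its asymptote during the following
    fixation, so there is no artificial position jump anywhere. Ground
    truth (onset time at the 2% point, amplitude, duration, peak velocity,
    direction) comes from the closed forms and, with ``noise_sd = 0``,
    lies exactly on the configured main-sequence law.

    Returns the trace and a per-saccade ground-truth table; deterministic
    for a given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_frequency
    dt = 1.0 / fs
    lo_a, hi_a = config.amplitude_range

    # sample the event sequence first, then lay it out on a uniform clock
    events = []
    pos = np.array([0.0, 0.0])
    t_cursor = float(rng.uniform(*config.fixation_duration))
    truth_rows = []
    for i in range(config.n_saccades):
        amplitude = float(np.exp(rng.uniform(np.log(lo_a), np.log(hi_a))))
        # re-draw direction until the target stays inside the box
        for _ in range(100):
            direction = float(rng.uniform(0.0, 360.0))
            step = amplitude / (END_FRACTION - START_FRACTION)
            target = pos + step * np.array(
                [np.cos(np.radians(direction)), np.sin(np.radians(direction))]
            )
            if np.all(np.abs(target) <= config.position_bound):
                break
        else:  # pull back to center as a last resort
            direction = float(
                np.degrees(np.arctan2(-pos[1], -pos[0]))
            )
            target = pos + step * np.array(
                [np.cos(np.radians(direction)), np.sin(np.radians(direction))]
            )
        alpha = float(rng.uniform(*config.alpha_range))
        v_peak = float(config.law(np.array([amplitude]))[0])
        params = hill_params_for(amplitude, v_peak, alpha)
        k = extract_kinematics(params)
        events.append(
            {
                "t_event": t_cursor,  # Hill time origin
                "origin": pos.copy(),
                "unit": (target - pos) / np.hypot(*(target - pos)),
                "params": params,
            }
        )
        truth_rows.append(
            {
                "saccade": i,
                "onset_time": t_cursor + k.t_start,
                "amplitude": k.amplitude,
                "duration": k.duration,
                "peak_velocity": k.peak_velocity,
                "direction_deg": ((direction + 180.0) % 360.0) - 180.0,
                "alpha": alpha,
                "E50": params.E50,
            }
        )
        # next event: after the saccade has essentially landed plus a fixation
        t_cursor += k.t_end + float(rng.uniform(*config.fixation_duration))
        pos = target

    total_t = t_cursor + float(rng.uniform(*config.fixation_duration))
    n = int(np.ceil(total_t * fs)) + 1
    t = np.arange(n) * dt
    az = np.zeros(n)
    el = np.zeros(n)
    # superpose each saccade's displacement from its own onset onward
    for ev in events:
        rel = t - ev["t_event"]
        active = rel > 0
        disp = hill_value(ev["params"], rel[active])
        az[active] += disp * ev["unit"][0]
        el[active] += disp * ev["unit"][1]
    if config.noise_sd > 0:
        az = az + rng.normal(0.0, config.noise_sd, size=n)
        el = el + rng.normal(0.0, config.noise_sd, size=n)
    trace = GazeTrace(t, az, el, sampling_frequency=fs, eye_label="unknown")
    return trace, pd.DataFrame(truth_rows)


def generate_points(config: SynthConfig) -> pd.DataFrame:
    """Sample main-sequence points directly, bypassing trace simulation.

    Amplitudes are log-uniform on the configured range; peak velocities
    are the law values times (1 + eps) with eps ~ N(0, relative_noise).
    Fast path for the model-zoo and bootstrap tests.
    """
    rng = np.random.default_rng(config.seed)
    lo_a, hi_a = config.amplitude_range
    amp = np.exp(rng.uniform(np.log(lo_a), np.log(hi_a), size=config.n_saccades))
    v = config.law(amp)
    if config.relative_noise > 0:
        v = v * (1.0 + rng.normal(0.0, config.relative_noise, size=config.n_saccades))
    v = np.maximum(v, 1e-6)
    return pd.DataFrame(
        {
            "amplitude": amp,
            "peak_velocity": v,
            "direction_deg": rng.uniform(-180.0, 180.0, size=config.n_saccades),
            "source_id": np.arange(config.n_saccades),
        }
    )
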