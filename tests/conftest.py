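import numpy as np
import pytest

from saccfit.synth import SynthConfig, generate_trace
from saccfit.trajectory import HillParams


@pytest.fixture(scope="session")
def reference_hill() -> HillParams:
    """The worked single-saccade example used across modules."""
    return HillParams(E0=0.0, Emax=10.0, E50=0.02, alpha=2.0)


@pytest.fixture(scope="session")
def noiseless_trace():
    """20 noiseless synthetic saccades at 250 Hz with ground truth."""
    cfg = SynthConfig(n_saccades=20, noise_sd=0.0, seed=3)
    return generate_trace(cfg)


@pytest.fixture(scope="session")
def noisy_trace():
    """100 saccades at 250 Hz with default (0.05 deg) position noise."""
    cfg = SynthConfig(n_saccades=100, noise_sd=0.05, seed=17)
    return generate_trace(cfg)


def single_saccade_trace(amplitude=10.0, fs=250.0, noise_sd=0.0, seed=0, alpha=2.0):
    """One fixation-saccade-fixation trace built directly (no generator),
    handy for deterministic detection tests."""
    from saccfit.synth import hill_params_for
    from saccfit.trajectory import hill_value
    from saccfit.trace_io import GazeTrace
    from saccfit.mainseq import model_function

    law = model_function("fixed_sqrt")
    pv = float(law(np.array([amplitude]), {"V": 100.0}, {"VA": 40.0, "A_th": 1.0})[0])
    params = hill_params_for(amplitude, pv, alpha)
    dt = 1.0 / fs
    t = np.arange(0.0, 0.8, dt)
    rel = t - 0.3
    az = np.where(rel > 0, hill_value(params, np.maximum(rel, 0.0)), 0.0)
    el = np.zeros_like(az)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        az = az + rng.normal(0, noise_sd, az.size)
        el = el + rng.normal(0, noise_sd, el.size)
    return GazeTrace(t, az, el, sampling_frequency=fs), params
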