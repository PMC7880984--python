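# saccfit

Model-based saccade kinematics and main-sequence estimation from gaze
traces.

## The problem

Saccades — the rapid ballistic eye movements between fixations — are
characterized by their *amplitude*, *duration* and *peak velocity*, and by
the stereotyped relation between amplitude and peak velocity known as the
**main sequence**. The classical way to measure these quantities is to
differentiate the gaze signal numerically (a two-point difference,
V(t) = ‖X(t) − X(t−1)‖/Δt), threshold the resulting speed to mark the
saccade's start and end, and read the peak velocity off the largest
velocity sample. That pipeline is doubly fragile: numerical
differentiation amplifies measurement noise, and every quantity is
quantized to the sampling clock — each threshold-marked endpoint can be
wrong by a full sampling period (±5 ms at 200 Hz, ±20 ms at 50 Hz), and
the true velocity peak almost always falls *between* two samples, so peak
velocity is systematically underestimated. This is why classical
guidelines demand 330 Hz or faster eye trackers.

`saccfit` instead fits a model to the *spatial trajectory* of each
saccade. The projected position along the fixation-to-fixation direction
is fitted with a Hill-form sigmoid

```
y(t) = E0 + (Emax − E0) · t^α / (E50^α + t^α),        t > 0
```

where `E0`/`Emax` are the pre/post-saccadic positions, `E50` the time of
half displacement and `α > 1` the slope exponent. Every kinematic
quantity then has a closed form with sub-sample resolution:

- time at displacement fraction f: `t_f = E50 · (f/(1−f))^(1/α)`;
  start/end are the 2% and 98% points, so
  `duration = t_0.98 − t_0.02` and `amplitude = 0.96·|Emax − E0|`
- peak velocity occurs at `t_peak = E50 · ((α−1)/(α+1))^(1/α)` and equals
  the analytic derivative there.

Because the estimates come from an analytic fit rather than from sample
arithmetic, they remain reliable down to ~50 Hz — which opens oculomotor
assessment to consumer-grade eye trackers.

On top of the per-saccade kinematics the package fits and compares nine
main-sequence models from the literature (slope, line, quadratic
"cubic", `V√x`, `VA + V√(x − A_th)`, power law, log-log, saturating
exponential, sigmoid), and provides the bootstrap machinery to judge
them: goodness of fit (adjusted R²) and repeatability (pairwise symmetric
MAPE between bootstrap curves) as a function of boot size, a Hotelling T²
test for the boot size beyond which estimates stop changing,
range-generalization matrices, test-retest MAPE across recordings, and a
sampling-frequency robustness study on decimated traces.

A synthetic generator produces gaze traces with exactly known ground
truth (fixations plus Hill-shaped saccades whose peak velocities follow a
configured main-sequence law), so the whole pipeline is testable without
recorded data.

## Worked example

```python
import numpy as np
import saccfit as sf
from saccfit.synth import SynthConfig, generate_trace
from saccfit.mainseq import fit_model

# 100 synthetic saccades at 250 Hz, 0.05 deg measurement noise,
# peak velocities on the law v = 40 + 100*sqrt(A - 1)
trace, truth = generate_trace(SynthConfig(n_saccades=100, noise_sd=0.05, seed=7))

# detect, project and fit every saccade (both estimators side by side)
df = sf.analyze_trace(trace)

# one saccade in detail
seg = sf.project_trajectory(sf.detect_saccades(trace)[0], trace)
sl = slice(seg.window_start_index, seg.window_end_index + 1)
res = sf.HillTrajectoryModel(
    seg.projected_position, trace.timestamps[sl],
    onset_hint=float(trace.timestamps[seg.onset_index]),
).fit()
print(res.summary())

# the main sequence across all fitted saccades
ok = df.converged & np.isfinite(df.fit_amplitude) & np.isfinite(df.fit_peak_velocity)
ms = fit_model(df.fit_amplitude[ok], df.fit_peak_velocity[ok], "fixed_sqrt",
               constants={"VA": 40.0, "A_th": 1.0})
print(ms.summary())
```

prints

```
Hill trajectory fit
===================
n samples        : 38
converged        : True
R^2              : 0.999950
E0    [deg]      : 0.0638
Emax  [deg]      : 18.9283
E50   [s]        : 0.025744
alpha            : 1.7964
onset latency [s]: 0.029382 (window start -> motion onset)
amplitude [deg]  : 18.1099   (2-98% of |Emax - E0|)
duration  [ms]   : 221.72
peak vel. [deg/s]: 456.97  at t = 12.79 ms

Main-sequence fit: fixed_sqrt
==================================
n points     : 99
converged    : True
R^2          : 0.996047
adjusted R^2 : 0.996006
VA           : 40.0000 (constant)
A_th         : 1.0000 (constant)
V            : 99.9177
```

The first block is one 18-deg saccade: the sigmoid explains 99.995% of
the positional variance, and its closed forms give the duration and the
456.97 deg/s peak with sub-sample resolution. The second block is the
one-parameter main-sequence fit over all 99 usable saccades: the
recovered slope V = 99.9 deg·s⁻¹·deg⁻½ matches the generating value of
100 to 0.1%.

The same workflows are available from the shell:

```sh
saccfit synth --n-saccades 100 --seed 7 --out trace.csv --truth truth.csv
saccfit detect trace.csv --out saccades.csv
saccfit mainseq saccades.csv --models fixed_sqrt,sqrt --boots 1000 --out-dir results/
saccfit subsample trace.csv --out subsampling.csv
```

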