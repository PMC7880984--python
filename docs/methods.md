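# Methods

This note documents the models, estimators and numerical choices in
`saccfit`, and what the synthetic studies can and cannot show.

## Trajectory model

A saccade's projected position (degrees along the straight line from the
pre-saccadic to the post-saccadic fixation centroid) is modelled as a
Hill sigmoid

    y(t) = E0 + (Emax − E0) · t^α / (E50^α + t^α),    t > 0,

with E0, Emax the plateau positions (deg), E50 the half-displacement time
(s) and α > 1 a dimensionless slope exponent. The form is monotone,
starts at E0 with zero velocity (for α > 1), accelerates fast and
decelerates slowly toward Emax — the canonical saccade shape. The
derived kinematics are closed-form:

- t at displacement fraction f: `t_f = E50 (f/(1−f))^(1/α)`; the start
  and end are the 2% and 98% points, so the reported amplitude is
  0.96·|Emax − E0| (the asymptotic |Emax − E0| is also exposed);
- velocity peak at `t_peak = E50 ((α−1)/(α+1))^(1/α)`, with
  `v_peak = (|Emax − E0|/E50) · h(α)`,
  `h(α) = α c^(α−1)/(1+c^α)²`, `c = ((α−1)/(α+1))^(1/α)`.

An equivalent printed variant with denominator `(E50 + t)^α` circulates
in the literature; it does not place half saturation at t = E50 and is
implemented only behind `denominator="printed"` for comparison.

### Fitting

`HillTrajectoryModel.fit()` minimizes squared residuals with scipy's
bounded trust-region reflective least squares (`method="trf"`; the
classical Levenberg–Marquardt implementation does not support the bounds
below). Initialization: E0/Emax from the medians of the first/last three
window samples, E50 from the first midpoint crossing, α = 2, with
restarts at α ∈ {1.5, 2, 3}. All starts are run and the lowest-cost
solution kept: when the transition covers only a few samples the loss
surface has shallow local minima, and accepting the first "converged"
solution is not safe.

**Onset latency.** The analysis window deliberately begins before the
physical saccade onset (the pre-saccadic plateau anchors E0), but a Hill
clocked from the window start cannot represent that latency — a
time-shifted Hill is outside the Hill family, and forcing it biases peak
velocity by 10–20% even on noiseless data. The optimizer therefore
carries a fifth internal parameter t0 (model ≡ E0 for t ≤ t0, Hill(t−t0)
after). The public parameter set stays the four Hill parameters; all
closed forms are unchanged, and `onset_latency` locates the motion
origin inside the window. When the detection stage supplies the
threshold-crossing time as `onset_hint`, t0 is confined to ±3 sampling
periods around it, which keeps (E50, α, t0) identifiable even when the
transition spans one or two samples.

**Bounds and diagnostics.** E0/Emax within the window's position range
±5 deg; E50 ∈ [Δt/3, window length] — a half-saturation time below a
third of a sample is not resolvable, and letting E50 → 0 lets the curve
degenerate into a step that chases noise; α ∈ (1, 10]. A fit whose E50
or α ends on a bound is flagged `converged=False`: the parameters are
still returned, but downstream analyses (and the acceptance pipelines)
exclude flagged fits instead of letting their unbounded 1/E50 peak
velocities bias the main sequence. On noisy 50 Hz recordings roughly a
fifth of fits — mostly small saccades whose transition spans a single
sample — are flagged this way.

## Detection

Speed is the Euclidean norm of the componentwise derivative, either the
backward two-point difference ‖X(t) − X(t−1)‖/Δt (`first_difference`,
the classical formula) or the central ‖X(t+1) − X(t−1)‖/(2Δt)
(`central_difference`, less phase lag, the detection default). Saccades
are supra-threshold runs at 20 deg/s; runs closer than 20 ms merge
(below any physiological intersaccadic interval); flanking fixations are
the neighboring sub-threshold intervals, their centroids the per-axis
medians (robust to drift). The analysis window pads the detected run by
max(5 samples, 20 ms) on each side without crossing a neighbor. Saccades
below 1 deg (micro-saccades) are filtered out but returned for audit;
`select_horizontal` keeps directions within ±15 deg of horizontal
(inclusive boundary).

**Noise and thresholding.** For thresholding only, positions are
boxcar-smoothed over 20 ms before differentiation. This matters at high
sampling rates: with 0.1 deg RMS noise at 250 Hz the *mean* of the raw
two-point speed during fixation is ≈22 deg/s — above the detection
threshold — so no post-hoc smoothing of the speed magnitude can work;
the noise must be attenuated before the norm is taken. Saccadic speeds
are an order of magnitude above threshold, so the blurring does not cost
detections, and the raw trace is always used for kinematics. At 50 Hz
and below the smoothing window rounds to one sample and the step is a
no-op.

**The threshold baseline.** `threshold_kinematics` reimplements the
classical estimator the model fit is compared against: endpoints at the
first/last window samples above 50 deg/s, duration as their time
difference, peak velocity as the largest speed sample. Its default
velocity is the backward two-point difference — the formula this
estimator is historically built on; with a centered difference its
timing errors become symmetric and the characteristic low-rate duration
bias disappears, which would misrepresent the method being critiqued.
Each threshold endpoint can be off by one sampling period
(`duration_quantization_error`: 1/fs, i.e. 5 ms at 200 Hz, 20 ms at
50 Hz).

## Main-sequence models

Nine amplitude→peak-velocity models, grouped by free-parameter count
(1: slope `ax`, sqrt `V√x`, fixed-sqrt `VA + V√(x−A_th)`; 2: line,
power law `m x^V`, log-log `exp(V log x + Q)`; 3: "cubic"
`ax² + bx + c`, exponential `V(1 − e^{−(x−A0)/k})`, sigmoid
`Amax/(1+(V50/x)^α)`). Models linear in their parameters are solved in
closed form; log-log by OLS in log–log space (the transformation is the
point of the model, so its residual criterion intentionally differs from
the power law's even though the curves coincide); power law, exponential
and sigmoid by bounded least squares initialized from a log–log
regression, (1.1·max y, 0, 10 deg) and (1.2·max y, median x, 2)
respectively. "Cubic" follows the literature's label for the quadratic
polynomial printed above. The fixed-sqrt constants are data-driven: VA
is the mean peak velocity within ±0.25 deg of A_th = 1 deg, falling back
to 40 deg/s (a typical adult value) with a warning when no such saccades
exist; points at or below A_th are excluded from its fit, with the count
reported. Both plain and adjusted R² are reported
(`R²_adj = 1 − (1−R²)(n−1)/(n−p−1)`).

## Reliability machinery

**MAPE.** Repeatability between two fitted curves is the symmetric mean
absolute percentage error on a common amplitude grid (1–25 deg, step
0.25): `100 · mean |y_a − y_b| / ((y_a + y_b)/2)`. The symmetric
denominator is chosen because both curves are equally valid estimates —
neither is a privileged reference — and it makes the cross-condition
matrix well defined with MAPE(a,b) = MAPE(b,a). Grid points where both
curves are zero contribute zero error.

**Bootstrap.** For each boot size (default 10…100 step 10), `n_boots`
resamples with replacement are fitted; the report stores parameter
vectors, adjusted R² computed against the *full* dataset (the quantity
of interest is how well a resample-based estimate describes all the
data), and all pairwise curve MAPEs. Above 10⁵ pairs a seeded subsample
of pairs is used (size logged; `max_pairs=None` forces the full set).
Fits that fail on a resample are excluded with counts reported.
Everything is bit-reproducible for a fixed seed.

**Stability.** Consecutive boot sizes' parameter collections are
compared with a two-sample Hotelling T² (implemented directly on
`scipy.stats.f`; the pooled covariance is ridge-regularized by
1e-8·trace when singular, and the 1-parameter case reduces exactly to a
t-test). The reported stability size is the smallest size whose
comparison with the next is non-significant at α = 0.05; with an
alternating pattern the first non-significant comparison wins.

**Range generalization.** Models are fitted on bootstrap resamples of
the points with amplitude ≤ each fit range (5…25 deg) and scored
against all points within each eval range — including ranges never seen
during fitting. The matrix holds median adjusted R² across boots.

**Subsampling study.** A trace is decimated by factors 1:2…1:8 (pure
sample dropping from index 0 — emulating a slower device, so no
anti-alias filtering). Saccades on the decimated trace are matched to
the 250 Hz reference by onset-time proximity within one *decimated*
sampling period (onsets on a decimated trace are quantized to
factor/fs, so a tolerance of one original period would unmatch
everything at high factors); unmatched saccades are excluded with
counts reported. For each factor × parameter × estimator the table
reports the two-sided Wilcoxon rank-sum p-value (raw — no
multiple-testing correction, so each cell is read on its own) and an
agreement R² (1 − SS_res/SS_tot with the reference as truth, which
penalizes bias, unlike a correlation).

## Synthetic generator

`generate_trace` emulates a fixation/saccade recording: alternating
fixations (uniform 0.3–0.5 s) and saccades whose Hill parameters are
derived by inverting the closed forms (`hill_params_for`) so that the
2–98% amplitude and the peak velocity are exact by construction. Peak
velocities follow a configurable main-sequence law — default fixed-sqrt
with VA = 40 deg/s, A_th = 1 deg, V = 100 deg·s⁻¹·deg⁻½, mid-range of
typical adult values. Amplitudes are log-uniform on [1.1, 25] deg
(natural viewing is dominated by short saccades), α uniform on
[1.6, 2.6], directions uniform with re-draws that keep gaze within ±22
deg. Each saccade's sigmoid keeps relaxing toward its asymptote through
the following fixation, so the trace has no artificial position jumps.
Measurement noise is additive white Gaussian on position (default
0.05 deg; 0.1 deg in the robustness studies). `generate_points` samples
main-sequence points directly (law value times 1 + ε,
ε ~ N(0, 0.15)) as a fast path for model-zoo studies.

What the generator does *not* emulate: colored tracker noise, blinks
and track losses, drift, glissades/post-saccadic oscillations,
corrective saccades, curved trajectories, and any deviation of the true
trajectory from the Hill family. Passing tests therefore demonstrate
correctness of the estimators under the model's own assumptions and
their robustness to white noise and decimation — not performance on any
particular hardware.

A note on the fixed-sqrt constants in the synthetic studies: because the
amplitude sampler starts at 1.1 deg, the ±0.25-deg band around 1 deg
contains only saccades whose law velocity is already 70–90 deg/s, so the
plug-in VA overestimates the true 40 deg/s. Analyses of synthetic data
therefore pass the generator's known constants explicitly; the plug-in
estimator remains available (and tested) for real recordings, where
saccades at and below 1 deg exist.

## Problem sizes

The bundled studies use sizes chosen to make their statistical patterns
stable: 100 saccades for end-to-end recovery (errors ≤ ~3% at both 250
and 50 Hz), 200 saccades for the subsampling contrasts, 200 bootstrap
replicates and boot sizes 10–100 for the model-complexity comparison,
400 points for range generalization, and a 200-point parameter sweep for
the closed-form-vs-oracle check. All are driven by a single seed.

## Known limitations

- Each eye's trace is analyzed independently; binocular combination
  (cyclopean averaging, vergence) is left to the caller.
- No glissade/PSO or smooth-pursuit event classes; overlapping or
  corrective saccades within the merge window are treated as one event.
- The Hill family is symmetric in neither time nor velocity shape
  beyond what α provides; strongly asymmetric velocity profiles will
  show in the residuals rather than in a dedicated parameter.
- At 50 Hz and below, saccades whose transition spans a single sample
  are frequently flagged unidentifiable under realistic noise; the
  pipelines exclude rather than guess them, which thins small-amplitude
  coverage at low rates.
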