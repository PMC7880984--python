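"""Bootstrap reliability and robustness machinery for main-sequence fits.

Three questions are answered here, all by resampling:

* How repeatable is a fitted main-sequence curve? — pairwise symmetric
  MAPE between bootstrap fits at increasing boot sizes, plus a Hotelling
  T² stability test giving the smallest boot size beyond which parameters
  stop changing.
* How well does a fit on a restricted amplitude range generalize? —
  the range-generalization matrix of median R² (fit range × eval range).
* How robust are per-saccade kinematics to the sampling frequency? —
  the subsampling study compares estimates on a trace against the same
  trace decimated by factors 2..8 with a two-sided Wilcoxon rank-sum test
  and an agreement R².

The MAPE here is symmetric (denominator = mean of the two curves): both
curves in a pair are equally valid estimates, so neither is privileged as
the reference, and MAPE(a, b) == MAPE(b, a) by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .detection import analyze_trace
from .errors import DataError
from .mainseq import (
    DEFAULT_GRID,
    N_PARAMS,
    MainSequenceModel,
    MainSequenceResults,
    adjusted_r_squared,
    compute_fixed_sqrt_constants,
    r_squared,
)
from .trace_io import GazeTrace, downsample

logger = logging.getLogger(__name__)

__all__ = [
    "curve_mape",
    "pairwise_mape",
    "bootstrap_models",
    "stability_test",
    "hotelling_t2",
    "range_generalization",
    "cross_condition_mape",
    "subsampling_study",
    "BootstrapReport",
    "RangeGeneralizationMatrix",
]

DEFAULT_BOOT_SIZES = tuple(range(10, 101, 10))
DEFAULT_N_BOOTS = 1000
#: Above this many curve pairs, a seeded subsample of pairs is used.
DEFAULT_MAX_PAIRS = 100_000


# ----------------------------------------------------------------- MAPE


def _smape_curves(ya: np.ndarray, yb: np.ndarray) -> np.ndarray:
    """Symmetric MAPE (%) between rows of ya and rows of yb, elementwise
    over the last (grid) axis. Grid points where both curves are zero
    (e.g. a fixed-sqrt with VA = 0 at its threshold amplitude) contribute
    zero error."""
    num = np.abs(ya - yb)
    den = 0.5 * (ya + yb)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where((den == 0) & (num == 0), 0.0, num / den)
    return 100.0 * np.mean(ratio, axis=-1)


def curve_mape(
    fit_a: MainSequenceResults, fit_b: MainSequenceResults, grid: np.ndarray = DEFAULT_GRID
) -> float:
    """Symmetric mean absolute percentage error (%) between two fitted
    curves evaluated on a common amplitude grid."""
    ya = fit_a.predict(grid)
    yb = fit_b.predict(grid)
    return float(_smape_curves(ya, yb))


def pairwise_mape(
    curves: np.ndarray,
    max_pairs: int | None = DEFAULT_MAX_PAIRS,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """All-pairs symmetric MAPE among rows of a (n_curves, grid) matrix.

    With ``max_pairs`` set and exceeded, a seeded subsample of pairs is
    evaluated instead (size logged); pass ``max_pairs=None`` for the full
    n(n-1)/2 set.
    """
    n = len(curves)
    if n < 2:
        return np.empty(0)
    total = n * (n - 1) // 2
    if max_pairs is not None and total > max_pairs:
        if rng is None:
            rng = np.random.default_rng(0)
        ii = rng.integers(0, n, size=max_pairs)
        jj = rng.integers(0, n - 1, size=max_pairs)
        jj = np.where(jj >= ii, jj + 1, jj)  # j != i, uniform over off-diagonal
        logger.info("pairwise MAPE: subsampled %d of %d pairs", max_pairs, total)
        return _smape_curves(curves[ii], curves[jj])
    iu, ju = np.triu_indices(n, k=1)
    out = np.empty(total)
    # chunk to bound memory at ~n_chunk * grid floats
    chunk = max(1, 10_000_000 // max(curves.shape[1], 1))
    for s in range(0, total, chunk):
        e = min(s + chunk, total)
        out[s:e] = _smape_curves(curves[iu[s:e]], curves[ju[s:e]])
    return out


# ------------------------------------------------------------ bootstrap


@dataclass
class BootstrapReport:
    """Bootstrap distributions for one model across boot sizes."""

    model_id: str
    boot_sizes: tuple[int, ...]
    n_boots: int
    rng_seed: int
    param_names: tuple[str, ...]
    params: dict[int, np.ndarray]  # size -> (n_ok, p) parameter vectors
    r_squared_adjusted: dict[int, np.ndarray]  # size -> (n_ok,)
    mape: dict[int, np.ndarray]  # size -> pairwise MAPE values (%)
    n_failed: dict[int, int]
    stability_size: int | None = None

    def summary_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-size summary (medians and quartiles)."""
        rows = []
        for s in self.boot_sizes:
            m = self.mape[s]
            r2 = self.r_squared_adjusted[s]
            rows.append(
                {
                    "model_id": self.model_id,
                    "boot_size": s,
                    "n_boots_ok": len(r2),
                    "n_failed": self.n_failed[s],
                    "r2_adj_median": float(np.median(r2)) if len(r2) else np.nan,
                    "mape_median": float(np.median(m)) if len(m) else np.nan,
                    "mape_q1": float(np.percentile(m, 25)) if len(m) else np.nan,
                    "mape_q3": float(np.percentile(m, 75)) if len(m) else np.nan,
                    "stability_size": self.stability_size,
                }
            )
        return pd.DataFrame(rows)


def _fit_resamples(
    x: np.ndarray,
    y: np.ndarray,
    model_id: str,
    constants: dict | None,
    sizes: tuple[int, ...],
    n_boots: int,
    rng: np.random.Generator,
    eval_x: np.ndarray,
    eval_y: np.ndarray,
    grid: np.ndarray | None,
):
    """Core loop: per boot size, fit n_boots resamples-with-replacement.

    Returns per-size parameter matrices, adjusted R² against the supplied
    evaluation set, curve values on the grid and failure counts.
    """
    n = len(x)
    p = N_PARAMS[model_id]
    params_by_size: dict[int, np.ndarray] = {}
    r2_by_size: dict[int, np.ndarray] = {}
    curves_by_size: dict[int, np.ndarray] = {}
    failed: dict[int, int] = {}
    names: tuple[str, ...] | None = None
    for size in sizes:
        idx = rng.integers(0, n, size=(n_boots, size))
        vecs, r2s, curves = [], [], []
        n_fail = 0
        for b in range(n_boots):
            xi, yi = x[idx[b]], y[idx[b]]
            try:
                res = MainSequenceModel(xi, yi, model=model_id, constants=constants).fit()
                if not res.converged:
                    raise DataError("non-convergence")
            except Exception:
                n_fail += 1
                continue
            if names is None:
                names = tuple(res.params.keys())
            vecs.append([res.params[k] for k in names])
            r2_full = r_squared(eval_y, res.predict(eval_x))
            r2s.append(adjusted_r_squared(r2_full, len(eval_x), p))
            if grid is not None:
                curves.append(res.predict(grid))
        params_by_size[size] = np.asarray(vecs, dtype=float).reshape(len(vecs), -1)
        r2_by_size[size] = np.asarray(r2s, dtype=float)
        if grid is not None:
            curves_by_size[size] = np.asarray(curves, dtype=float).reshape(len(curves), -1)
        failed[size] = n_fail
        if n_fail:
            logger.info("%s boot size %d: %d failed fit(s) excluded", model_id, size, n_fail)
    return names or (), params_by_size, r2_by_size, curves_by_size, failed


def bootstrap_models(
    amplitude: np.ndarray,
    peak_velocity: np.ndarray,
    model_id: str,
    boot_sizes: tuple[int, ...] = DEFAULT_BOOT_SIZES,
    n_boots: int = DEFAULT_N_BOOTS,
    seed: int = 0,
    constants: dict | None = None,
    grid: np.ndarray = DEFAULT_GRID,
    max_pairs: int | None = DEFAULT_MAX_PAIRS,
) -> BootstrapReport:
    """Bootstrap one main-sequence model at increasing boot sizes.

    For each boot size, ``n_boots`` resamples with replacement are fitted;
    the report stores parameter vectors, adjusted R² computed against the
    *full* point set, and all pairwise curve MAPEs on ``grid``. Fully
    deterministic given ``seed``. Constants for fixed_sqrt are computed
    once from the full dataset (not per resample) unless supplied.
    """
    x = np.asarray(amplitude, dtype=float)
    y = np.asarray(peak_velocity, dtype=float)
    if len(x) == 0:
        raise DataError("empty point set")
    if model_id == "fixed_sqrt" and constants is None:
        constants = compute_fixed_sqrt_constants(x, y)
    rng = np.random.default_rng(seed)
    names, params, r2s, curves, failed = _fit_resamples(
        x, y, model_id, constants, tuple(boot_sizes), n_boots, rng, x, y, grid
    )
    mape = {
        s: pairwise_mape(curves[s], max_pairs=max_pairs, rng=rng) for s in boot_sizes
    }
    report = BootstrapReport(
        model_id=model_id,
        boot_sizes=tuple(boot_sizes),
        n_boots=n_boots,
        rng_seed=seed,
        param_names=names,
        params=params,
        r_squared_adjusted=r2s,
        mape=mape,
        n_failed=failed,
    )
    try:
        report.stability_size = stability_test(params, tuple(boot_sizes))
    except DataError:
        report.stability_size = None
    return report


# ------------------------------------------------------------ stability


def hotelling_t2(a: np.ndarray, b: np.ndarray, ridge: float = 1e-8) -> tuple[float, float]:
    """Two-sample Hotelling T² test; returns (T², p-value).

    Pooled covariance is ridge-regularized by ``ridge * trace`` when
    singular. With one-dimensional parameter vectors this reduces exactly
    to the squared two-sample t statistic.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n1, p = a.shape
    n2 = b.shape[0]
    if n1 < 2 or n2 < 2:
        raise DataError("need at least 2 vectors per group for Hotelling T²")
    diff = a.mean(axis=0) - b.mean(axis=0)
    s_pooled = ((n1 - 1) * np.cov(a, rowvar=False) + (n2 - 1) * np.cov(b, rowvar=False)) / (
        n1 + n2 - 2
    )
    s_pooled = np.atleast_2d(s_pooled)
    try:
        sol = np.linalg.solve(s_pooled, diff)
    except np.linalg.LinAlgError:
        eps = ridge * np.trace(s_pooled)
        logger.info("singular pooled covariance; ridge-regularized by %.3g", eps)
        sol = np.linalg.solve(s_pooled + eps * np.eye(p), diff)
    t2 = float(n1 * n2 / (n1 + n2) * diff @ sol)
    dof2 = n1 + n2 - p - 1
    if dof2 <= 0:
        raise DataError("not enough samples for the F transform of T²")
    f_stat = t2 * dof2 / ((n1 + n2 - 2) * p)
    pval = float(stats.f.sf(f_stat, p, dof2))
    return t2, pval


def stability_test(
    params_by_size: dict[int, np.ndarray],
    boot_sizes: tuple[int, ...] | None = None,
    alpha: float = 0.05,
) -> int | None:
    """Smallest boot size whose parameters stop changing.

    Consecutive boot sizes' parameter collections are compared with a
    two-sample Hotelling T² (a plain t-test in the 1-parameter case); the
    first size whose comparison with the next is non-significant at
    ``alpha`` is returned, or None if every comparison is significant.
    """
    sizes = tuple(sorted(params_by_size)) if boot_sizes is None else tuple(boot_sizes)
    if len(sizes) < 2:
        raise DataError("need at least two boot sizes")
    for s_lo, s_hi in zip(sizes[:-1], sizes[1:]):
        a, b = params_by_size[s_lo], params_by_size[s_hi]
        if len(a) < 2 or len(b) < 2:
            continue
        if a.shape[1] == 1:
            _, p = stats.ttest_ind(a[:, 0], b[:, 0], equal_var=True)
        else:
            _, p = hotelling_t2(a, b)
        if p >= alpha:
            return int(s_lo)
    return None


# ------------------------------------------- range generalization


@dataclass
class RangeGeneralizationMatrix:
    """Median R² of fits restricted to one amplitude range, evaluated on
    points within each (possibly wider) range."""

    model_id: str
    fit_ranges: tuple[float, ...]
    eval_ranges: tuple[float, ...]
    r_squared: pd.DataFrame  # index fit_range, columns eval_range


DEFAULT_RANGES = (5.0, 10.0, 15.0, 20.0, 25.0)


def range_generalization(
    amplitude: np.ndarray,
    peak_velocity: np.ndarray,
    model_id: str,
    fit_ranges: tuple[float, ...] = DEFAULT_RANGES,
    eval_ranges: tuple[float, ...] = DEFAULT_RANGES,
    n_boots: int = 200,
    seed: int = 0,
    constants: dict | None = None,
) -> RangeGeneralizationMatrix:
    """Fit within each eccentricity range, evaluate against every range.

    Bootstrap fits use only points with amplitude <= fit range (resample
    size = subset size); goodness of fit is computed against all points
    with amplitude <= eval range, not just those used for the fit. The
    matrix holds the median adjusted R² across boots. fixed_sqrt constants
    come from the full dataset so every row shares them.
    """
    x = np.asarray(amplitude, dtype=float)
    y = np.asarray(peak_velocity, dtype=float)
    if model_id == "fixed_sqrt" and constants is None:
        constants = compute_fixed_sqrt_constants(x, y)
    rng = np.random.default_rng(seed)
    p = N_PARAMS[model_id]
    mat = {}
    for fr in fit_ranges:
        sub = x <= fr
        xs, ys = x[sub], y[sub]
        if len(xs) < p + 1:
            logger.warning("fit range <=%g deg has %d point(s); row skipped", fr, len(xs))
            continue
        row = {er: [] for er in eval_ranges}
        for _ in range(n_boots):
            idx = rng.integers(0, len(xs), size=len(xs))
            try:
                res = MainSequenceModel(
                    xs[idx], ys[idx], model=model_id, constants=constants
                ).fit()
            except Exception:
                continue
            for er in eval_ranges:
                ev = x <= er
                r2 = r_squared(y[ev], res.predict(x[ev]))
                row[er].append(adjusted_r_squared(r2, int(ev.sum()), p))
        mat[fr] = {er: float(np.median(v)) if v else np.nan for er, v in row.items()}
    frame = pd.DataFrame(mat).T
    frame.index.name = "fit_range"
    frame.columns.name = "eval_range"
    return RangeGeneralizationMatrix(model_id, tuple(mat.keys()), tuple(eval_ranges), frame)


# ------------------------------------------- cross-condition MAPE


def cross_condition_mape(
    amplitude_a: np.ndarray,
    peak_velocity_a: np.ndarray,
    amplitude_b: np.ndarray,
    peak_velocity_b: np.ndarray,
    model_id: str,
    boot_sizes: tuple[int, ...] = DEFAULT_BOOT_SIZES,
    n_boots: int = DEFAULT_N_BOOTS,
    seed: int = 0,
    constants_a: dict | None = None,
    constants_b: dict | None = None,
    grid: np.ndarray = DEFAULT_GRID,
    max_pairs: int | None = DEFAULT_MAX_PAIRS,
) -> pd.DataFrame:
    """Test-retest / cross-condition repeatability of a fitted curve.

    For each boot size, ``n_boots`` bootstrap fits per condition; the MAPE
    is computed between every fit from A and every fit from B (all
    n_boots² pairs, or a seeded subsample of ``max_pairs``), and summarized
    by median and quartiles per size.
    """
    xa = np.asarray(amplitude_a, dtype=float)
    ya = np.asarray(peak_velocity_a, dtype=float)
    xb = np.asarray(amplitude_b, dtype=float)
    yb = np.asarray(peak_velocity_b, dtype=float)
    if len(xa) == 0 or len(xb) == 0:
        raise DataError("both point sets must be non-empty")
    if model_id == "fixed_sqrt":
        if constants_a is None:
            constants_a = compute_fixed_sqrt_constants(xa, ya)
        if constants_b is None:
            constants_b = compute_fixed_sqrt_constants(xb, yb)
    rng = np.random.default_rng(seed)
    sizes = tuple(boot_sizes)
    _, _, _, curves_a, _ = _fit_resamples(
        xa, ya, model_id, constants_a, sizes, n_boots, rng, xa, ya, grid
    )
    _, _, _, curves_b, _ = _fit_resamples(
        xb, yb, model_id, constants_b, sizes, n_boots, rng, xb, yb, grid
    )
    rows = []
    for s in sizes:
        ca, cb = curves_a[s], curves_b[s]
        na, nb = len(ca), len(cb)
        if na == 0 or nb == 0:
            rows.append({"boot_size": s, "n_pairs": 0, "mape_median": np.nan,
                         "mape_q1": np.nan, "mape_q3": np.nan})
            continue
        total = na * nb
        if max_pairs is not None and total > max_pairs:
            ii = rng.integers(0, na, size=max_pairs)
            jj = rng.integers(0, nb, size=max_pairs)
            vals = _smape_curves(ca[ii], cb[jj])
            logger.info(
                "cross MAPE boot size %d: subsampled %d of %d pairs", s, max_pairs, total
            )
        else:
            vals = np.empty(total)
            for i in range(na):  # chunk row by row
                vals[i * nb:(i + 1) * nb] = _smape_curves(ca[i][None, :], cb)
        rows.append(
            {
                "boot_size": s,
                "n_pairs": len(vals),
                "mape_median": float(np.median(vals)),
                "mape_q1": float(np.percentile(vals, 25)),
                "mape_q3": float(np.percentile(vals, 75)),
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------- subsampling study


SUBSAMPLING_PARAMETERS = ("amplitude", "duration", "peak_velocity")
_COLUMNS = {
    ("fit", "amplitude"): "fit_amplitude",
    ("fit", "duration"): "fit_duration",
    ("fit", "peak_velocity"): "fit_peak_velocity",
    ("threshold", "amplitude"): "thr_amplitude",
    ("threshold", "duration"): "thr_duration",
    ("threshold", "peak_velocity"): "thr_peak_velocity",
}


def _agreement_r2(reference: np.ndarray, estimate: np.ndarray) -> float:
    """R² of the estimates against the reference values (1 - SS_res/SS_tot
    with the reference as truth); penalizes bias, unlike a correlation."""
    ss_tot = float(np.sum((reference - reference.mean()) ** 2))
    if ss_tot == 0:
        return float("nan")
    return 1.0 - float(np.sum((estimate - reference) ** 2)) / ss_tot


def subsampling_study(
    trace: GazeTrace,
    factors: tuple[int, ...] = tuple(range(1, 9)),
    match_tolerance_s: float | None = None,
    **analyze_kwargs,
) -> pd.DataFrame:
    """Sampling-frequency robustness of saccade kinematics.

    The trace is decimated by each factor; saccades on the decimated trace
    are matched to the reference (factor 1) saccades by onset-time
    proximity (default tolerance: one *decimated* sampling period). For
    every factor × parameter × method the table reports the two-sided
    Wilcoxon rank-sum p-value between reference and decimated estimates
    over matched saccades, and the agreement R² between the matched pairs.
    Unmatched saccades are excluded with their count reported. p-values
    are raw (no multiple-testing correction).
    """
    ref = analyze_trace(trace, **analyze_kwargs)
    if len(ref) == 0:
        raise DataError("no saccades detected on the reference trace")
    ref_onsets = ref["onset_time"].to_numpy()
    rows = []
    for factor in factors:
        sub = downsample(trace, factor)
        table = analyze_trace(sub, **analyze_kwargs) if factor > 1 else ref
        tol = (
            match_tolerance_s
            if match_tolerance_s is not None
            else factor / trace.sampling_frequency
        )
        if len(table) == 0:
            logger.warning("factor %d: no saccades detected", factor)
            continue
        onsets = table["onset_time"].to_numpy()
        # nearest reference saccade within tolerance, one-to-one
        ref_idx = np.abs(ref_onsets[None, :] - onsets[:, None]).argmin(axis=1)
        dt_match = np.abs(ref_onsets[ref_idx] - onsets)
        matched = dt_match <= tol + 1e-12
        # drop duplicate claims on the same reference saccade (keep nearest)
        order = np.argsort(dt_match)
        seen: set[int] = set()
        keep = np.zeros(len(table), dtype=bool)
        for i in order:
            if matched[i] and ref_idx[i] not in seen:
                seen.add(int(ref_idx[i]))
                keep[i] = True
        n_unmatched = int(len(table) - keep.sum()) + int(len(ref) - keep.sum())
        if keep.sum() < 3:
            logger.warning("factor %d: fewer than 3 matched saccades; skipped", factor)
            continue
        sub_rows = table.loc[keep]
        ref_rows = ref.iloc[ref_idx[keep]]
        for method in ("fit", "threshold"):
            for param in SUBSAMPLING_PARAMETERS:
                col = _COLUMNS[(method, param)]
                a = ref_rows[col].to_numpy()
                b = sub_rows[col].to_numpy()
                ok = np.isfinite(a) & np.isfinite(b)
                a, b = a[ok], b[ok]
                if factor == 1:
                    p_val, r2 = 1.0, 1.0
                elif len(a) < 3:
                    p_val, r2 = np.nan, np.nan
                else:
                    p_val = float(stats.ranksums(a, b).pvalue)
                    r2 = _agreement_r2(a, b)
                rows.append(
                    {
                        "factor": factor,
                        "frequency_hz": trace.sampling_frequency / factor,
                        "parameter": param,
                        "method": method,
                        "n_matched": int(ok.sum()),
                        "n_unmatched": n_unmatched,
                        "p_value": p_val,
                        "r_squared_vs_original": r2,
                    }
                )
    return pd.DataFrame(rows)
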