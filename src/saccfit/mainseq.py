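"""Amplitude → peak-velocity main-sequence models.

Nine classical models, grouped by number of free parameters:

====== ============ =====================================  ==========
params id           equation                               fit
====== ============ =====================================  ==========
1      slope        y = a x                                closed form
1      sqrt         y = V sqrt(x)                          closed form
1      fixed_sqrt   y = VA + V sqrt(x - A_th)              closed form
2      line         y = a x + b                            closed form
2      power_law    y = m x^V                              iterative
2      log_log      y = exp(V log x + Q)                   OLS in log-log
3      cubic        y = a x^2 + b x + c                    closed form
3      exponential  y = V (1 - exp(-(x - A0)/k))           iterative
3      sigmoid      y = Amax / (1 + (V50/x)^alpha)         iterative
====== ============ =====================================  ==========

``fixed_sqrt`` takes its constants from the data: ``VA`` is the mean peak
velocity of saccades at the micro-saccade threshold amplitude ``A_th``
(~40 deg/s at 1 deg in typical adult recordings). The model named
``cubic`` follows the literature's label for the quadratic polynomial
above; the equation, not the name, is what is fitted. ``log_log`` is fitted
by ordinary least squares on the log-transformed data — the transformation
is the point of the model — so its residual criterion intentionally differs
from ``power_law`` even though the two curves are reparameterizations.
"""

from __future__ import annotations

import json
import logging

import numpy as np
from scipy import optimize, stats

from .errors import DataError, DomainError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_IDS",
    "N_PARAMS",
    "MainSequenceModel",
    "MainSequenceResults",
    "fit_model",
    "evaluate_model",
    "compute_fixed_sqrt_constants",
    "model_function",
    "DEFAULT_GRID",
]

MODEL_IDS = (
    "slope", "line", "cubic", "sqrt", "fixed_sqrt",
    "power_law", "log_log", "exponential", "sigmoid",
)

N_PARAMS = {
    "slope": 1, "sqrt": 1, "fixed_sqrt": 1,
    "line": 2, "power_law": 2, "log_log": 2,
    "cubic": 3, "exponential": 3, "sigmoid": 3,
}

DEFAULT_VA = 40.0  # deg/s: typical mean peak velocity of 1-deg saccades
DEFAULT_A_TH = 1.0  # deg: micro-saccade amplitude threshold

#: Amplitude grid (deg) used for curve comparisons downstream: the analyzed
#: 1-25 deg range at 0.25 deg steps (97 points).
DEFAULT_GRID = np.round(np.arange(1.0, 25.0 + 1e-9, 0.25), 10)


def _check_domain(model_id: str, x: np.ndarray, constants: dict) -> None:
    if model_id == "fixed_sqrt":
        a_th = constants.get("A_th", DEFAULT_A_TH)
        if np.any(x < a_th - 1e-12):
            raise DomainError(f"fixed_sqrt requires amplitude >= A_th = {a_th}")
    elif model_id in ("power_law", "log_log", "sigmoid"):
        if np.any(x <= 0):
            raise DomainError(f"{model_id} requires amplitude > 0")
    elif model_id == "sqrt":
        if np.any(x < 0):
            raise DomainError("sqrt requires amplitude >= 0")


def model_function(model_id: str):
    """Return ``f(x, params, constants) -> y`` for a model id."""
    if model_id == "slope":
        return lambda x, p, c: p["a"] * x
    if model_id == "line":
        return lambda x, p, c: p["a"] * x + p["b"]
    if model_id == "cubic":
        return lambda x, p, c: p["a"] * x**2 + p["b"] * x + p["c"]
    if model_id == "sqrt":
        return lambda x, p, c: p["V"] * np.sqrt(x)
    if model_id == "fixed_sqrt":
        return lambda x, p, c: c["VA"] + p["V"] * np.sqrt(np.maximum(x - c["A_th"], 0.0))
    if model_id == "power_law":
        return lambda x, p, c: p["m"] * np.power(x, p["V"])
    if model_id == "log_log":
        return lambda x, p, c: np.exp(p["V"] * np.log(x) + p["Q"])
    if model_id == "exponential":
        return lambda x, p, c: p["V"] * (1.0 - np.exp(-(x - p["A0"]) / p["k"]))
    if model_id == "sigmoid":
        return lambda x, p, c: p["Amax"] / (1.0 + np.power(p["V50"] / x, p["alpha"]))
    raise ParameterError(f"unknown main-sequence model {model_id!r}")


def compute_fixed_sqrt_constants(
    amplitude: np.ndarray,
    peak_velocity: np.ndarray,
    A_th: float = DEFAULT_A_TH,
    band: float = 0.25,
    default_VA: float = DEFAULT_VA,
) -> dict:
    """Data-driven constants for the fixed_sqrt model.

    ``VA`` is the mean peak velocity of saccades with amplitude within
    ``band`` of ``A_th``. With no such points it falls back to
    ``default_VA`` (with a logged warning) so sparse datasets stay usable.
    """
    amplitude = np.asarray(amplitude, dtype=float)
    peak_velocity = np.asarray(peak_velocity, dtype=float)
    near = np.abs(amplitude - A_th) <= band
    if near.any():
        va = float(np.mean(peak_velocity[near]))
    else:
        logger.warning(
            "no saccades within %.3g deg of A_th=%.3g; using default VA=%.3g deg/s",
            band, A_th, default_VA,
        )
        va = float(default_VA)
    return {"VA": va, "A_th": float(A_th)}


class MainSequenceModel:
    """One main-sequence model bound to a set of (amplitude, peak velocity)
    points.

    Parameters
    ----------
    amplitude, peak_velocity
        Per-saccade amplitude (deg) and peak velocity (deg/s); must be
        strictly positive.
    model
        One of :data:`MODEL_IDS`.
    constants
        For ``fixed_sqrt``: ``{"VA": deg/s, "A_th": deg}``. If omitted they
        are computed from the data via
        :func:`compute_fixed_sqrt_constants`.
    """

    def __init__(
        self,
        amplitude: np.ndarray,
        peak_velocity: np.ndarray,
        model: str = "fixed_sqrt",
        constants: dict | None = None,
    ):
        if model not in MODEL_IDS:
            raise ParameterError(f"unknown main-sequence model {model!r}")
        x = np.asarray(amplitude, dtype=float)
        y = np.asarray(peak_velocity, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if np.any(x <= 0) or np.any(y <= 0):
            raise DataError("amplitude and peak velocity must be strictly positive")
        self.model_id = model
        self.constants = dict(constants) if constants else {}
        if model == "fixed_sqrt" and not self.constants:
            self.constants = compute_fixed_sqrt_constants(x, y)
        self.n_excluded = 0
        if model == "fixed_sqrt":
            a_th = self.constants["A_th"]
            keep = x > a_th
            self.n_excluded = int(np.sum(~keep))
            if self.n_excluded:
                logger.info(
                    "fixed_sqrt: excluded %d point(s) with amplitude <= A_th=%.3g",
                    self.n_excluded, a_th,
                )
            x, y = x[keep], y[keep]
        self.exog = x
        self.endog = y
        p = N_PARAMS[model]
        if len(x) < p + 1:
            raise DataError(
                f"{model} needs at least {p + 1} points, got {len(x)}"
            )

    @classmethod
    def from_dataframe(
        cls,
        df,
        model: str = "fixed_sqrt",
        amplitude_col: str = "fit_amplitude",
        peak_velocity_col: str = "fit_peak_velocity",
        constants: dict | None = None,
    ) -> "MainSequenceModel":
        """Build from a per-saccade table such as ``analyze_trace`` output."""
        return cls(
            df[amplitude_col].to_numpy(),
            df[peak_velocity_col].to_numpy(),
            model=model,
            constants=constants,
        )

    # --- fitting -----------------------------------------------------

    def fit(self) -> "MainSequenceResults":
        x, y = self.exog, self.endog
        c = self.constants
        converged = True
        mid = self.model_id
        if mid == "slope":
            params = {"a": float(np.dot(x, y) / np.dot(x, x))}
        elif mid == "line":
            a, b = np.polyfit(x, y, 1)
            params = {"a": float(a), "b": float(b)}
        elif mid == "cubic":
            a, b, cc = np.polyfit(x, y, 2)
            params = {"a": float(a), "b": float(b), "c": float(cc)}
        elif mid == "sqrt":
            s = np.sqrt(x)
            params = {"V": float(np.dot(s, y) / np.dot(s, s))}
        elif mid == "fixed_sqrt":
            s = np.sqrt(x - c["A_th"])
            params = {"V": float(np.dot(s, y - c["VA"]) / np.dot(s, s))}
        elif mid == "log_log":
            reg = stats.linregress(np.log(x), np.log(y))
            params = {"V": float(reg.slope), "Q": float(reg.intercept)}
        else:
            params, converged = self._fit_iterative()
        return MainSequenceResults(self, params, converged)

    def _fit_iterative(self) -> tuple[dict, bool]:
        x, y = self.exog, self.endog
        mid = self.model_id
        fn = model_function(mid)
        if mid == "power_law":
            reg = stats.linregress(np.log(x), np.log(y))
            names = ("m", "V")
            x0 = np.array([np.exp(reg.intercept), reg.slope])
            lo = np.array([1e-9, -10.0])
            hi = np.array([np.inf, 10.0])
        elif mid == "exponential":
            names = ("V", "A0", "k")
            x0 = np.array([1.1 * y.max(), 0.0, 10.0])
            lo = np.array([1e-6, -np.inf, 1e-3])
            hi = np.array([np.inf, x.min(), np.inf])
        else:  # sigmoid
            names = ("Amax", "V50", "alpha")
            x0 = np.array([1.2 * y.max(), np.median(x), 2.0])
            lo = np.array([1e-6, 1e-3, 0.1])
            hi = np.array([5.0 * y.max(), 10.0 * x.max(), 20.0])
        x0 = np.clip(x0, lo + 1e-12, np.where(np.isinf(hi), x0, hi - 1e-9))

        def resid(theta):
            return fn(x, dict(zip(names, theta)), self.constants) - y

        sol = optimize.least_squares(resid, x0, bounds=(lo, hi), method="trf", max_nfev=400)
        if not sol.success:
            logger.debug("%s fit did not converge: %s", mid, sol.message)
        return dict(zip(names, (float(v) for v in sol.x))), bool(sol.success)


class MainSequenceResults:
    """Fitted main-sequence model: parameters, fit quality, prediction."""

    def __init__(self, model: MainSequenceModel, params: dict, converged: bool = True):
        self.model = model
        self.model_id = model.model_id
        self.params = params
        self.constants = model.constants
        self.converged = bool(converged)
        self.n_points = len(model.exog)
        yhat = self.predict(model.exog)
        self.r_squared = r_squared(model.endog, yhat)
        self.r_squared_adjusted = adjusted_r_squared(
            self.r_squared, self.n_points, N_PARAMS[self.model_id]
        )

    @property
    def n_free_params(self) -> int:
        return N_PARAMS[self.model_id]

    def predict(self, amplitudes: np.ndarray) -> np.ndarray:
        """Evaluate the fitted curve on an amplitude grid (deg -> deg/s)."""
        x = np.asarray(amplitudes, dtype=float)
        _check_domain(self.model_id, x, self.constants)
        return model_function(self.model_id)(x, self.params, self.constants)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "params": self.params,
            "constants": self.constants,
            "r_squared": self.r_squared,
            "r_squared_adjusted": self.r_squared_adjusted,
            "n_points": self.n_points,
            "converged": self.converged,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        lines = [
            f"Main-sequence fit: {self.model_id}",
            "=" * 34,
            f"n points     : {self.n_points}"
            + (f"  ({self.model.n_excluded} excluded below A_th)" if self.model.n_excluded else ""),
            f"converged    : {self.converged}",
            f"R^2          : {self.r_squared:.6f}",
            f"adjusted R^2 : {self.r_squared_adjusted:.6f}",
        ]
        for k, v in self.constants.items():
            lines.append(f"{k:<13}: {v:.4f} (constant)")
        for k, v in self.params.items():
            lines.append(f"{k:<13}: {v:.6g}")
        return "\n".join(lines)

    def plot(self, ax=None, grid: np.ndarray | None = None, **scatter_kw):
        """Scatter the data and overlay the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if grid is None:
            lo = max(float(self.model.exog.min()), 1e-3)
            grid = np.linspace(lo, float(self.model.exog.max()), 200)
        ax.plot(self.model.exog, self.model.endog, ".", alpha=0.5, **scatter_kw)
        ax.plot(grid, self.predict(grid), "-", lw=2, label=self.model_id)
        ax.set_xlabel("amplitude [deg]")
        ax.set_ylabel("peak velocity [deg/s]")
        ax.legend()
        return ax


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot."""
    y = np.asarray(y, dtype=float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return float("nan")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def adjusted_r_squared(r2: float, n: int, p: int) -> float:
    """Adjust R^2 for the number of free parameters p."""
    if n <= p + 1:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def fit_model(
    amplitude: np.ndarray,
    peak_velocity: np.ndarray,
    model_id: str,
    constants: dict | None = None,
) -> MainSequenceResults:
    """Functional one-shot fit (see :class:`MainSequenceModel`)."""
    return MainSequenceModel(amplitude, peak_velocity, model=model_id, constants=constants).fit()


def evaluate_model(fit: MainSequenceResults, amplitudes: np.ndarray) -> np.ndarray:
    """Evaluate a fitted model on an amplitude grid (alias of ``predict``)."""
    return fit.predict(amplitudes)
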