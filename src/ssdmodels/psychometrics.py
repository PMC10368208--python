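"""Psychometric fits, intercepts, signal-detection measures, bootstrap CIs.

The psychometric model throughout is the four-parameter logistic (4PL) in the
absolute displacement |x|,

    y(x) = max + (min - max) / (1 + (x / thresh)^slope),

with slope constrained positive so the curve rises from y(0) = min toward max
as |x| grows.  Parameters are fit to the raw binary responses by minimizing
mean squared error (a Bernoulli-likelihood fit is available as an option).
The curve's value at zero displacement -- the intercept -- is the bias
measure used to quantify prior use: for continuous displacement designs it is
the fitted ``min``; for discretized designs with a displacement = 0 condition
it is simply the raw proportion of "jumped" reports there.

Signal-detection measures: d' = Z(hit) - Z(FA) and Criterion
C = -0.5 [Z(hit) + Z(FA)]; lower C means a more liberal "jumped" reporter.
Perfect rates are clamped to 1/(2N) .. 1 - 1/(2N) before the inverse normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PsychometricFit",
    "SDTMeasures",
    "PsychometricCurve",
    "fit_4pl",
    "logistic4",
    "intercept_at_zero",
    "sdt_measures",
    "response_rate_difference",
    "bootstrap_ci",
]


def logistic4(x, min_, max_, thresh, slope):
    """4PL curve in |x|; slope > 0 gives y(0) = min_, y(inf) = max_."""
    x = np.abs(np.asarray(x, dtype=float))
    with np.errstate(divide="ignore"):
        ratio = np.where(x > 0, (x / thresh) ** slope, 0.0)
    return max_ + (min_ - max_) / (1.0 + ratio)


@dataclass(frozen=True)
class PsychometricFit:
    min: float
    max: float
    thresh: float
    slope: float
    sse: float
    intercept: float
    intercept_mode: str  # "fitted_min" | "raw_at_zero"

    def curve(self, x):
        return logistic4(x, self.min, self.max, self.thresh, self.slope)


@dataclass(frozen=True)
class SDTMeasures:
    hit_rate: float
    fa_rate: float
    dprime: float
    criterion: float


class PsychometricCurve:
    """Sklearn-style 4PL psychometric fit.

    Parameters
    ----------
    loss : "mse" (default) or "bernoulli"
        MSE matches the convention of fitting the logistic directly to binary
        data; the likelihood option is statistically tidier but changes the
        estimator.
    n_restarts, random_state : multi-start control for the bounded optimizer.

    Attributes (after ``fit``): ``min_``, ``max_``, ``thresh_``, ``slope_``,
    ``sse_``, ``intercept_`` (= ``min_``).
    """

    def __init__(self, loss: str = "mse", n_restarts: int = 8, random_state: int = 0,
                 thresh_bounds=(1e-2, 20.0), slope_bounds=(1e-2, 30.0)):
        self.loss = loss
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.thresh_bounds = thresh_bounds
        self.slope_bounds = slope_bounds

    def get_params(self, deep: bool = True) -> dict:
        return {
            "loss": self.loss,
            "n_restarts": self.n_restarts,
            "random_state": self.random_state,
            "thresh_bounds": self.thresh_bounds,
            "slope_bounds": self.slope_bounds,
        }

    def set_params(self, **params):
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, x, y):
        x = np.abs(np.asarray(x, dtype=float))
        y = np.asarray(y, dtype=float)
        if len(x) < 20:
            raise ValueError("need at least 20 trials")
        if len(np.unique(np.round(x, 9))) < 3:
            raise ValueError("need at least 3 distinct |x| values")
        if self.loss not in ("mse", "bernoulli"):
            raise ValueError(f"unknown loss {self.loss!r}")

        eps = 1e-9

        def objective(theta):
            yhat = logistic4(x, *theta)
            if self.loss == "mse":
                return float(np.mean((y - yhat) ** 2))
            p = np.clip(yhat, eps, 1 - eps)
            return float(-np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))

        bounds = [(0.0, 1.0), (0.0, 1.0), self.thresh_bounds, self.slope_bounds]
        rng = np.random.default_rng(self.random_state)
        best = None
        for restart in range(self.n_restarts):
            if restart == 0:
                theta0 = [max(y.mean() / 2, 0.01), min(y.mean() + 0.3, 0.99),
                          np.median(x[x > 0]) if (x > 0).any() else 1.0, 2.0]
            else:
                theta0 = [
                    rng.uniform(0, 0.5),
                    rng.uniform(0.5, 1),
                    rng.uniform(*self.thresh_bounds),
                    rng.uniform(0.5, 8.0),
                ]
            res = optimize.minimize(objective, theta0, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
        min_, max_, thresh, slope = best.x
        if min_ > max_:  # enforce the min <= max orientation
            min_, max_ = max_, min_
        self.min_, self.max_ = float(min_), float(max_)
        self.thresh_, self.slope_ = float(thresh), float(slope)
        self.sse_ = float(best.fun)
        self.intercept_ = self.min_
        return self

    def predict(self, x) -> np.ndarray:
        if not hasattr(self, "sse_"):
            raise RuntimeError("curve is not fitted")
        return logistic4(x, self.min_, self.max_, self.thresh_, self.slope_)

    def result_(self, intercept_mode: str = "fitted_min") -> PsychometricFit:
        return PsychometricFit(
            min=self.min_, max=self.max_, thresh=self.thresh_, slope=self.slope_,
            sse=self.sse_, intercept=self.intercept_, intercept_mode=intercept_mode,
        )


def fit_4pl(x_abs, responses, **kwargs) -> PsychometricFit:
    """Fit the 4PL to binary responses; returns a :class:`PsychometricFit`."""
    est = PsychometricCurve(**kwargs)
    est.fit(x_abs, responses)
    return est.result_()


def intercept_at_zero(table: pd.DataFrame) -> float:
    """Raw proportion of "jumped" reports among displacement = 0 trials."""
    zero = table[table["displacement_deg"] == 0]
    if len(zero) == 0:
        raise ValueError(
            "no displacement = 0 trials; use the fitted-min intercept instead"
        )
    return float(zero["response"].astype(float).mean())


def sdt_measures(table: pd.DataFrame) -> SDTMeasures:
    """Hit/false-alarm rates, d' and Criterion from a binary-response table."""
    jumped = table["jumped"].astype(bool)
    resp = table["response"].astype(float)
    n_jump = int(jumped.sum())
    n_nojump = int((~jumped).sum())
    if n_jump == 0 or n_nojump == 0:
        raise ValueError("table must contain both jump and no-jump trials")
    hit = resp[jumped].mean()
    fa = resp[~jumped].mean()
    hit_c = float(np.clip(hit, 1.0 / (2 * n_jump), 1.0 - 1.0 / (2 * n_jump)))
    fa_c = float(np.clip(fa, 1.0 / (2 * n_nojump), 1.0 - 1.0 / (2 * n_nojump)))
    z_hit, z_fa = stats.norm.ppf(hit_c), stats.norm.ppf(fa_c)
    return SDTMeasures(
        hit_rate=hit_c,
        fa_rate=fa_c,
        dprime=float(z_hit - z_fa),
        criterion=float(-0.5 * (z_hit + z_fa)),
    )


def response_rate_difference(table_high: pd.DataFrame, table_low: pd.DataFrame):
    """High-prior minus low-prior "jumped" rate per displacement, plus mean.

    Both tables must share the same (discretized) displacement grid.  Returns
    ``(per_displacement: DataFrame, mean_difference: float)``.
    """
    grid_h = np.sort(table_high["displacement_deg"].unique())
    grid_l = np.sort(table_low["displacement_deg"].unique())
    if len(grid_h) != len(grid_l) or not np.allclose(grid_h, grid_l):
        raise ValueError("displacement grids differ between tables")
    rate_h = table_high.groupby("displacement_deg")["response"].mean()
    rate_l = table_low.groupby("displacement_deg")["response"].mean()
    diff = (rate_h - rate_l).rename("rate_difference").reset_index()
    return diff, float(diff["rate_difference"].mean())


def bootstrap_ci(statistic, table: pd.DataFrame, n_boot: int = 10_000,
                 seed: int = 0, ci: float = 95.0):
    """Percentile bootstrap CI of ``statistic(table)`` over trial resamples.

    Returns ``(point, lo, hi)`` with the 2.5/97.5 percentiles at the default
    95% level.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    point = float(statistic(table))
    n = len(table)
    values = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        values[b] = statistic(table.iloc[idx])
    lo_q, hi_q = (100 - ci) / 2, 100 - (100 - ci) / 2
    return point, float(np.percentile(values, lo_q)), float(np.percentile(values, hi_q))
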