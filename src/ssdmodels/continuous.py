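"""Continuous reliability-weighted (Bayesian) observer for displacement reports.

For a Gaussian prior over displacements and a Gaussian sensory likelihood
centered on the presented displacement, the posterior mean is the familiar
precision-weighted average

    mu_post = (sigma_L^2 mu_prior + sigma_prior^2 mu_L) / (sigma_L^2 + sigma_prior^2)

with weights w_prior = sigma_L^2 / (sigma_L^2 + sigma_prior^2) and
w_likelihood = 1 - w_prior, and posterior variance
1 / (1/sigma_L^2 + 1/sigma_prior^2).  The observer's report is the posterior
mean, so the deviation of the report from the presented displacement
(displacement - report) is linear in the displacement with slope w_prior for a
zero-mean prior: the noisier the likelihood, the harder the report is pulled
toward the prior.

Sign convention: displacements and the prior mean are coded relative to the
saccade direction, positive = in the direction of the saccade.  A prior bias
*opposite* to the saccade is therefore a negative ``mu_prior`` in these
coordinates; fitted results are reported with ``bias_opposite_saccade`` =
``-mu_prior`` for readability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .design import INFINITE_NOISE

__all__ = [
    "ContinuousObserverParams",
    "posterior_mean",
    "posterior_variance",
    "deviation_curve",
    "ContinuousBayesObserver",
    "fit_continuous",
]


@dataclass(frozen=True)
class ContinuousObserverParams:
    """Prior and per-noise-level likelihood widths of the continuous observer."""

    mu_prior: float
    sigma_prior: float
    sigma_likelihood_by_noise: dict

    def __post_init__(self) -> None:
        if self.sigma_prior <= 0:
            raise ValueError("sigma_prior must be positive")
        for level, sd in self.sigma_likelihood_by_noise.items():
            if level != INFINITE_NOISE and sd <= 0:
                raise ValueError(f"likelihood SD for noise {level!r} must be positive")

    def sigma_likelihood(self, noise_level) -> float:
        try:
            return self.sigma_likelihood_by_noise[noise_level]
        except KeyError:
            raise KeyError(f"noise level {noise_level!r} not in params") from None


def _weights(sigma_likelihood: float, sigma_prior: float):
    vl, vp = sigma_likelihood**2, sigma_prior**2
    w_prior = vl / (vl + vp)
    return w_prior, 1.0 - w_prior


def posterior_mean(mu_likelihood, params: ContinuousObserverParams, noise_level):
    """Reliability-weighted posterior mean; handles the target-absent sentinel.

    When the target never reappears (infinite noise) the likelihood carries no
    information and the posterior collapses onto the prior mean.
    """
    if noise_level == INFINITE_NOISE:
        return np.full_like(np.asarray(mu_likelihood, dtype=float), params.mu_prior)[()]
    w_prior, w_lik = _weights(params.sigma_likelihood(noise_level), params.sigma_prior)
    mu_likelihood = np.asarray(mu_likelihood, dtype=float)
    return (w_prior * params.mu_prior + w_lik * mu_likelihood)[()]


def posterior_variance(params: ContinuousObserverParams, noise_level) -> float:
    """Posterior variance 1/(1/sigma_L^2 + 1/sigma_prior^2); < both components."""
    if noise_level == INFINITE_NOISE:
        return params.sigma_prior**2
    vl = params.sigma_likelihood(noise_level) ** 2
    vp = params.sigma_prior**2
    return 1.0 / (1.0 / vl + 1.0 / vp)


def deviation_curve(displacements, params: ContinuousObserverParams, noise_level):
    """Predicted deviation (displacement - report) per presented displacement.

    For a zero-mean prior this is linear with slope w_prior; in the
    target-absent condition the report is the prior mean so the deviation
    equals the displacement itself (shifted by the prior bias).
    """
    displacements = np.asarray(displacements, dtype=float)
    return displacements - posterior_mean(displacements, params, noise_level)


class ContinuousBayesObserver:
    """Least-squares fit of the continuous observer, sklearn-style.

    Jointly fits the prior mean and one likelihood SD per noise level (the
    prior SD is fixed to the experiment's displacement-distribution SD) by
    minimizing squared error between reports and the noiseless posterior mean.

    Attributes (after ``fit``)
    --------------------------
    mu_prior_ : fitted prior mean (saccade-direction coordinates).
    bias_opposite_saccade_ : ``-mu_prior_`` (positive = bias against saccade).
    sigma_likelihood_ : dict noise level -> fitted likelihood SD.
    noise_levels_ : sorted noise levels seen in fit.
    sse_ : summed squared residual at the optimum.
    """

    def __init__(
        self,
        sigma_prior: float = 1.0,
        n_restarts: int = 5,
        random_state: int = 0,
        sigma_bounds=(1e-3, 20.0),
        mu_bounds=(-5.0, 5.0),
    ):
        self.sigma_prior = sigma_prior
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.sigma_bounds = sigma_bounds
        self.mu_bounds = mu_bounds

    def get_params(self, deep: bool = True) -> dict:
        return {
            "sigma_prior": self.sigma_prior,
            "n_restarts": self.n_restarts,
            "random_state": self.random_state,
            "sigma_bounds": self.sigma_bounds,
            "mu_bounds": self.mu_bounds,
        }

    def set_params(self, **params):
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y):
        """Fit to continuous reports.

        Parameters
        ----------
        X : array-like of shape (n_trials, 2)
            Columns: presented displacement (deg, saccade-direction coded) and
            noise-level label.  Target-absent trials must be excluded by the
            caller -- observers revert to reporting the presaccadic location
            there, a strategy change the weighted-average model does not cover.
        y : continuous reports (deg).
        """
        X = np.asarray(X, dtype=object)
        disp = np.asarray([row[0] for row in X], dtype=float)
        noise = np.asarray([row[1] for row in X], dtype=object)
        y = np.asarray(y, dtype=float)
        if INFINITE_NOISE in set(noise):
            raise ValueError("exclude target-absent (infinite-noise) trials before fitting")
        levels = sorted(set(noise.tolist()))
        if len(levels) < 2:
            raise ValueError("need at least 2 noise levels to fit")
        masks = [noise == lv for lv in levels]
        vp = self.sigma_prior**2

        def residuals(theta):
            mu_prior = theta[0]
            sds = np.exp(theta[1:])
            res = np.empty_like(y)
            for mask, sd in zip(masks, sds):
                vl = sd**2
                w_prior = vl / (vl + vp)
                pred = w_prior * mu_prior + (1.0 - w_prior) * disp[mask]
                res[mask] = y[mask] - pred
            return res

        lo_s, hi_s = np.log(self.sigma_bounds[0]), np.log(self.sigma_bounds[1])
        bounds_lo = [self.mu_bounds[0]] + [lo_s] * len(levels)
        bounds_hi = [self.mu_bounds[1]] + [hi_s] * len(levels)
        rng = np.random.default_rng(self.random_state)
        best = None
        for restart in range(self.n_restarts):
            if restart == 0:
                theta0 = np.concatenate([[0.0], np.log(np.full(len(levels), 0.5))])
            else:
                theta0 = np.concatenate(
                    [
                        [rng.uniform(*self.mu_bounds)],
                        rng.uniform(lo_s, hi_s, size=len(levels)),
                    ]
                )
            res = optimize.least_squares(
                residuals, theta0, bounds=(bounds_lo, bounds_hi)
            )
            if best is None or res.cost < best.cost:
                best = res

        self.noise_levels_ = levels
        self.mu_prior_ = float(best.x[0])
        self.bias_opposite_saccade_ = -self.mu_prior_
        self.sigma_likelihood_ = {
            lv: float(np.exp(v)) for lv, v in zip(levels, best.x[1:])
        }
        self.sse_ = float(2.0 * best.cost)
        return self

    def predict(self, X) -> np.ndarray:
        """Posterior-mean reports for (displacement, noise level) rows."""
        if not hasattr(self, "sse_"):
            raise RuntimeError("observer is not fitted")
        params = self.params_()
        X = np.asarray(X, dtype=object)
        return np.asarray(
            [posterior_mean(float(row[0]), params, row[1]) for row in X], dtype=float
        )

    def params_(self) -> ContinuousObserverParams:
        return ContinuousObserverParams(
            mu_prior=self.mu_prior_,
            sigma_prior=self.sigma_prior,
            sigma_likelihood_by_noise=dict(self.sigma_likelihood_),
        )


def fit_continuous(table, sigma_prior: float = 1.0, n_restarts: int = 5,
                   random_state: int = 0):
    """Fit the continuous observer to a trial table with continuous responses.

    Target-absent trials are dropped.  Returns the fitted
    :class:`ContinuousObserverParams` and the summed squared error.
    """
    finite = table[table["noise_sigma_deg"] != INFINITE_NOISE]
    X = list(zip(finite["displacement_deg"], finite["noise_sigma_deg"]))
    y = finite["response"].to_numpy(dtype=float)
    est = ContinuousBayesObserver(
        sigma_prior=sigma_prior, n_restarts=n_restarts, random_state=random_state
    )
    est.fit(X, y)
    return est.params_(), est.sse_
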