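"""Categorical Bayesian ideal observer for trans-saccadic jump detection.

The observer reports "jumped" when the posterior odds favor the jump
hypothesis,

    P(x_hat | J) P(J)  >  P(x_hat | not-J) P(not-J),

where the perceived displacement x_hat ~ N(x, sigma_t^2) is the true
displacement corrupted by sensory noise set by the blob width sigma_t, and the
two class-conditional densities are the experiment's jump/no-jump Gaussians
broadened by the same sensory noise: x_hat | J ~ N(mu_J, sigma_J^2 + sigma_t^2)
and x_hat | not-J ~ N(mu_NJ, sigma_NJ^2 + sigma_t^2).

With zero means the log-odds condition reduces to a threshold on x_hat^2, and
because x_hat^2 / sigma_t^2 is a noncentral chi-square variable (df = 1,
noncentrality x^2 / sigma_t^2), the probability of reporting "jumped" at true
displacement x has the closed form

    D(x) = 1 - F_chi2(crit / sigma_t^2; df=1, lambda=x^2 / sigma_t^2),

which is what :func:`decision_curve` evaluates.  A Monte-Carlo evaluation of
the defining integral (:func:`mc_decision_oracle`) is kept as an independent
cross-check and handles the non-zero-mean case, where the decision region is
a general quadratic-inequality region in x_hat.

The observer is also exposed as a scikit-learn style estimator,
:class:`CategoricalBayesObserver`, whose ``fit`` performs the 14-parameter
maximum-likelihood fit used for a 3-prior x 3-noise-level session: three
priors, three sensory-noise SDs, shared jump/no-jump widths, and a lower
bound and lapse rate per noise level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ALWAYS_JUMP",
    "NEVER_JUMP",
    "CategoricalObserverParams",
    "DecisionCriterion",
    "FitResult",
    "decision_criterion",
    "decision_curve",
    "lapse_scaled_curve",
    "mc_decision_oracle",
    "predict_intercept_difference",
    "CategoricalBayesObserver",
    "fit_mle",
]

#: Sentinels for degenerate criteria where the observer's report is constant.
ALWAYS_JUMP = "always_jump"
NEVER_JUMP = "never_jump"


@dataclass(frozen=True)
class CategoricalObserverParams:
    """All parameters of the categorical ideal observer (one condition)."""

    p_jump: float
    sigma_jump: float
    sigma_nojump: float
    sigma_t: float
    mu_jump: float = 0.0
    mu_nojump: float = 0.0
    lower_bound: float = 0.0
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_jump < 1.0:
            raise ValueError(f"p_jump must be in (0, 1), got {self.p_jump}")
        if self.sigma_jump <= 0 or self.sigma_nojump < 0 or self.sigma_t < 0:
            raise ValueError("sigma_jump > 0, sigma_nojump >= 0, sigma_t >= 0 required")
        if self.lower_bound < 0 or self.lapse < 0 or self.lower_bound + self.lapse >= 1:
            raise ValueError("need lower_bound, lapse >= 0 and lower_bound + lapse < 1")

    @property
    def zero_mean(self) -> bool:
        return self.mu_jump == 0.0 and self.mu_nojump == 0.0


@dataclass(frozen=True)
class DecisionCriterion:
    """Region of perceived displacement where the observer reports "jumped".

    ``kind`` is ``"threshold"`` (|x_hat| beyond sqrt(xhat_crit_sq)), one of the
    constant sentinels, or ``"region"`` for non-zero means, where ``intervals``
    lists the open intervals of x_hat in which the jump condition holds.
    """

    kind: str
    xhat_crit_sq: float | None = None
    intervals: tuple = ()

    def contains(self, xhat) -> np.ndarray:
        """Vectorized membership of x_hat in the jump-report region."""
        xhat = np.asarray(xhat, dtype=float)
        if self.kind == ALWAYS_JUMP:
            return np.ones_like(xhat, dtype=bool)
        if self.kind == NEVER_JUMP:
            return np.zeros_like(xhat, dtype=bool)
        if self.kind == "threshold":
            return xhat**2 > self.xhat_crit_sq
        mask = np.zeros_like(xhat, dtype=bool)
        for lo, hi in self.intervals:
            mask |= (xhat > lo) & (xhat < hi)
        return mask


def _variances(params: CategoricalObserverParams):
    a = params.sigma_jump**2 + params.sigma_t**2      # var of x_hat | jump
    b = params.sigma_nojump**2 + params.sigma_t**2    # var of x_hat | no jump
    return a, b


def _quadratic_coefficients(params: CategoricalObserverParams):
    """Coefficients of the log-odds quadratic q(x_hat) = a2 x^2 + a1 x + a0.

    The observer reports "jumped" where q(x_hat) > 0.
    """
    va, vb = _variances(params)
    p = params.p_jump
    a2 = 1.0 / vb - 1.0 / va
    a1 = 2.0 * params.mu_jump / va - 2.0 * params.mu_nojump / vb
    a0 = (
        params.mu_nojump**2 / vb
        - params.mu_jump**2 / va
        - np.log(va / vb)
        - 2.0 * np.log((1.0 - p) / p)
    )
    return a2, a1, a0


def decision_criterion(params: CategoricalObserverParams) -> DecisionCriterion:
    """Derive the jump-report criterion from the observer's log-odds condition.

    Zero-mean case: the closed-form squared threshold

        crit = [log((sJ^2+st^2)/(sNJ^2+st^2)) + 2 log((1-P(J))/P(J))]
               / [1/(sNJ^2+st^2) - 1/(sJ^2+st^2)]

    with sentinel handling when the threshold is non-positive (report "jumped"
    everywhere) or the variance difference vanishes or reverses sign.  For
    non-zero means the quadratic inequality is solved by a bracketing root
    finder and returned as an interval region.
    """
    a2, a1, a0 = _quadratic_coefficients(params)

    if params.zero_mean:
        if a2 == 0.0:
            # Equal effective variances: the decision is prior-only.
            warnings.warn(
                "degenerate criterion: equal jump/no-jump variances; decision "
                "is determined by the prior log-odds alone",
                stacklevel=2,
            )
            return DecisionCriterion(kind=ALWAYS_JUMP if a0 > 0 else NEVER_JUMP)
        crit = -a0 / a2  # x_hat^2 threshold from a2 * x^2 + a0 > 0
        if a2 > 0:
            if crit <= 0:
                return DecisionCriterion(kind=ALWAYS_JUMP)
            root = float(np.sqrt(crit))
            return DecisionCriterion(
                kind="threshold",
                xhat_crit_sq=float(crit),
                intervals=((-np.inf, -root), (root, np.inf)),
            )
        # a2 < 0: jump condition holds *inside* |x_hat| < sqrt(crit)
        if crit <= 0:
            return DecisionCriterion(kind=NEVER_JUMP)
        root = float(np.sqrt(crit))
        return DecisionCriterion(kind="region", intervals=((-root, root),))

    # Non-zero means: solve a2 x^2 + a1 x + a0 > 0 by bracketed root finding.
    q = np.polynomial.Polynomial([a0, a1, a2])
    if a2 == 0.0:
        if a1 == 0.0:
            return DecisionCriterion(kind=ALWAYS_JUMP if a0 > 0 else NEVER_JUMP)
        root = optimize.brentq(q, *_linear_bracket(a1, a0))
        if a1 > 0:
            return DecisionCriterion(kind="region", intervals=((root, np.inf),))
        return DecisionCriterion(kind="region", intervals=((-np.inf, root),))

    disc = a1 * a1 - 4.0 * a2 * a0
    vertex = -a1 / (2.0 * a2)
    if disc <= 0:
        # No sign change: constant-sign quadratic (touching counts as no region)
        positive = a2 > 0
        return DecisionCriterion(kind=ALWAYS_JUMP if positive else NEVER_JUMP)
    half_width = np.sqrt(disc) / (2.0 * abs(a2))
    lo = optimize.brentq(q, vertex - 2.0 * half_width - 1.0, vertex)
    hi = optimize.brentq(q, vertex, vertex + 2.0 * half_width + 1.0)
    if a2 > 0:
        intervals = ((-np.inf, float(lo)), (float(hi), np.inf))
    else:
        intervals = ((float(lo), float(hi)),)
    return DecisionCriterion(kind="region", intervals=intervals)


def _linear_bracket(a1, a0):
    root = -a0 / a1
    return root - 1.0, root + 1.0


def decision_curve(x, params: CategoricalObserverParams) -> np.ndarray:
    """P(report "jumped" | true displacement x) for the zero-mean observer.

    Uses the noncentral chi-square survivor function; constant-report sentinel
    criteria map to 0 or 1, and sigma_t = 0 degenerates to the noiseless
    indicator x^2 > crit.
    """
    if not params.zero_mean:
        raise ValueError(
            "closed form requires mu_jump = mu_nojump = 0; "
            "use mc_decision_oracle for non-zero means"
        )
    x = np.asarray(x, dtype=float)
    crit = decision_criterion(params)
    if crit.kind == ALWAYS_JUMP:
        return np.ones_like(x)
    if crit.kind == NEVER_JUMP:
        return np.zeros_like(x)
    if params.sigma_t == 0.0:
        return crit.contains(x).astype(float)
    st2 = params.sigma_t**2
    if crit.kind == "threshold":
        return stats.ncx2.sf(crit.xhat_crit_sq / st2, df=1, nc=x**2 / st2)
    # Interior region (sigma_nojump > sigma_jump): jump reported inside |x_hat| < r
    (lo, hi), = crit.intervals
    return stats.ncx2.cdf(hi**2 / st2, df=1, nc=x**2 / st2)


def lapse_scaled_curve(x, params: CategoricalObserverParams) -> np.ndarray:
    """Decision curve rescaled into [lower_bound, 1 - lapse]."""
    d = decision_curve(x, params)
    return params.lower_bound + (1.0 - params.lower_bound - params.lapse) * d


def mc_decision_oracle(
    x: float,
    params: CategoricalObserverParams,
    n_samples: int = 10**6,
    seed: int = 0,
):
    """Monte-Carlo evaluation of the observer's report probability.

    Draws perceived displacements x_hat ~ N(x, sigma_t^2) and evaluates the
    exact Gaussian log-odds indicator on each.  Returns ``(mean, se)``.
    Supports non-zero means; serves as the independent oracle for
    :func:`decision_curve`.
    """
    if n_samples < 10**3:
        raise ValueError("n_samples must be at least 1000")
    rng = np.random.default_rng(seed)
    xhat = x + params.sigma_t * rng.standard_normal(n_samples)
    a2, a1, a0 = _quadratic_coefficients(params)
    indicator = (a2 * xhat**2 + a1 * xhat + a0) > 0
    mean = indicator.mean()
    se = float(np.sqrt(mean * (1.0 - mean) / n_samples))
    return float(mean), se


def predict_intercept_difference(
    params_high: CategoricalObserverParams,
    params_low: CategoricalObserverParams,
) -> float:
    """High-prior minus low-prior report probability at zero displacement."""
    same = replace(params_high, p_jump=params_low.p_jump)
    if same != params_low:
        raise ValueError("parameter sets must differ only in p_jump")
    return float(
        lapse_scaled_curve(0.0, params_high) - lapse_scaled_curve(0.0, params_low)
    )


# ---------------------------------------------------------------------------
# 14-parameter maximum-likelihood fit
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of the per-session MLE: parameters per (prior, noise) condition."""

    priors: np.ndarray          # one per prior condition
    sigma_t: np.ndarray         # one per noise condition
    sigma_jump: float
    sigma_nojump: float
    lower_bound: np.ndarray     # one per noise condition
    lapse: np.ndarray           # one per noise condition
    nll: float
    converged: bool
    n_restarts_used: int

    def params_for(self, prior_idx: int, noise_idx: int) -> CategoricalObserverParams:
        return CategoricalObserverParams(
            p_jump=float(self.priors[prior_idx]),
            sigma_jump=self.sigma_jump,
            sigma_nojump=self.sigma_nojump,
            sigma_t=float(self.sigma_t[noise_idx]),
            lower_bound=float(self.lower_bound[noise_idx]),
            lapse=float(self.lapse[noise_idx]),
        )

    def to_dict(self) -> dict:
        return {
            "priors": list(map(float, self.priors)),
            "sigma_t": list(map(float, self.sigma_t)),
            "sigma_jump": float(self.sigma_jump),
            "sigma_nojump": float(self.sigma_nojump),
            "lower_bound": list(map(float, self.lower_bound)),
            "lapse": list(map(float, self.lapse)),
            "nll": float(self.nll),
            "converged": bool(self.converged),
            "n_restarts_used": int(self.n_restarts_used),
        }


def _curve_probability(x, p_jump, sigma_jump, sigma_nojump, sigma_t, lower, lapse):
    """Vectorized lapse-scaled curve without parameter-object overhead."""
    va = sigma_jump**2 + sigma_t**2
    vb = sigma_nojump**2 + sigma_t**2
    num = np.log(va / vb) + 2.0 * np.log((1.0 - p_jump) / p_jump)
    den = 1.0 / vb - 1.0 / va
    if den <= 0:
        d = np.ones_like(x) if num < 0 else np.zeros_like(x)
    else:
        crit = num / den
        if crit <= 0:
            d = np.ones_like(x)
        elif sigma_t == 0:
            d = (x**2 > crit).astype(float)
        else:
            st2 = sigma_t**2
            d = stats.ncx2.sf(crit / st2, df=1, nc=x**2 / st2)
    return lower + (1.0 - lower - lapse) * d


class CategoricalBayesObserver:
    """Maximum-likelihood categorical ideal observer, sklearn-style.

    Parameters
    ----------
    n_restarts : int
        Number of random multi-start restarts for the bounded optimizer.  The
        14-dimensional Bernoulli NLL surface is multimodal; the best restart
        is kept.
    random_state : int
        Seed for restart initialization.
    sigma_bounds, prior_bounds, lapse_bound : optimizer box constraints.
        SDs are optimized on a log scale; priors on a logit scale.

    Attributes (after ``fit``)
    --------------------------
    priors_, sigma_t_, sigma_jump_, sigma_nojump_, lower_bound_, lapse_ :
        fitted values (arrays ordered by the sorted unique condition labels).
    prior_levels_, noise_levels_ : condition labels seen during fit.
    nll_ : best negative log likelihood.
    converged_, n_restarts_used_ : optimizer diagnostics.
    """

    def __init__(
        self,
        n_restarts: int = 10,
        random_state: int = 0,
        sigma_bounds=(1e-3, 20.0),
        prior_bounds=(1e-3, 1 - 1e-3),
        lapse_bound: float = 0.5,
    ):
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.sigma_bounds = sigma_bounds
        self.prior_bounds = prior_bounds
        self.lapse_bound = lapse_bound

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_restarts": self.n_restarts,
            "random_state": self.random_state,
            "sigma_bounds": self.sigma_bounds,
            "prior_bounds": self.prior_bounds,
            "lapse_bound": self.lapse_bound,
        }

    def set_params(self, **params):
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y):
        """Fit the 14 free parameters to binary responses.

        Parameters
        ----------
        X : array-like of shape (n_trials, 3)
            Columns: signed displacement (deg), prior condition label, noise
            condition label.  Labels are grouped into the 3 x 3 condition grid.
        y : array-like of binary responses (1 = reported "jumped").
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must have columns (displacement, prior, noise)")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if not np.isin(np.unique(y), [0.0, 1.0]).all():
            raise ValueError("y must be binary")

        self.prior_levels_ = np.unique(X[:, 1])
        self.noise_levels_ = np.unique(X[:, 2])
        n_p, n_n = len(self.prior_levels_), len(self.noise_levels_)

        # Per-trial condition indices for the fully vectorized NLL.
        prior_idx = np.searchsorted(self.prior_levels_, X[:, 1])
        noise_idx = np.searchsorted(self.noise_levels_, X[:, 2])
        x_trials = X[:, 0]

        lo_s, hi_s = np.log(self.sigma_bounds[0]), np.log(self.sigma_bounds[1])
        lo_p = np.log(self.prior_bounds[0] / (1 - self.prior_bounds[0]))
        hi_p = np.log(self.prior_bounds[1] / (1 - self.prior_bounds[1]))

        def unpack(theta):
            priors = 1.0 / (1.0 + np.exp(-theta[:n_p]))
            sigma_t = np.exp(theta[n_p : n_p + n_n])
            sigma_jump = np.exp(theta[n_p + n_n])
            sigma_nojump = np.exp(theta[n_p + n_n + 1])
            lower = theta[n_p + n_n + 2 : n_p + n_n + 2 + n_n]
            lapse = theta[n_p + n_n + 2 + n_n :]
            return priors, sigma_t, sigma_jump, sigma_nojump, lower, lapse

        eps = 1e-9

        def nll(theta):
            priors, sigma_t, sj, snj, lower, lapse = unpack(theta)
            # criterion per (prior, noise) cell: (n_p, n_n) scalars
            va = sj**2 + sigma_t**2                       # (n_n,)
            vb = snj**2 + sigma_t**2
            num = (
                np.log(va / vb)[None, :]
                + 2.0 * np.log((1.0 - priors) / priors)[:, None]
            )
            den = (1.0 / vb - 1.0 / va)[None, :]
            with np.errstate(divide="ignore", invalid="ignore"):
                crit = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
            # per-trial survivor of |x_hat| beyond sqrt(crit): two normal tails
            xc = np.sqrt(np.clip(crit, 0.0, None))[prior_idx, noise_idx]
            st = sigma_t[noise_idx]
            z_hi = (xc - x_trials) / st
            z_lo = (-xc - x_trials) / st
            d = stats.norm.sf(z_hi) + stats.norm.cdf(z_lo)
            # degenerate cells: crit <= 0 -> always jump; den <= 0 -> prior-only
            cell_d = np.where(np.isnan(crit), (num < 0).astype(float), np.nan)
            crit_flat = crit[prior_idx, noise_idx]
            d = np.where(crit_flat <= 0, 1.0, d)
            override = cell_d[prior_idx, noise_idx]
            d = np.where(np.isnan(override), d, override)
            p = lower[noise_idx] + (1.0 - lower[noise_idx] - lapse[noise_idx]) * d
            p = np.clip(p, eps, 1.0 - eps)
            return -np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p))

        bounds = (
            [(lo_p, hi_p)] * n_p
            + [(lo_s, hi_s)] * n_n
            + [(lo_s, hi_s)] * 2
            + [(0.0, self.lapse_bound)] * (2 * n_n)
        )
        rng = np.random.default_rng(self.random_state)

        # Data-informed anchor start: empirical "jumped" rates per prior
        # condition seed the priors, the noise-condition labels (blob SDs)
        # seed the sensory-noise SDs.
        anchor = np.empty(len(bounds))
        for pi, p in enumerate(self.prior_levels_):
            rate = np.clip(y[X[:, 1] == p].mean(), 0.05, 0.95)
            anchor[pi] = np.log(rate / (1.0 - rate))
        anchor[n_p : n_p + n_n] = np.log(np.clip(self.noise_levels_, *self.sigma_bounds))
        anchor[n_p + n_n] = np.log(max(np.std(X[:, 0]), 0.5))
        anchor[n_p + n_n + 1] = np.log(0.1)
        anchor[n_p + n_n + 2 :] = 0.02

        best = None
        n_used = 0
        any_converged = False
        for restart in range(self.n_restarts):
            n_used += 1
            if restart == 0:
                theta0 = anchor.copy()
            elif restart % 2 == 1:
                # local jitter around the anchor
                theta0 = anchor + rng.normal(0.0, 0.3, size=len(bounds))
                theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])
            else:
                # wide exploration
                theta0 = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
            res = optimize.minimize(
                nll, theta0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 500},
            )
            if best is None or res.fun < best.fun:
                best = res
            any_converged = any_converged or res.success

        priors, sigma_t, sj, snj, lower, lapse = unpack(best.x)
        self.priors_ = priors
        self.sigma_t_ = sigma_t
        self.sigma_jump_ = float(sj)
        self.sigma_nojump_ = float(snj)
        self.lower_bound_ = lower
        self.lapse_ = lapse
        self.nll_ = float(best.fun)
        self.converged_ = bool(any_converged and np.isfinite(best.fun))
        self.n_restarts_used_ = n_used
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-trial P(report "jumped") under the fitted parameters.

        Returns an (n, 2) array with columns [P(no jump), P(jump)].
        """
        p1 = self._proba1(X)
        return np.column_stack([1.0 - p1, p1])

    def _proba1(self, X) -> np.ndarray:
        if not hasattr(self, "nll_"):
            raise RuntimeError("observer is not fitted")
        X = np.asarray(X, dtype=float)
        out = np.empty(len(X))
        for pi, p in enumerate(self.prior_levels_):
            for ni, n in enumerate(self.noise_levels_):
                mask = (X[:, 1] == p) & (X[:, 2] == n)
                if mask.any():
                    out[mask] = _curve_probability(
                        X[mask, 0],
                        self.priors_[pi],
                        self.sigma_jump_,
                        self.sigma_nojump_,
                        self.sigma_t_[ni],
                        self.lower_bound_[ni],
                        self.lapse_[ni],
                    )
        return out

    def predict(self, X) -> np.ndarray:
        return (self._proba1(X) > 0.5).astype(int)

    def result_(self) -> FitResult:
        return FitResult(
            priors=self.priors_,
            sigma_t=self.sigma_t_,
            sigma_jump=self.sigma_jump_,
            sigma_nojump=self.sigma_nojump_,
            lower_bound=self.lower_bound_,
            lapse=self.lapse_,
            nll=self.nll_,
            converged=self.converged_,
            n_restarts_used=self.n_restarts_used_,
        )


def fit_mle(table, n_restarts: int = 10, random_state: int = 0) -> FitResult:
    """Fit the 14-parameter observer to a trial table with binary responses.

    Thin wrapper over :class:`CategoricalBayesObserver` taking the trial-table
    layout of :mod:`ssdmodels.design` (columns ``displacement_deg``,
    ``prior_label``, ``noise_sigma_deg``, ``response``).
    """
    X = np.column_stack(
        [
            table["displacement_deg"].to_numpy(dtype=float),
            table["prior_label"].to_numpy(dtype=float),
            table["noise_sigma_deg"].to_numpy(dtype=float),
        ]
    )
    y = table["response"].to_numpy(dtype=float)
    est = CategoricalBayesObserver(n_restarts=n_restarts, random_state=random_state)
    est.fit(X, y)
    return est.result_()
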