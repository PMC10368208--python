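"""Categorical ideal observer: criterion, decision curve, oracle, MLE."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from ssdmodels.categorical import (
    ALWAYS_JUMP,
    NEVER_JUMP,
    CategoricalObserverParams,
    decision_criterion,
    decision_curve,
    fit_mle,
    lapse_scaled_curve,
    mc_decision_oracle,
    predict_intercept_difference,
)

SIM = dict(sigma_jump=2.0, sigma_nojump=0.017)


def params(p_jump=0.5, sigma_t=0.1, **kw):
    base = dict(SIM, p_jump=p_jump, sigma_t=sigma_t)
    base.update(kw)
    return CategoricalObserverParams(**base)


class TestDecisionCriterion:
    def test_closed_form_matches_root_solve(self):
        """Independent oracle: solve the log-odds equation numerically."""
        p = params()
        crit = decision_criterion(p)
        va = p.sigma_jump**2 + p.sigma_t**2
        vb = p.sigma_nojump**2 + p.sigma_t**2

        def log_odds(xhat):
            return (
                -0.5 * xhat**2 / va + 0.5 * xhat**2 / vb
                - 0.5 * np.log(va / vb) - np.log((1 - p.p_jump) / p.p_jump)
            )

        root = optimize.brentq(log_odds, 1e-6, 10.0)
        assert crit.kind == "threshold"
        assert crit.xhat_crit_sq == pytest.approx(root**2, rel=1e-9)

    def test_prior_near_one_always_jumps(self):
        crit = decision_criterion(params(p_jump=1 - 1e-9))
        assert crit.kind == ALWAYS_JUMP

    def test_region_symmetric_for_zero_means(self):
        crit = decision_criterion(params(p_jump=0.3))
        xs = np.linspace(-4, 4, 101)
        np.testing.assert_array_equal(crit.contains(xs), crit.contains(-xs))

    def test_equal_variances_degenerate_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            crit = decision_criterion(
                CategoricalObserverParams(
                    p_jump=0.8, sigma_jump=1.0, sigma_nojump=1.0, sigma_t=0.5
                )
            )
        assert crit.kind == ALWAYS_JUMP  # prior log-odds favor jump
        with pytest.warns(UserWarning, match="degenerate"):
            crit = decision_criterion(
                CategoricalObserverParams(
                    p_jump=0.2, sigma_jump=1.0, sigma_nojump=1.0, sigma_t=0.5
                )
            )
        assert crit.kind == NEVER_JUMP

    def test_nonzero_means_region_matches_quadratic_signs(self):
        p = params(mu_jump=1.0, mu_nojump=-0.5, p_jump=0.4)
        crit = decision_criterion(p)
        va = p.sigma_jump**2 + p.sigma_t**2
        vb = p.sigma_nojump**2 + p.sigma_t**2
        xs = np.linspace(-8, 8, 2001)
        lhs = -((xs - p.mu_jump) ** 2) / va + (xs - p.mu_nojump) ** 2 / vb
        rhs = np.log(va / vb) + 2 * np.log((1 - p.p_jump) / p.p_jump)
        np.testing.assert_array_equal(crit.contains(xs), lhs > rhs)


class TestDecisionCurve:
    def test_matches_monte_carlo_oracle_on_grid(self):
        """Closed form vs MC integral of the indicator, 3 MC SEs, coarse grid."""
        for p_jump in (0.1, 0.5, 0.9):
            for sigma_t in (0.1, 0.5):
                p = params(p_jump=p_jump, sigma_t=sigma_t)
                for x in (0.0, 0.5, 2.0):
                    cf = float(decision_curve(x, p))
                    mc, se = mc_decision_oracle(x, p, n_samples=10**5, seed=42)
                    assert abs(cf - mc) <= 3 * max(se, 1e-4)

    def test_symmetric_in_displacement(self):
        p = params(p_jump=0.3, sigma_t=0.25)
        xs = np.linspace(0, 5, 21)
        np.testing.assert_allclose(decision_curve(xs, p), decision_curve(-xs, p))

    def test_always_jump_sentinel_gives_one(self):
        p = params(p_jump=1 - 1e-9)
        assert decision_curve(np.array([0.0, 3.0]), p).tolist() == [1.0, 1.0]

    def test_noiseless_indicator(self):
        p = params(sigma_t=0.0)
        crit = decision_criterion(p)
        thr = np.sqrt(crit.xhat_crit_sq)
        assert decision_curve(thr * 1.01, p) == 1.0
        assert decision_curve(thr * 0.99, p) == 0.0

    def test_nonzero_means_rejected(self):
        with pytest.raises(ValueError, match="mc_decision_oracle"):
            decision_curve(0.0, params(mu_jump=0.5))

    def test_monotone_in_abs_displacement_and_prior(self):
        xs = np.linspace(0, 5, 26)
        for sigma_t in (0.1, 0.25, 0.5):
            d_prev = None
            for p_jump in (0.1, 0.5, 0.9):
                d = decision_curve(xs, params(p_jump=p_jump, sigma_t=sigma_t))
                assert np.all(np.diff(d) >= -1e-12)  # non-decreasing in |x|
                if d_prev is not None:
                    assert np.all(d - d_prev >= -1e-12)  # non-decreasing in prior
                d_prev = d


class TestMCOracle:
    def test_noiseless_is_indicator(self):
        p = params(sigma_t=0.0)
        crit = decision_criterion(p)
        thr = np.sqrt(crit.xhat_crit_sq)
        assert mc_decision_oracle(thr * 2, p, 10**4, seed=0)[0] == 1.0
        assert mc_decision_oracle(thr / 2, p, 10**4, seed=0)[0] == 0.0

    def test_equal_widths_linear_discriminant(self):
        """With equal likelihood widths the rule is a midpoint threshold."""
        p = CategoricalObserverParams(
            p_jump=0.5, sigma_jump=1.0, sigma_nojump=1.0, sigma_t=0.3,
            mu_jump=2.0, mu_nojump=0.0,
        )
        midpoint = (p.mu_jump + p.mu_nojump) / 2
        from scipy import stats

        for x in (0.0, 1.0, 2.0):
            mc, se = mc_decision_oracle(x, p, n_samples=10**5, seed=7)
            expected = stats.norm.sf((midpoint - x) / p.sigma_t)
            assert abs(mc - expected) <= 3 * max(se, 1e-4)

    def test_minimum_samples_enforced(self):
        with pytest.raises(ValueError):
            mc_decision_oracle(0.0, params(), n_samples=10)


class TestLapseScaling:
    def test_identity_without_lapse(self):
        p = params()
        xs = np.linspace(-3, 3, 13)
        np.testing.assert_allclose(lapse_scaled_curve(xs, p), decision_curve(xs, p))

    @given(
        lower=st.floats(0.0, 0.4), lapse=st.floats(0.0, 0.4),
        x=st.floats(-5.0, 5.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_range_is_lower_to_one_minus_lapse(self, lower, lapse, x):
        p = params(lower_bound=lower, lapse=lapse)
        v = float(lapse_scaled_curve(x, p))
        assert lower - 1e-12 <= v <= 1 - lapse + 1e-12

    def test_affine_arithmetic(self):
        p = params(p_jump=1 - 1e-9, lower_bound=0.1, lapse=0.2)  # D == 1
        assert float(lapse_scaled_curve(0.0, p)) == pytest.approx(0.8)


class TestInterceptDifference:
    def test_zero_for_equal_priors(self):
        p = params(p_jump=0.5)
        assert predict_intercept_difference(p, p) == 0.0

    def test_grows_with_sensory_noise(self):
        """The Bayesian signature: prior separation increases with noise."""
        diffs = []
        for sigma_t in (0.1, 0.25, 0.5):
            hi = params(p_jump=0.78, sigma_t=sigma_t)
            lo = params(p_jump=0.22, sigma_t=sigma_t)
            diffs.append(predict_intercept_difference(hi, lo))
        assert diffs[0] < diffs[1] < diffs[2]
        assert all(-1 <= d <= 1 for d in diffs)

    def test_rejects_other_differences(self):
        hi = params(p_jump=0.8)
        lo = params(p_jump=0.2, sigma_t=0.5)
        with pytest.raises(ValueError):
            predict_intercept_difference(hi, lo)


class TestFitMLE:
    def test_parameter_recovery(self, recovery_table):
        """Priors within 0.1 and noise-SD ordering recovered from synthetic data."""
        fit = recovery_table["fit"]
        assert fit.converged
        assert np.all(np.diff(fit.sigma_t) > 0)
        np.testing.assert_allclose(fit.priors, [0.2, 0.5, 0.8], atol=0.1)

    def test_nll_not_worse_than_truth(self, recovery_table):
        """On-sample optimality: fitted NLL <= NLL at the generating values."""
        assert recovery_table["fit"].nll <= recovery_table["truth_nll"] + 1.0

    def test_degenerate_all_jump_data_hits_bounds(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        rows = []
        for prior in (0.2, 0.5, 0.8):
            for noise in (0.5, 1.25, 2.0):
                disp = rng.standard_normal(50)
                rows.append(
                    pd.DataFrame(
                        {
                            "displacement_deg": disp,
                            "prior_label": prior,
                            "noise_sigma_deg": noise,
                            "response": 1.0,
                        }
                    )
                )
        table = pd.concat(rows, ignore_index=True)
        fit = fit_mle(table, n_restarts=2, random_state=0)
        # a perfect always-jump dataset is explained by boundary parameters
        preds = [
            lapse_scaled_curve(0.0, fit.params_for(i, j))
            for i in range(3)
            for j in range(3)
        ]
        assert np.mean(preds) > 0.9


@pytest.fixture(scope="module")
def recovery_table():
    """Moderate-size recovery harness shared by the MLE tests."""
    from conftest import make_categorical_session
    from ssdmodels.categorical import lapse_scaled_curve as curve

    table = make_categorical_session(seed=11, n_per=2000)
    fit = fit_mle(table, n_restarts=6, random_state=0)
    # NLL at the generating parameters
    truth_nll = 0.0
    for prior in (0.2, 0.5, 0.8):
        for sigma_t in (0.5, 1.25, 2.0):
            m = (table.prior_label == prior) & (table.noise_sigma_deg == sigma_t)
            p = CategoricalObserverParams(
                p_jump=prior, sigma_jump=2.5, sigma_nojump=0.2, sigma_t=sigma_t,
                lower_bound=0.02, lapse=0.05,
            )
            probs = np.clip(
                curve(table.displacement_deg[m].to_numpy(), p), 1e-9, 1 - 1e-9
            )
            y = table.response[m].to_numpy()
            truth_nll -= float(
                np.sum(y * np.log(probs) + (1 - y) * np.log1p(-probs))
            )
    return {"fit": fit, "truth_nll": truth_nll}
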