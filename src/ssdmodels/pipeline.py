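"""Config-driven scenario runner.

Each scenario binds the library's operations with the canonical simulation
parameters and writes summary CSVs plus a JSON manifest (written last, so its
presence signals a complete run).  Scenario defaults are the simulation
parameters the models were designed around; any override is recorded in the
manifest.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .categorical import CategoricalObserverParams, decision_curve, fit_mle
from .combined import CombinedConfig, simulate_combined_experiment, simulate_saccade_contrast
from .continuous import ContinuousObserverParams, deviation_curve, fit_continuous
from .design import write_manifest
from .perceptron import run_training, snapshot_curves, standard_training_blocks

log = logging.getLogger("ssdmodels")

__all__ = ["SCENARIOS", "run_scenario"]

# Canonical simulation parameters: broad/narrow likelihood widths 2 / 0.017 deg,
# mixture-corrected priors 0.22 / 0.78 (70% true-statistic trials, 30% neutral).
_SIM_PRIORS = (0.22, 0.5, 0.78)
_SIM_SIGMA_J = 2.0
_SIM_SIGMA_NJ = 0.017
_NOISE_LEVELS = (0.1, 0.25, 0.5)


def _curve_table(priors, sigma_t_levels, x_grid):
    rows = []
    for sigma_t in sigma_t_levels:
        for p in priors:
            params = CategoricalObserverParams(
                p_jump=p, sigma_jump=_SIM_SIGMA_J, sigma_nojump=_SIM_SIGMA_NJ,
                sigma_t=sigma_t,
            )
            d = decision_curve(x_grid, params)
            for x, v in zip(x_grid, d):
                rows.append(
                    {"sigma_t": sigma_t, "prior": p, "displacement": x, "p_jump_report": v}
                )
    return pd.DataFrame(rows)


def _scenario_prior_learning(outdir: Path, seed: int, config: dict):
    """Ideal-observer decision curves and intercepts at the lowest noise level."""
    x_grid = np.linspace(0.0, 5.0, 101)
    curves = _curve_table(_SIM_PRIORS, (_NOISE_LEVELS[0],), x_grid)
    curves.to_csv(outdir / "decision_curves.csv", index=False)
    intercepts = (
        curves[curves["displacement"] == 0.0][["sigma_t", "prior", "p_jump_report"]]
        .rename(columns={"p_jump_report": "intercept"})
    )
    intercepts.to_csv(outdir / "intercepts.csv", index=False)
    return {"decision_curves": outdir / "decision_curves.csv",
            "intercepts": outdir / "intercepts.csv"}


def _scenario_noise_tradeoff(outdir: Path, seed: int, config: dict):
    """High-low prior intercept differences across sensory-noise levels."""
    x_grid = np.linspace(0.0, 5.0, 101)
    curves = _curve_table((_SIM_PRIORS[0], _SIM_PRIORS[2]), _NOISE_LEVELS, x_grid)
    curves.to_csv(outdir / "decision_curves.csv", index=False)
    rows = []
    for sigma_t in _NOISE_LEVELS:
        at0 = curves[(curves["displacement"] == 0.0) & (curves["sigma_t"] == sigma_t)]
        hi = at0[at0["prior"] == _SIM_PRIORS[2]]["p_jump_report"].iloc[0]
        lo = at0[at0["prior"] == _SIM_PRIORS[0]]["p_jump_report"].iloc[0]
        rows.append({"sigma_t": sigma_t, "intercept_difference": hi - lo})
    pd.DataFrame(rows).to_csv(outdir / "intercept_differences.csv", index=False)
    return {"decision_curves": outdir / "decision_curves.csv",
            "intercept_differences": outdir / "intercept_differences.csv"}


def _scenario_continuous(outdir: Path, seed: int, config: dict):
    """Deviation-curve predictions for the continuous observer (biased and unbiased)."""
    x = np.linspace(-3.0, 3.0, 61)
    rows = []
    for mu_prior in (0.0, config.get("bias", -0.5)):
        params = ContinuousObserverParams(
            mu_prior=mu_prior,
            sigma_prior=1.0,
            sigma_likelihood_by_noise={0.1: 0.1, 0.5: 0.5, 1.0: 1.0},
        )
        for noise in (0.1, 0.5, 1.0):
            dev = deviation_curve(x, params, noise)
            for xi, di in zip(x, dev):
                rows.append(
                    {"mu_prior": mu_prior, "noise": noise,
                     "displacement": xi, "predicted_deviation": di}
                )
    pd.DataFrame(rows).to_csv(outdir / "deviation_curves.csv", index=False)
    return {"deviation_curves": outdir / "deviation_curves.csv"}


def _scenario_motor_noise(outdir: Path, seed: int, config: dict):
    """Saccade vs no-saccade Bayesian predictions (motor-driven uncertainty)."""
    table = simulate_saccade_contrast()
    table.to_csv(outdir / "saccade_contrast.csv", index=False)
    return {"saccade_contrast": outdir / "saccade_contrast.csv"}


def _scenario_perceptron_training(outdir: Path, seed: int, config: dict):
    """Delta-rule training ensemble with early-training snapshot curves."""
    n_runs = int(config.get("n_runs", 200))
    result = run_training(blocks=standard_training_blocks(), seed=seed, n_runs=n_runs)
    curves = snapshot_curves(result)
    curves.to_csv(outdir / "training_curves.csv", index=False)
    log.info("perceptron training: %d runs x %d trials", n_runs, result.o_jump.shape[1])
    return {"training_curves": outdir / "training_curves.csv"}


def _scenario_combined(outdir: Path, seed: int, config: dict):
    """Combined-model simulation: intercept differences across visual noise."""
    n_runs = int(config.get("n_runs", 1000))
    sim = simulate_combined_experiment(CombinedConfig(), seed=seed, n_runs=n_runs)
    diffs = pd.DataFrame(
        [{"noise_sigma_deg": k, "intercept_difference": v}
         for k, v in sim.intercept_differences.items()]
    )
    diffs.to_csv(outdir / "intercept_differences.csv", index=False)
    sim.intercepts.to_csv(outdir / "intercepts.csv", index=False)
    sim.early_curves.to_csv(outdir / "early_curves.csv", index=False)
    sim.late_curves.to_csv(outdir / "late_curves.csv", index=False)
    return {
        "intercept_differences": outdir / "intercept_differences.csv",
        "intercepts": outdir / "intercepts.csv",
        "early_curves": outdir / "early_curves.csv",
        "late_curves": outdir / "late_curves.csv",
    }


def _scenario_recovery(outdir: Path, seed: int, config: dict):
    """Parameter-recovery report for the categorical MLE and continuous fit."""
    rng = np.random.default_rng(seed)
    # categorical: simulate one session from known parameters and refit
    n_per = int(config.get("n_per_condition", 2000))
    true_priors = {0.2: 0.2, 0.5: 0.5, 0.8: 0.8}
    noise_levels = (0.5, 1.25, 2.0)
    rows = []
    for prior in true_priors:
        for sigma_t in noise_levels:
            params = CategoricalObserverParams(
                p_jump=prior, sigma_jump=2.5, sigma_nojump=0.2, sigma_t=sigma_t,
                lower_bound=0.05, lapse=0.05,
            )
            jumped = rng.random(n_per) < prior
            disp = np.where(
                jumped, 2.5 * rng.standard_normal(n_per), 0.2 * rng.standard_normal(n_per)
            )
            from .categorical import lapse_scaled_curve

            p = lapse_scaled_curve(disp, params)
            resp = (rng.random(n_per) < p).astype(float)
            for d, j, r in zip(disp, jumped, resp):
                rows.append(
                    {"displacement_deg": d, "prior_label": prior,
                     "noise_sigma_deg": sigma_t, "jumped": j, "response": r}
                )
    table = pd.DataFrame(rows)
    fit = fit_mle(table, n_restarts=int(config.get("n_restarts", 5)),
                  random_state=seed)
    cat_report = pd.DataFrame(
        {
            "true_prior": sorted(true_priors),
            "fit_prior": fit.priors,
            "true_sigma_t": noise_levels,
            "fit_sigma_t": fit.sigma_t,
        }
    )
    cat_report.to_csv(outdir / "categorical_recovery.csv", index=False)

    # continuous: simulate reports from known params and refit
    true = ContinuousObserverParams(
        mu_prior=-0.2, sigma_prior=1.0,
        sigma_likelihood_by_noise={0.1: 0.3, 0.5: 0.6, 1.0: 0.9},
    )
    n = int(config.get("n_continuous", 400))
    disp = rng.standard_normal(n)
    noise = rng.choice([0.1, 0.5, 1.0], size=n)
    from .continuous import posterior_mean

    reports = np.array(
        [posterior_mean(d, true, nz) for d, nz in zip(disp, noise)]
    ) + 0.3 * rng.standard_normal(n)
    cont_table = pd.DataFrame(
        {"displacement_deg": disp, "noise_sigma_deg": noise, "response": reports}
    )
    cont_fit, sse = fit_continuous(cont_table, random_state=seed)
    cont_report = pd.DataFrame(
        {
            "noise": [0.1, 0.5, 1.0],
            "true_sigma_likelihood": [0.3, 0.6, 0.9],
            "fit_sigma_likelihood": [cont_fit.sigma_likelihood_by_noise[z]
                                     for z in (0.1, 0.5, 1.0)],
            "true_mu_prior": true.mu_prior,
            "fit_mu_prior": cont_fit.mu_prior,
        }
    )
    cont_report.to_csv(outdir / "continuous_recovery.csv", index=False)
    return {
        "categorical_recovery": outdir / "categorical_recovery.csv",
        "continuous_recovery": outdir / "continuous_recovery.csv",
    }


SCENARIOS = {
    "prior_learning_predictions": _scenario_prior_learning,
    "noise_tradeoff_predictions": _scenario_noise_tradeoff,
    "continuous_predictions": _scenario_continuous,
    "motor_noise_predictions": _scenario_motor_noise,
    "perceptron_training": _scenario_perceptron_training,
    "combined_model": _scenario_combined,
    "recovery_suite": _scenario_recovery,
}


def run_scenario(name: str, config: dict | None = None, seed: int = 0,
                 outdir=None) -> Path:
    """Run a named scenario; returns the output directory.

    The manifest (``manifest.json``) is written last; treat its absence as a
    partial run.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}")
    config = dict(config or {})
    outdir = Path(outdir or f"scenario_{name}")
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("scenario %s: seed=%d outdir=%s", name, seed, outdir)
    outputs = SCENARIOS[name](outdir, seed, config)
    write_manifest(
        outdir / "manifest.json",
        seeds={"scenario": seed},
        outputs=outputs,
        config={"scenario": name, **config},
        version=__version__,
    )
    return outdir
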