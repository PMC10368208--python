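"""Synthetic trial schedules for saccadic suppression of displacement (SSD) tasks.

Every experiment in this package follows the same skeleton: an observer makes
(or withholds) a saccade, the target is displaced mid-saccade by an amount
drawn from a broad "jump" or a narrow "no-jump" Gaussian, and the observer
reports either a binary jump judgment or a continuous landing position.  The
generator here builds trial tables with exactly the cell structure of those
designs -- per-(prior, noise, phase) counts are deterministic, only the order
and the displacement draws are random -- so that realized trial proportions
can be asserted exactly in tests.

The canonical categorical design is a 1300-trial session: one 100-trial
neutral baseline block followed by six 100-trial blocks per cued prior.  70%
of the trials in each prior block are low-noise training trials whose true
jump probability matches the cue; the remaining 30% are medium/high-noise
testing trials with a veridical jump probability of 0.5.  That makes each
prior's training trials 420/1300 = 32.3% of the session and each
(prior, noise) testing cell 90/1300 = 6.9%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "INFINITE_NOISE",
    "TRIAL_COLUMNS",
    "DisplacementDistributions",
    "BlockSpec",
    "ExperimentDesign",
    "human_categorical_design",
    "monkey_categorical_design",
    "monkey_control_design",
    "continuous_design",
    "motor_noise_design",
    "get_design",
    "build_schedule",
    "respond_categorical",
    "respond_continuous",
    "filter_by_timing",
    "write_trial_table",
    "read_trial_table",
    "write_design",
    "read_design",
    "write_manifest",
]

#: Sentinel for the "target never reappears" condition.  Deliberately a string,
#: not a float, so that accidental arithmetic on it raises instead of silently
#: propagating an infinity.
INFINITE_NOISE = "infinite"

#: Fixed serialized column order for trial tables.
TRIAL_COLUMNS = [
    "trial",
    "block",
    "prior_label",
    "veridical_p_jump",
    "noise_sigma_deg",
    "jumped",
    "displacement_deg",
    "saccade_made",
    "direction_vs_saccade",
    "phase",
    "jump_cmd_to_saccade_end_ms",
    "response",
]

# Jump-command timing relative to detected saccade end (ms), used only to
# exercise the timing filter.  Negative = command issued before saccade end.
HUMAN_TIMING_MS = (-17.25, 1.80)
MONKEY_TIMING_MS = (-7.63, 5.07)


@dataclass(frozen=True)
class DisplacementDistributions:
    """Overlapping Gaussians from which signed displacements are drawn.

    The jump distribution is broad, the no-jump distribution narrow; both are
    centered on zero in every experiment modeled here.
    """

    mu_jump: float = 0.0
    sigma_jump: float = 1.5
    mu_nojump: float = 0.0
    sigma_nojump: float = 0.017

    def __post_init__(self) -> None:
        if not (self.sigma_jump > self.sigma_nojump > 0):
            raise ValueError(
                "require sigma_jump > sigma_nojump > 0, got "
                f"{self.sigma_jump}, {self.sigma_nojump}"
            )


@dataclass(frozen=True)
class BlockSpec:
    """One contiguous block of trials.

    ``cells`` maps (noise level, phase) to (n_trials, veridical jump
    probability).  Noise level may be the :data:`INFINITE_NOISE` sentinel.
    """

    prior_label: float
    cells: tuple  # tuple of ((noise, phase), (count, p_jump))
    saccade: bool = True

    def n_trials(self) -> int:
        return sum(count for (_, _), (count, _) in self.cells)


@dataclass(frozen=True)
class ExperimentDesign:
    design_id: str
    displacement: DisplacementDistributions
    blocks: tuple  # tuple of BlockSpec
    timing_mean_ms: float
    timing_sd_ms: float
    continuous_report: bool = False

    def __post_init__(self) -> None:
        for block in self.blocks:
            if not 0.0 <= block.prior_label <= 1.0:
                raise ValueError(f"prior_label {block.prior_label} outside [0, 1]")
            for (noise, phase), (count, p_jump) in block.cells:
                if count <= 0 or count != int(count):
                    raise ValueError(f"cell count {count} must be a positive integer")
                if not 0.0 <= p_jump <= 1.0:
                    raise ValueError(f"jump probability {p_jump} outside [0, 1]")
                if noise == INFINITE_NOISE and not self.continuous_report:
                    raise ValueError(
                        "infinite-noise trials exist only in the continuous design"
                    )

    @property
    def prior_levels(self) -> tuple:
        return tuple(sorted({b.prior_label for b in self.blocks}))

    @property
    def noise_levels(self) -> tuple:
        finite = sorted(
            {n for b in self.blocks for (n, _), _ in b.cells if n != INFINITE_NOISE}
        )
        has_inf = any(
            n == INFINITE_NOISE for b in self.blocks for (n, _), _ in b.cells
        )
        return tuple(finite) + ((INFINITE_NOISE,) if has_inf else ())

    def n_trials(self) -> int:
        return sum(b.n_trials() for b in self.blocks)


# ---------------------------------------------------------------------------
# Design presets
# ---------------------------------------------------------------------------

def _categorical_blocks(priors, noise_levels, *, veridical_testing=0.5,
                        control=False, n_blocks_per_prior=6, block_size=100,
                        train_frac=0.7):
    """Baseline block + prior blocks with a 70/30 training/testing split.

    Per 100-trial prior block: 70 low-noise training trials at the cued jump
    probability and 30 testing trials split evenly between the medium and high
    noise levels.  In the control design the testing trials keep the cued
    probability instead of reverting to 0.5.
    """
    low, med, high = noise_levels
    n_train = round(block_size * train_frac)
    n_test_each = (block_size - n_train) // 2
    # Baseline: neutral prior; a token 5% of trials at each higher noise level
    # keeps the noise manipulation familiar from the start of the session.
    baseline = BlockSpec(
        prior_label=0.5,
        cells=(
            ((low, "baseline"), (90, 0.5)),
            ((med, "baseline"), (5, 0.5)),
            ((high, "baseline"), (5, 0.5)),
        ),
    )
    blocks = [baseline]
    for prior in priors:
        p_test = prior if control else veridical_testing
        for _ in range(n_blocks_per_prior):
            blocks.append(
                BlockSpec(
                    prior_label=prior,
                    cells=(
                        ((low, "training"), (n_train, prior)),
                        ((med, "testing"), (n_test_each, p_test)),
                        ((high, "testing"), (n_test_each, p_test)),
                    ),
                )
            )
    return tuple(blocks)


def human_categorical_design() -> ExperimentDesign:
    """Human categorical session: priors cued at 0.1/0.9, blob SDs 0.1/0.25/0.5 deg."""
    return ExperimentDesign(
        design_id="human_categorical",
        displacement=DisplacementDistributions(sigma_jump=1.5, sigma_nojump=0.017),
        blocks=_categorical_blocks((0.9, 0.1), (0.1, 0.25, 0.5)),
        timing_mean_ms=HUMAN_TIMING_MS[0],
        timing_sd_ms=HUMAN_TIMING_MS[1],
    )


def monkey_categorical_design(high_noise: float = 2.0) -> ExperimentDesign:
    """Macaque categorical session: priors 0.2/0.8, blob SDs 0.5/1.25/`high_noise`."""
    return ExperimentDesign(
        design_id="monkey_categorical",
        displacement=DisplacementDistributions(sigma_jump=2.5, sigma_nojump=0.2),
        blocks=_categorical_blocks((0.8, 0.2), (0.5, 1.25, high_noise)),
        timing_mean_ms=MONKEY_TIMING_MS[0],
        timing_sd_ms=MONKEY_TIMING_MS[1],
    )


def monkey_control_design(high_noise: float = 2.0) -> ExperimentDesign:
    """Control session: jump probability matches the cued prior at every noise level."""
    return ExperimentDesign(
        design_id="monkey_control",
        displacement=DisplacementDistributions(sigma_jump=2.5, sigma_nojump=0.2),
        blocks=_categorical_blocks((0.8, 0.2), (0.5, 1.25, high_noise), control=True),
        timing_mean_ms=MONKEY_TIMING_MS[0],
        timing_sd_ms=MONKEY_TIMING_MS[1],
    )


def continuous_design() -> ExperimentDesign:
    """Continuous-report session.

    600 training trials (80% low noise, 20% target-absent) followed by 400
    testing trials across blob SDs 0.1/0.5/1.0 deg plus 20% target-absent
    ("infinite noise") trials.  Displacements are drawn from the continuous
    prior N(0 deg, 1 deg) on every trial, so every trial is a "jump" trial and
    the jump/no-jump dichotomy is degenerate.
    """
    displacement = DisplacementDistributions(sigma_jump=1.0, sigma_nojump=1e-6)
    training = BlockSpec(
        prior_label=1.0,
        cells=(
            ((0.1, "training"), (480, 1.0)),
            ((INFINITE_NOISE, "training"), (120, 1.0)),
        ),
    )
    testing = BlockSpec(
        prior_label=1.0,
        cells=(
            ((0.1, "testing"), (107, 1.0)),
            ((0.5, "testing"), (107, 1.0)),
            ((1.0, "testing"), (106, 1.0)),
            ((INFINITE_NOISE, "testing"), (80, 1.0)),
        ),
    )
    return ExperimentDesign(
        design_id="continuous",
        displacement=displacement,
        blocks=(training, testing),
        timing_mean_ms=HUMAN_TIMING_MS[0],
        timing_sd_ms=HUMAN_TIMING_MS[1],
        continuous_report=True,
    )


def motor_noise_design(n_per_cell: int = 1000) -> ExperimentDesign:
    """Saccade vs no-saccade session: priors 0.2/0.5/0.8, lowest blob SD throughout.

    All six (prior x saccade) trial types are interleaved; the jump probability
    is veridical (matches the cue) in every cell.
    """
    blocks = []
    for saccade in (True, False):
        for prior in (0.2, 0.5, 0.8):
            blocks.append(
                BlockSpec(
                    prior_label=prior,
                    cells=(((0.5, "testing"), (n_per_cell, prior)),),
                    saccade=saccade,
                )
            )
    return ExperimentDesign(
        design_id="motor_noise",
        displacement=DisplacementDistributions(sigma_jump=2.5, sigma_nojump=0.2),
        blocks=tuple(blocks),
        timing_mean_ms=MONKEY_TIMING_MS[0],
        timing_sd_ms=MONKEY_TIMING_MS[1],
    )


_DESIGNS = {
    "human_categorical": human_categorical_design,
    "monkey_categorical": monkey_categorical_design,
    "monkey_control": monkey_control_design,
    "continuous": continuous_design,
    "motor_noise": motor_noise_design,
}


def get_design(design_id: str) -> ExperimentDesign:
    try:
        return _DESIGNS[design_id]()
    except KeyError:
        raise ValueError(
            f"unknown design {design_id!r}; known: {sorted(_DESIGNS)}"
        ) from None


# ---------------------------------------------------------------------------
# Schedule construction
# ---------------------------------------------------------------------------

def build_schedule(design: ExperimentDesign, seed: int) -> pd.DataFrame:
    """Build a trial table with exact per-cell counts and randomized order.

    Jump flags are Bernoulli draws at each cell's veridical probability;
    displacements come from the design's jump/no-jump Gaussians.  The schedule
    also carries a synthetic jump-command-to-saccade-end latency (Gaussian with
    the design's timing parameters) for exercising the timing filter.
    Responses are left missing; use a responder pass to fill them.
    """
    rng = np.random.default_rng(seed)
    d = design.displacement
    rows = []
    trial = 0
    for block_idx, block in enumerate(design.blocks):
        block_rows = []
        for (noise, phase), (count, p_jump) in block.cells:
            for _ in range(int(count)):
                block_rows.append((noise, phase, p_jump))
        order = rng.permutation(len(block_rows))
        for i in order:
            noise, phase, p_jump = block_rows[i]
            jumped = bool(rng.random() < p_jump)
            sigma = d.sigma_jump if jumped else d.sigma_nojump
            mu = d.mu_jump if jumped else d.mu_nojump
            disp = mu + sigma * rng.standard_normal()
            timing = design.timing_mean_ms + design.timing_sd_ms * rng.standard_normal()
            rows.append(
                {
                    "trial": trial,
                    "block": block_idx,
                    "prior_label": block.prior_label,
                    "veridical_p_jump": p_jump,
                    "noise_sigma_deg": noise,
                    "jumped": jumped,
                    "displacement_deg": disp,
                    "saccade_made": block.saccade,
                    "direction_vs_saccade": "with" if disp >= 0 else "against",
                    "phase": phase,
                    "jump_cmd_to_saccade_end_ms": timing,
                    "response": np.nan,
                }
            )
            trial += 1
    table = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    table.attrs["design_id"] = design.design_id
    table.attrs["seed"] = seed
    return table


# ---------------------------------------------------------------------------
# Responder passes
# ---------------------------------------------------------------------------

def respond_categorical(table: pd.DataFrame, observer, seed: int) -> pd.DataFrame:
    """Fill binary responses by Bernoulli sampling from a decision curve.

    ``observer(displacement, prior_label, noise_sigma) -> P(report "jumped")``
    is evaluated per trial; values outside [0, 1] raise.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    probs = np.array(
        [
            observer(row.displacement_deg, row.prior_label, row.noise_sigma_deg)
            for row in table.itertuples()
        ],
        dtype=float,
    )
    if np.any((probs < 0) | (probs > 1)) or np.any(~np.isfinite(probs)):
        raise ValueError("observer returned probabilities outside [0, 1]")
    out["response"] = (rng.random(len(probs)) < probs).astype(float)
    return out


def respond_continuous(
    table: pd.DataFrame,
    params,
    report_noise_sd: float = 0.0,
    seed: int = 0,
    infinite_policy: str = "presaccadic",
) -> pd.DataFrame:
    """Fill continuous responses with the posterior mean plus report noise.

    Finite-noise trials respond with the reliability-weighted posterior mean of
    the continuous observer ``params`` (a
    :class:`~ssdmodels.continuous.ContinuousObserverParams`).  Target-absent
    trials follow ``infinite_policy``:

    - ``"presaccadic"`` (default): report the presaccadic location, i.e. a
      displacement of zero -- the strategy observers adopt when the target
      never reappears.
    - ``"prior"``: report the prior mean.
    """
    from .continuous import posterior_mean

    if infinite_policy not in ("presaccadic", "prior"):
        raise ValueError(f"unknown infinite_policy {infinite_policy!r}")
    rng = np.random.default_rng(seed)
    out = table.copy()
    responses = np.empty(len(table), dtype=float)
    for i, row in enumerate(table.itertuples()):
        if row.noise_sigma_deg == INFINITE_NOISE:
            responses[i] = 0.0 if infinite_policy == "presaccadic" else params.mu_prior
        else:
            responses[i] = posterior_mean(
                row.displacement_deg, params, row.noise_sigma_deg
            )
    if report_noise_sd > 0:
        responses = responses + report_noise_sd * rng.standard_normal(len(responses))
    out["response"] = responses
    return out


# ---------------------------------------------------------------------------
# Trial-timing exclusion filter
# ---------------------------------------------------------------------------

def filter_by_timing(table: pd.DataFrame, frame_ms: float) -> pd.DataFrame:
    """Drop trials whose jump command preceded saccade end by more than one frame.

    Keeps trials with ``jump_cmd_to_saccade_end_ms >= -frame_ms``.  The number
    of removed trials is stored in ``.attrs["n_excluded_by_timing"]``.
    """
    if "jump_cmd_to_saccade_end_ms" not in table.columns:
        raise ValueError("table has no jump_cmd_to_saccade_end_ms column")
    timing = table["jump_cmd_to_saccade_end_ms"]
    if timing.isna().any():
        raise ValueError("timing field contains missing values")
    keep = timing >= -frame_ms
    out = table.loc[keep].copy()
    out.attrs.update(table.attrs)
    out.attrs["n_excluded_by_timing"] = int((~keep).sum())
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_trial_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def read_trial_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    # noise column mixes floats with the infinite sentinel; keep as object
    def _coerce(v):
        if v == INFINITE_NOISE:
            return INFINITE_NOISE
        return float(v)

    table["noise_sigma_deg"] = table["noise_sigma_deg"].map(_coerce)
    return table[TRIAL_COLUMNS]


def write_design(design: ExperimentDesign, path) -> None:
    payload = {
        "design_id": design.design_id,
        "displacement": asdict(design.displacement),
        "timing_mean_ms": design.timing_mean_ms,
        "timing_sd_ms": design.timing_sd_ms,
        "continuous_report": design.continuous_report,
        "blocks": [
            {
                "prior_label": b.prior_label,
                "saccade": b.saccade,
                "cells": [
                    {"noise": n, "phase": ph, "count": c, "p_jump": p}
                    for (n, ph), (c, p) in b.cells
                ],
            }
            for b in design.blocks
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_design(path) -> ExperimentDesign:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    blocks = tuple(
        BlockSpec(
            prior_label=b["prior_label"],
            saccade=b.get("saccade", True),
            cells=tuple(
                ((c["noise"], c["phase"]), (c["count"], c["p_jump"]))
                for c in b["cells"]
            ),
        )
        for b in payload["blocks"]
    )
    return ExperimentDesign(
        design_id=payload["design_id"],
        displacement=DisplacementDistributions(**payload["displacement"]),
        blocks=blocks,
        timing_mean_ms=payload["timing_mean_ms"],
        timing_sd_ms=payload["timing_sd_ms"],
        continuous_report=payload.get("continuous_report", False),
    )


def write_manifest(path, *, seeds: dict, outputs: dict, config: dict | None = None,
                   version: str | None = None) -> None:
    """Record seeds and output paths for a pipeline run (written last)."""
    if version is None:
        from . import __version__ as version
    payload = {
        "version": version,
        "seeds": seeds,
        "outputs": {k: str(v) for k, v in outputs.items()},
        "config": config or {},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
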