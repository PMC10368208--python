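"""Discriminative (delta-rule) two-layer network for jump categorization.

The network bins absolute displacements (0 to 7.5 deg in 0.1-deg bins, 75
input units) and maps them onto two output units, "jump" and "no jump".
Sensory noise spreads input activation as a Gaussian over the bins, truncated
to the input range and renormalized so total input activation is always 1.
Output activations are the weighted sums of the inputs, rectified at zero and
normalized to sum to 1.  Weights are updated by the delta (Perceptron) rule

    dw_ij = beta * a_i * (d_j - o_j)

toward the desired state d (1 for the correct output unit, 0 for the other),
with weights constrained to be non-negative (excitatory-only connections);
see the methods note for why the constraint matters.
Each cued prior has its own context -- a separate weight matrix -- so the
psychometric curve the network expresses can differ across prior cues at the
same point in training.  The error-driven rule overweights infrequent events
early in training (large displacements under a low prior produce large
errors and hence large updates), which is the behavioral signature this model
exists to capture; late in training, weights asymptote and curves across
priors become parallel.

The trainer is vectorized across ensemble runs: an ensemble of N independent
networks (each with its own random trial order and displacement draws) is a
single set of array operations per trial, which keeps thousand-run ensembles
cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PerceptronConfig",
    "PerceptronState",
    "TrainingBlock",
    "TrainingResult",
    "encode_input",
    "forward",
    "update",
    "standard_training_blocks",
    "extended_training_blocks",
    "run_training",
    "snapshot_curves",
    "DisplacementPerceptron",
]

_EPS = 1e-12


@dataclass(frozen=True)
class PerceptronConfig:
    bin_width: float = 0.1
    range_min: float = 0.0
    range_max: float = 7.5
    learning_rate: float = 0.5
    contexts: tuple = (0.5, 0.8, 0.2)

    def __post_init__(self) -> None:
        span = self.range_max - self.range_min
        n = span / self.bin_width
        if not (n > 0 and abs(n - round(n)) < 1e-9):
            raise ValueError("(range_max - range_min)/bin_width must be a positive integer")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @property
    def n_bins(self) -> int:
        return int(round((self.range_max - self.range_min) / self.bin_width))

    @property
    def edges(self) -> np.ndarray:
        return self.range_min + self.bin_width * np.arange(self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        return self.range_min + self.bin_width * (np.arange(self.n_bins) + 0.5)


@dataclass
class PerceptronState:
    """Per-context weight matrices (n_bins x 2); column 0 = jump, 1 = no jump."""

    config: PerceptronConfig
    weights: dict = field(default_factory=dict)
    trial_count: int = 0

    @classmethod
    def zeros(cls, config: PerceptronConfig) -> "PerceptronState":
        # Zero initialization is symmetric; the (0.5, 0.5) output guard in
        # `forward` makes the first-trial output well defined.
        weights = {c: np.zeros((config.n_bins, 2)) for c in config.contexts}
        return cls(config=config, weights=weights)


def encode_input(x_abs: float, sigma_noise: float, config: PerceptronConfig) -> np.ndarray:
    """Gaussian population activation over displacement bins, summing to 1.

    Each bin receives the N(x_abs, sigma^2) probability mass inside it; the
    truncated total over [range_min, range_max] is renormalized to exactly 1.
    sigma = 0 puts all mass in the bin containing x_abs.  Inputs above the top
    of the range are clamped to the last bin with a warning (broad jump draws
    occasionally exceed the coded range).
    """
    if x_abs < 0:
        raise ValueError("x_abs must be non-negative (inputs are absolute displacements)")
    if x_abs > config.range_max:
        warnings.warn(
            f"displacement {x_abs:.3g} exceeds coded range; clamping", stacklevel=2
        )
        x_abs = config.range_max
    return _encode_batch(np.array([x_abs]), sigma_noise, config)[0]


def _encode_batch(x_abs: np.ndarray, sigma_noise: float, config: PerceptronConfig) -> np.ndarray:
    """Vectorized encoder: (n,) displacements -> (n, n_bins) activations."""
    x = np.clip(np.asarray(x_abs, dtype=float), config.range_min, config.range_max)
    n_bins = config.n_bins
    if sigma_noise == 0.0:
        idx = np.minimum(
            ((x - config.range_min) / config.bin_width).astype(int), n_bins - 1
        )
        act = np.zeros((len(x), n_bins))
        act[np.arange(len(x)), idx] = 1.0
        return act
    z = (config.edges[None, :] - x[:, None]) / sigma_noise
    cdf = stats.norm.cdf(z)
    act = np.diff(cdf, axis=1)
    total = act.sum(axis=1, keepdims=True)
    # Guard: far out-of-range centers leave negligible truncated mass
    total = np.where(total < _EPS, 1.0, total)
    return act / total


def forward(state: PerceptronState, context, activation: np.ndarray):
    """Output (o_jump, o_nojump): rectified, normalized weighted input sums."""
    w = state.weights[context]
    a_out = activation @ w
    rect = np.maximum(a_out, 0.0)
    total = rect.sum()
    if total <= _EPS:
        return 0.5, 0.5
    return float(rect[0] / total), float(rect[1] / total)


def update(state: PerceptronState, context, activation: np.ndarray,
           desired_jump: int) -> PerceptronState:
    """Delta-rule update of the active context's weights (in place).

    dw_ij = beta * a_i * (d_j - o_j) with d = (1, 0) on jump trials and (0, 1)
    otherwise; only the active context learns, and bins with zero activation
    keep their weights.  Updated weights are clipped at zero: connections are
    excitatory-only, which keeps the rectified output stage well behaved.
    """
    o = np.array(forward(state, context, activation))
    d = np.array([1.0, 0.0]) if desired_jump else np.array([0.0, 1.0])
    beta = state.config.learning_rate
    w = state.weights[context]
    np.maximum(w + beta * activation[:, None] * (d - o)[None, :], 0.0, out=w)
    state.trial_count += 1
    return state


# ---------------------------------------------------------------------------
# Training protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingBlock:
    """One training block: a prior context with a 70/30 training/testing mix.

    Training trials use the lowest input noise and the context's veridical
    jump probability; testing trials split evenly between ``test_noises`` at a
    neutral jump probability but use the same prior context's inputs.
    """

    context: float
    n_trials: int
    train_frac: float = 0.7
    train_noise: float = 0.1
    test_noises: tuple = (1.0, 2.0)
    test_p_jump: float = 0.5


def standard_training_blocks(n_block: int = 600, n_baseline: int = 100) -> tuple:
    """Short protocol: neutral baseline block, then one block per biased prior."""
    return (
        TrainingBlock(context=0.5, n_trials=n_baseline),
        TrainingBlock(context=0.8, n_trials=n_block),
        TrainingBlock(context=0.2, n_trials=n_block),
    )


def extended_training_blocks(n_trials: int = 5000, n_baseline: int = 100) -> tuple:
    """Long-run protocol for late-training (asymptotic) snapshots."""
    return (
        TrainingBlock(context=0.5, n_trials=n_baseline),
        TrainingBlock(context=0.8, n_trials=n_trials),
        TrainingBlock(context=0.2, n_trials=n_trials),
    )


@dataclass
class TrainingResult:
    config: PerceptronConfig
    context: np.ndarray        # (n_trials,) block context per trial
    block: np.ndarray          # (n_trials,) block index
    phase: np.ndarray          # (n_trials,) "training" | "testing"
    noise: np.ndarray          # (n_runs, n_trials) input noise SD
    displacement: np.ndarray   # (n_runs, n_trials) absolute displacement
    jumped: np.ndarray         # (n_runs, n_trials) bool
    o_jump: np.ndarray         # (n_runs, n_trials) jump-unit output pre-update
    weights: np.ndarray        # (n_runs, n_contexts, n_bins, 2) final weights
    context_index: dict        # context label -> index into weights axis 1

    @property
    def n_runs(self) -> int:
        return self.o_jump.shape[0]

    def final_output(self, x_abs, context, sigma_noise: float) -> np.ndarray:
        """Ensemble outputs o_jump for displacement(s) x under final weights."""
        x_abs = np.atleast_1d(np.asarray(x_abs, dtype=float))
        act = _encode_batch(x_abs, sigma_noise, self.config)   # (m, n_bins)
        w = self.weights[:, self.context_index[context]]       # (r, n_bins, 2)
        a_out = np.einsum("mb,rbo->rmo", act, w)
        rect = np.maximum(a_out, 0.0)
        total = rect.sum(axis=2)
        guard = total <= _EPS
        o = np.where(guard, 0.5, rect[:, :, 0] / np.where(guard, 1.0, total))
        return o  # (n_runs, m)


def run_training(
    blocks=None,
    config: PerceptronConfig | None = None,
    sigma_jump: float = 2.5,
    sigma_nojump: float = 0.5,
    seed: int = 0,
    n_runs: int = 1,
) -> TrainingResult:
    """Simulate delta-rule training over an ensemble of independent runs.

    Each run draws its own trial order and displacements; trial-type *counts*
    per block are deterministic (70/30 split, even noise split) and shared
    across runs.  Weight updates occur on every trial -- the behavioral
    protocol gives feedback on training and testing trials alike.

    Returns per-trial jump-unit outputs (evaluated before that trial's
    update), trial metadata, and final weights for snapshot evaluation.
    """
    if blocks is None:
        blocks = standard_training_blocks()
    if config is None:
        contexts = tuple(dict.fromkeys(b.context for b in blocks))
        config = PerceptronConfig(contexts=contexts)
    rng = np.random.default_rng(seed)
    n_bins = config.n_bins
    ctx_index = {c: i for i, c in enumerate(config.contexts)}
    weights = np.zeros((n_runs, len(config.contexts), n_bins, 2))

    ctx_per_trial, block_per_trial, phase_per_trial = [], [], []
    noise_rows, pjump_rows = [], []
    for bi, blk in enumerate(blocks):
        n_train = round(blk.n_trials * blk.train_frac)
        n_test = blk.n_trials - n_train
        per_noise = n_test // len(blk.test_noises)
        slots_noise = [blk.train_noise] * n_train
        slots_pjump = [blk.context] * n_train
        for j, tn in enumerate(blk.test_noises):
            extra = n_test - per_noise * len(blk.test_noises) if j == 0 else 0
            slots_noise += [tn] * (per_noise + extra)
            slots_pjump += [blk.test_p_jump] * (per_noise + extra)
        slots_noise = np.array(slots_noise)
        slots_pjump = np.array(slots_pjump)
        # independent within-block shuffle per run
        perm = np.argsort(rng.random((n_runs, blk.n_trials)), axis=1)
        noise_rows.append(slots_noise[perm])
        pjump_rows.append(slots_pjump[perm])
        ctx_per_trial += [blk.context] * blk.n_trials
        block_per_trial += [bi] * blk.n_trials
        phase_per_trial += ["training"] * 0  # filled below from p_jump/noise
    noise = np.concatenate(noise_rows, axis=1)      # (n_runs, n_trials)
    p_jump = np.concatenate(pjump_rows, axis=1)
    context = np.array(ctx_per_trial)
    block_arr = np.array(block_per_trial)
    n_trials = len(context)
    train_noise_per_trial = np.array(
        [blocks[b].train_noise for b in block_arr]
    )
    phase = np.where(noise[0] == train_noise_per_trial, "training", "testing")
    # phase is per-run in principle; counts identical, labels follow run 0 for
    # metadata and are recomputed per run where needed.

    jumped = rng.random((n_runs, n_trials)) < p_jump
    disp = np.where(
        jumped,
        np.abs(rng.standard_normal((n_runs, n_trials))) * sigma_jump,
        np.abs(rng.standard_normal((n_runs, n_trials))) * sigma_nojump,
    )

    o_jump = np.empty((n_runs, n_trials))
    beta = config.learning_rate
    run_idx = np.arange(n_runs)
    for t in range(n_trials):
        ci = ctx_index[context[t]]
        sig_t = noise[:, t]
        act = np.empty((n_runs, n_bins))
        for s in np.unique(sig_t):
            mask = sig_t == s
            act[mask] = _encode_batch(disp[mask, t], float(s), config)
        w = weights[:, ci]                        # (n_runs, n_bins, 2) view
        a_out = np.einsum("rb,rbo->ro", act, w)
        rect = np.maximum(a_out, 0.0)
        total = rect.sum(axis=1)
        guard = total <= _EPS
        safe_total = np.where(guard, 1.0, total)
        o = rect / safe_total[:, None]
        o[guard] = 0.5
        o_jump[:, t] = o[:, 0]
        d = np.where(jumped[:, t, None], [[1.0, 0.0]], [[0.0, 1.0]])
        np.maximum(
            w + beta * act[:, :, None] * (d - o)[:, None, :], 0.0,
            out=weights[:, ci],
        )

    return TrainingResult(
        config=config,
        context=context,
        block=block_arr,
        phase=phase,
        noise=noise,
        displacement=disp,
        jumped=jumped,
        o_jump=o_jump,
        weights=weights,
        context_index=ctx_index,
    )


def snapshot_curves(
    result: TrainingResult,
    window: tuple | None = None,
    bin_width: float = 0.5,
    ci: float = 95.0,
    noise_level: float | None = None,
) -> pd.DataFrame:
    """Binned psychometric curves per context over a within-block trial window.

    ``window = (lo, hi)`` selects trials by their index *within each context's
    block* (e.g. ``(3000, 5000)`` for a late-training snapshot); ``None`` uses
    all trials.  ``noise_level`` restricts to trials at one input-noise SD
    (per run, since trial order differs across runs).  Outputs are averaged
    within displacement bins per run, then summarized across the ensemble
    with percentile confidence bounds.
    """
    rows = []
    lo_q, hi_q = (100 - ci) / 2, 100 - (100 - ci) / 2
    for ctx in result.context_index:
        sel = result.context == ctx
        idx_within = np.cumsum(sel) - 1
        if window is not None:
            sel = sel & (idx_within >= window[0]) & (idx_within < window[1])
        if not sel.any():
            continue
        disp = result.displacement[:, sel]
        out = result.o_jump[:, sel]
        if noise_level is not None:
            keep = result.noise[:, sel] == noise_level
            # mask out other-noise trials run-by-run via NaN
            out = np.where(keep, out, np.nan)
        bins = np.floor(disp / bin_width).astype(int)
        for b in np.unique(bins):
            mask = (bins == b) & ~np.isnan(out)
            # per-run mean output in this displacement bin
            counts = mask.sum(axis=1)
            sums = np.where(mask, out, 0.0).sum(axis=1)
            valid = counts > 0
            if valid.sum() == 0:
                continue
            per_run = sums[valid] / counts[valid]
            rows.append(
                {
                    "context": ctx,
                    "bin_center": (b + 0.5) * bin_width,
                    "mean_output": float(per_run.mean()),
                    "ci_lo": float(np.percentile(per_run, lo_q)),
                    "ci_hi": float(np.percentile(per_run, hi_q)),
                    "n_runs": int(valid.sum()),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------

class DisplacementPerceptron:
    """Sklearn-style facade over the delta-rule network.

    ``fit`` consumes an ordered trial sequence (learning is online and
    order-dependent) and leaves the trained state in ``state_``;
    ``predict_proba`` evaluates the trained network.

    Parameters mirror :class:`PerceptronConfig`.
    """

    def __init__(
        self,
        bin_width: float = 0.1,
        range_min: float = 0.0,
        range_max: float = 7.5,
        learning_rate: float = 0.5,
        contexts: tuple = (0.5, 0.8, 0.2),
    ):
        self.bin_width = bin_width
        self.range_min = range_min
        self.range_max = range_max
        self.learning_rate = learning_rate
        self.contexts = contexts

    def get_params(self, deep: bool = True) -> dict:
        return {
            "bin_width": self.bin_width,
            "range_min": self.range_min,
            "range_max": self.range_max,
            "learning_rate": self.learning_rate,
            "contexts": self.contexts,
        }

    def set_params(self, **params):
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def _config(self) -> PerceptronConfig:
        return PerceptronConfig(
            bin_width=self.bin_width,
            range_min=self.range_min,
            range_max=self.range_max,
            learning_rate=self.learning_rate,
            contexts=tuple(self.contexts),
        )

    def fit(self, X, y):
        """Train online over an ordered trial sequence.

        X rows: (absolute displacement, context label, input noise SD);
        y: desired jump state (1 = jumped).
        """
        config = self._config()
        state = PerceptronState.zeros(config)
        y = np.asarray(y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # clamp warnings during bulk training
            for row, d in zip(X, y):
                act = encode_input(min(float(row[0]), config.range_max),
                                   float(row[2]), config)
                update(state, row[1], act, int(d))
        self.state_ = state
        self.n_trials_seen_ = state.trial_count
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "state_"):
            raise RuntimeError("perceptron is not fitted")
        config = self.state_.config
        out = np.empty((len(X), 2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i, row in enumerate(X):
                act = encode_input(min(float(row[0]), config.range_max),
                                   float(row[2]), config)
                o_jump, o_nojump = forward(self.state_, row[1], act)
                out[i] = (o_nojump, o_jump)
        return out

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)
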