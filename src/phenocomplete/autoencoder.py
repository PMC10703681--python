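"""Mixed-type denoising autoencoder for phenotype imputation.

The network h maps a zero-filled phenotype vector through leaky-rectified
hidden layers back to all P phenotypes: outputs 1..C (continuous/ordinal) are
returned raw, outputs C+1..P (binary) pass through a sigmoid s and live in
(0,1). Training minimizes a joint reconstruction loss over every *originally
observed* cell — squared error for continuous targets, cross-entropy for
binary — while copy-masking hides a pattern of inputs per row, so the model
learns to reconstruct values it cannot see (a denoising objective under
realistic, block-structured missingness).

Imputation composes X-hat = M * X + (1 - M) * h(X): observed cells pass
through verbatim; only missing cells are filled, continuous ones on their
original scale and binary ones as probabilities.

The implementation is plain numpy: explicit forward pass, hand-derived
backprop, minibatch SGD with momentum, Kaiming-uniform initialization and
validation-loss checkpointing. At the intended scale (thousands of rows, tens
of phenotypes) this runs in seconds on one CPU.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .masking import CopyMaskPlan, apply_copy_mask
from .phenotype_io import (
    MaskedPhenotypeMatrix,
    NormalizationStats,
    apply_normalization,
    fit_normalization,
)

CHECKPOINT_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelSpec:
    """Architecture of the autoencoder.

    ``hidden_widths`` lists the widths of the hidden layers; the output layer
    always has width P. The default is a single over-complete hidden layer of
    width ceil(1.5 P) — the one-hidden-layer feed-forward form; deeper
    encoders are configured by listing more widths (e.g. ``(60, 28)``).
    ``leaky_slope`` is the LeakyReLU negative-side slope
    l_phi, fixed (not learned). ``printed_phi`` switches to the variant
    phi(x) = max(0,x) - l*min(0,x), which maps negative inputs to small
    positive values; the default is the conventional LeakyReLU
    phi(x) = max(0,x) + l*min(0,x).
    """

    n_features: int
    n_continuous: int
    hidden_widths: tuple[int, ...] | None = None
    leaky_slope: float = 0.01
    printed_phi: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.n_features):
            raise ValueError("n_features must be positive")
        if not (0 <= self.n_continuous <= self.n_features):
            raise ValueError("n_continuous must be in [0, n_features]")
        if not (0.0 < self.leaky_slope < 1.0):
            raise ValueError("leaky_slope must be in (0, 1)")
        if self.hidden_widths is not None:
            object.__setattr__(self, "hidden_widths", tuple(int(w) for w in self.hidden_widths))
            if any(w < 1 for w in self.hidden_widths):
                raise ValueError("hidden widths must be positive")

    @property
    def widths(self) -> tuple[int, ...]:
        """Full layer width sequence: input, hidden..., output."""
        hidden = self.hidden_widths
        if hidden is None:
            hidden = (math.ceil(1.5 * self.n_features),)
        return (self.n_features, *hidden, self.n_features)

    def to_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "n_continuous": self.n_continuous,
            "hidden_widths": None if self.hidden_widths is None else list(self.hidden_widths),
            "leaky_slope": self.leaky_slope,
            "printed_phi": self.printed_phi,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        hw = d["hidden_widths"]
        return cls(
            n_features=d["n_features"],
            n_continuous=d["n_continuous"],
            hidden_widths=None if hw is None else tuple(hw),
            leaky_slope=d["leaky_slope"],
            printed_phi=d["printed_phi"],
        )


@dataclass
class ModelParams:
    """Learnable state Theta: weight matrices and bias vectors per layer."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def copy(self) -> "ModelParams":
        return ModelParams([w.copy() for w in self.weights], [b.copy() for b in self.biases])

    def check_finite(self) -> None:
        for arr in (*self.weights, *self.biases):
            if not np.isfinite(arr).all():
                raise ValueError("non-finite model parameters")


@dataclass(frozen=True)
class TrainConfig:
    """SGD training configuration.

    Defaults mirror the tuned large-biobank settings: learning rate 0.1,
    momentum 0.9, batch size 2,048, up to 500 epochs, copy-mask probability
    rho = 0.8 and a 20% validation split carved from the training rows. The
    scheduler halves the learning rate after ``scheduler_patience`` epochs
    without validation improvement; early stopping is off by default
    (training runs to max_epochs with checkpointing).
    """

    learning_rate: float = 0.1
    momentum: float = 0.9
    batch_size: int = 2048
    max_epochs: int = 500
    rho: float = 0.8
    validation_fraction: float = 0.2
    seed: int = 0
    scheduler_patience: int = 10
    scheduler_factor: float = 0.5
    early_stop_patience: int | None = None
    gradient_scaling: str = "cell"
    mask_mode: str = "copy"

    def __post_init__(self) -> None:
        if self.gradient_scaling not in ("cell", "row"):
            raise ValueError("gradient_scaling must be 'cell' or 'row'")
        if self.mask_mode not in ("copy", "uniform"):
            raise ValueError("mask_mode must be 'copy' or 'uniform'")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "learning_rate": self.learning_rate,
            "momentum": self.momentum,
            "batch_size": self.batch_size,
            "max_epochs": self.max_epochs,
            "rho": self.rho,
            "validation_fraction": self.validation_fraction,
            "seed": self.seed,
            "scheduler_patience": self.scheduler_patience,
            "scheduler_factor": self.scheduler_factor,
            "early_stop_patience": self.early_stop_patience,
            "gradient_scaling": self.gradient_scaling,
            "mask_mode": self.mask_mode,
        }


def _gradient_scale(mode: str, batch_rows: int, n_features: int) -> float:
    """Step-size normalization of summed-loss gradients.

    'cell' (default) divides by batch_rows x P — the per-element averaging
    under which the reference learning rate 0.1 with momentum 0.9 is stable.
    'row' divides by batch_rows only and needs a correspondingly smaller
    learning rate.
    """
    if mode == "cell":
        return 1.0 / (batch_rows * n_features)
    return 1.0 / batch_rows


@dataclass
class TrainLog:
    """Per-epoch loss history and the checkpointed epoch."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    checkpointed: list[bool] = field(default_factory=list)
    best_epoch: int | None = None
    best_val_loss: float = math.inf

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(self.n_epochs),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "checkpointed": self.checkpointed,
            }
        )


@dataclass
class FitResult:
    """Bundle returned by :func:`fit`: parameters, log and train-split stats.

    ``validation_bundle`` holds (masked inputs, targets, loss mask) of the
    frozen validation objective so the checkpointed loss can be re-verified:
    ``joint_loss(forward(x, params, spec), t, m, spec) == log.best_val_loss``.
    """

    params: ModelParams
    log: TrainLog
    stats: NormalizationStats
    spec: ModelSpec
    config: TrainConfig
    validation_bundle: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None


def _phi(x: np.ndarray, slope: float, printed: bool) -> np.ndarray:
    neg = np.minimum(x, 0.0)
    pos = np.maximum(x, 0.0)
    return pos - slope * neg if printed else pos + slope * neg


def _phi_grad(x: np.ndarray, slope: float, printed: bool) -> np.ndarray:
    s = -slope if printed else slope
    return np.where(x > 0, 1.0, s)


#: keeps saturated sigmoid outputs strictly inside (0, 1) in float arithmetic
_SIGMOID_EPS = 1e-12


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return np.clip(out, _SIGMOID_EPS, 1.0 - _SIGMOID_EPS)


def init_params(spec: ModelSpec, rng: np.random.Generator) -> ModelParams:
    """Kaiming-uniform initialization sized for the leaky-rectifier gain."""
    gain = math.sqrt(2.0 / (1.0 + spec.leaky_slope**2))
    weights, biases = [], []
    widths = spec.widths
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        bound = gain * math.sqrt(3.0 / fan_in)
        weights.append(rng.uniform(-bound, bound, size=(fan_out, fan_in)))
        b_bound = 1.0 / math.sqrt(fan_in)
        biases.append(rng.uniform(-b_bound, b_bound, size=fan_out))
    return ModelParams(weights, biases)


def _forward_raw(
    x: np.ndarray, params: ModelParams, spec: ModelSpec
) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
    """Forward pass returning output preactivations and per-layer caches."""
    a = np.atleast_2d(np.asarray(x, dtype=float))
    preacts, acts = [], [a]
    n_layers = len(params.weights)
    for l, (w, b) in enumerate(zip(params.weights, params.biases)):
        z = a @ w.T + b
        preacts.append(z)
        if l < n_layers - 1:
            a = _phi(z, spec.leaky_slope, spec.printed_phi)
        else:
            a = z
        acts.append(a)
    return preacts[-1], preacts, acts


def forward(x: np.ndarray, params: ModelParams, spec: ModelSpec) -> np.ndarray:
    """Reconstruct phenotype vectors: h(X~) rowwise.

    ``x`` must already be normalized/encoded with missing entries zero-filled.
    Continuous outputs (columns < C) are raw affine outputs; binary outputs
    are sigmoid-squashed into (0,1).
    """
    z_out, _, _ = _forward_raw(x, params, spec)
    if not np.isfinite(z_out).all():
        raise FloatingPointError("non-finite activations in forward pass")
    y = z_out.copy()
    c = spec.n_continuous
    y[:, c:] = _sigmoid(z_out[:, c:])
    return y if np.asarray(x).ndim == 2 else y[0]


def joint_loss(
    reconstruction: np.ndarray,
    targets: np.ndarray,
    observed_mask: np.ndarray,
    spec: ModelSpec,
) -> float:
    """Summed mixed reconstruction loss over observed cells.

    Squared error on continuous columns, cross-entropy on binary columns
    (predictions must be probabilities strictly inside (0,1), targets 0/1).
    Cells hidden from the input by copy-masking still count whenever they
    were originally observed.
    """
    y = np.atleast_2d(np.asarray(reconstruction, dtype=float))
    t = np.atleast_2d(np.asarray(targets, dtype=float))
    m = np.atleast_2d(np.asarray(observed_mask, dtype=bool))
    c = spec.n_continuous
    yb, tb, mb = y[:, c:], t[:, c:], m[:, c:]
    if ((yb <= 0.0) | (yb >= 1.0))[mb].any():
        raise ValueError("binary predictions must lie strictly in (0, 1)")
    if (~np.isin(tb[mb], (0.0, 1.0))).any():
        raise ValueError("binary targets must be 0 or 1")
    tc, yc, mc = t[:, :c], y[:, :c], m[:, :c]
    cont = np.where(mc, (yc - np.where(mc, tc, 0.0)) ** 2, 0.0).sum()
    tb0 = np.where(mb, tb, 0.0)
    ce = np.where(mb, -(tb0 * np.log(np.where(mb, yb, 0.5))
                        + (1.0 - tb0) * np.log(np.where(mb, 1.0 - yb, 0.5))), 0.0).sum()
    return float(cont + ce)


def encode_inputs(
    data: MaskedPhenotypeMatrix,
    stats: NormalizationStats,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build (model_input, loss_targets, observed_mask) arrays.

    Model input: z-scored continuous values; binary values recoded
    -0.5/+0.5 so the zero fill sits at the neutral point between classes;
    missing entries zero. Loss targets keep binary values on the 0/1 scale
    (cross-entropy) and continuous values z-scored; masked cells are zero
    but excluded by the mask.
    """
    normed = apply_normalization(data, stats, "forward")
    m = data.mask
    c = data.schema.n_continuous
    target = np.where(m, normed.values, 0.0)
    x = target.copy()
    if stats.binary_recode:
        x[:, c:] = np.where(m[:, c:], x[:, c:] - 0.5, 0.0)
    return x, target, m


def loss_and_grads(
    params: ModelParams,
    spec: ModelSpec,
    x: np.ndarray,
    targets: np.ndarray,
    observed_mask: np.ndarray,
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """Joint loss and its analytic gradients for a batch.

    Gradients are of the summed loss; callers scale by 1/batch_rows for
    step-size stability. Output-layer gradients: 2(y - t) for observed
    continuous cells, sigmoid(z) - t for observed binary cells (the
    cross-entropy/sigmoid composition), zero elsewhere.
    """
    x = np.atleast_2d(x)
    t = np.atleast_2d(targets)
    m = np.atleast_2d(observed_mask)
    z_out, preacts, acts = _forward_raw(x, params, spec)
    c = spec.n_continuous
    y = z_out.copy()
    y[:, c:] = _sigmoid(z_out[:, c:])
    loss = joint_loss(y, t, m, spec)

    dz = np.zeros_like(z_out)
    dz[:, :c] = np.where(m[:, :c], 2.0 * (z_out[:, :c] - t[:, :c]), 0.0)
    dz[:, c:] = np.where(m[:, c:], y[:, c:] - t[:, c:], 0.0)

    n_layers = len(params.weights)
    grads_w = [np.empty(0)] * n_layers
    grads_b = [np.empty(0)] * n_layers
    for l in range(n_layers - 1, -1, -1):
        grads_w[l] = dz.T @ acts[l]
        grads_b[l] = dz.sum(axis=0)
        if l > 0:
            da = dz @ params.weights[l]
            dz = da * _phi_grad(preacts[l - 1], spec.leaky_slope, spec.printed_phi)
    return loss, grads_w, grads_b


def fit(
    train: MaskedPhenotypeMatrix,
    config: TrainConfig | None = None,
    spec: ModelSpec | None = None,
) -> FitResult:
    """Train the autoencoder with copy-masking augmentation.

    A validation split is carved from ``train`` (``config.validation_fraction``
    of rows); normalization statistics are fitted on the remaining sub-training
    rows, which also supply the copy-mask pattern source. Each epoch shuffles
    the sub-training rows, applies a fresh copy-mask to each row with
    probability rho, and takes SGD-with-momentum steps per minibatch
    (summed-loss gradients scaled by the number of rows in the batch).
    Validation loss is the joint loss on the validation rows under a
    seed-frozen copy-mask fixed before training, so the checkpoint criterion
    matches the imputation task and is comparable across epochs; parameters
    are checkpointed whenever it improves, and the best checkpoint is
    returned.
    """
    config = config or TrainConfig()
    if train.n_samples == 0:
        raise ValueError("training data is empty")
    if spec is None:
        spec = ModelSpec(
            n_features=train.n_phenotypes, n_continuous=train.schema.n_continuous
        )
    if spec.n_features != train.n_phenotypes or spec.n_continuous != train.schema.n_continuous:
        raise ValueError("spec does not match the training schema")

    ss = np.random.SeedSequence(config.seed)
    rng_split, rng_init, rng_epoch, rng_valmask = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    n = train.n_samples
    n_val = int(round(n * config.validation_fraction))
    perm = rng_split.permutation(n)
    val_idx, sub_idx = np.sort(perm[:n_val]), np.sort(perm[n_val:])
    if len(sub_idx) == 0:
        raise ValueError("validation_fraction leaves no training rows")
    sub = train.take_rows(sub_idx)
    val = train.take_rows(val_idx) if n_val else None

    stats = fit_normalization(sub)
    x_sub, t_sub, m_sub = encode_inputs(sub, stats)

    params = init_params(spec, rng_init)
    log = TrainLog()
    if config.max_epochs == 0:
        return FitResult(params, log, stats, spec, config, None)

    plan = CopyMaskPlan(rho=config.rho, pattern_source=sub.mask, mode=config.mask_mode)

    # frozen validation objective: one copy-mask draw, fixed for all epochs
    if val is not None and val.n_samples > 0:
        x_val, t_val, m_val = encode_inputs(val, stats)
        x_val_in, _ = apply_copy_mask(x_val, val.mask, plan, rng_valmask)
    else:
        x_val_in = t_val = m_val = None

    velocity_w = [np.zeros_like(w) for w in params.weights]
    velocity_b = [np.zeros_like(b) for b in params.biases]
    lr = config.learning_rate
    best_params = params.copy()
    stagnant = 0
    since_best = 0

    for epoch in range(config.max_epochs):
        order = rng_epoch.permutation(len(sub_idx))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            xb, _ = apply_copy_mask(x_sub[batch], sub.mask[batch], plan, rng_epoch)
            loss, gw, gb = loss_and_grads(params, spec, xb, t_sub[batch], m_sub[batch])
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: non-finite loss "
                    f"(last train loss {log.train_loss[-1] if log.train_loss else 'n/a'}, "
                    f"last val loss {log.val_loss[-1] if log.val_loss else 'n/a'})"
                )
            epoch_loss += loss
            scale = _gradient_scale(config.gradient_scaling, len(batch), spec.n_features)
            for l in range(len(params.weights)):
                velocity_w[l] = config.momentum * velocity_w[l] - lr * scale * gw[l]
                velocity_b[l] = config.momentum * velocity_b[l] - lr * scale * gb[l]
                params.weights[l] += velocity_w[l]
                params.biases[l] += velocity_b[l]

        if x_val_in is not None:
            y_val = forward(x_val_in, params, spec)
            vloss = joint_loss(y_val, t_val, m_val, spec)
        else:
            vloss = epoch_loss
        improved = vloss < log.best_val_loss
        log.train_loss.append(epoch_loss)
        log.val_loss.append(float(vloss))
        log.checkpointed.append(bool(improved))
        if improved:
            log.best_val_loss = float(vloss)
            log.best_epoch = epoch
            best_params = params.copy()
            stagnant = 0
            since_best = 0
        else:
            stagnant += 1
            since_best += 1
            if stagnant >= config.scheduler_patience:
                lr *= config.scheduler_factor
                stagnant = 0
            if (
                config.early_stop_patience is not None
                and since_best >= config.early_stop_patience
            ):
                break

    bundle = None if x_val_in is None else (x_val_in, t_val, m_val)
    return FitResult(best_params, log, stats, spec, config, bundle)


def impute(
    data: MaskedPhenotypeMatrix,
    params: ModelParams,
    spec: ModelSpec,
    stats: NormalizationStats,
) -> np.ndarray:
    """Complete a phenotype matrix: X-hat = M * X + (1 - M) * h(X).

    Observed cells are copied verbatim from the input (exact passthrough);
    missing continuous cells are filled on the original scale and missing
    binary cells as probabilities in (0,1).
    """
    if stats.names != data.schema.names:
        raise ValueError("normalization stats do not match data schema")
    if spec.n_features != data.n_phenotypes or spec.n_continuous != data.schema.n_continuous:
        raise ValueError("model spec does not match data schema")
    x, _, _ = encode_inputs(data, stats)
    y = forward(x, params, spec)
    c = spec.n_continuous
    y[:, :c] = y[:, :c] * stats.sd[:c] + stats.mean[:c]
    return np.where(data.mask, data.values, y)


def save_checkpoint(path: str | Path, result: FitResult) -> None:
    """Write a single-archive checkpoint (npz with JSON metadata)."""
    arrays = {}
    for l, (w, b) in enumerate(zip(result.params.weights, result.params.biases)):
        arrays[f"W{l}"] = w
        arrays[f"b{l}"] = b
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "spec": result.spec.to_dict(),
        "config": result.config.to_dict(),
        "stats": {
            "names": list(result.stats.names),
            "mean": [None if np.isnan(m) else m for m in result.stats.mean],
            "sd": [None if np.isnan(s) else s for s in result.stats.sd],
            "binary_recode": result.stats.binary_recode,
        },
        "n_layers": len(result.params.weights),
    }
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[ModelParams, ModelSpec, NormalizationStats]:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["meta"]).decode())
        if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint format {meta['format_version']}")
        n_layers = meta["n_layers"]
        params = ModelParams(
            weights=[archive[f"W{l}"] for l in range(n_layers)],
            biases=[archive[f"b{l}"] for l in range(n_layers)],
        )
    spec = ModelSpec.from_dict(meta["spec"])
    st = meta["stats"]
    stats = NormalizationStats(
        names=tuple(st["names"]),
        mean=np.array([np.nan if m is None else m for m in st["mean"]]),
        sd=np.array([np.nan if s is None else s for s in st["sd"]]),
        binary_recode=st["binary_recode"],
    )
    return params, spec, stats
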