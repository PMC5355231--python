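"""Loss functions and the five-step adversarial-autoencoder training loop.

Each minibatch drives five separate stochastic-gradient updates, in order:

a) the discriminator learns to tell 4-D standard-normal prior samples
   (label 1) from encoded representations (label 0, detached);
b) the encoder learns to make its representations score as prior samples;
c) encoder and decoder jointly minimize the reconstruction cost — the sum
   over the 166 bits of the binary cross-entropy (logloss) plus the squared
   concentration error, averaged over the minibatch;
d) the encoder regresses its dedicated GI latent neuron onto the measured
   growth inhibition (mean squared error);
e) the encoder minimizes the manifold cost: one minus the mean pairwise
   cosine similarity between representations of the same fingerprint
   encoded at concentrations drawn from Normal(dataset LCONC mean,
   dataset LCONC variance).

Every step has its own learning rate and touches only its contracted
parameter group; there is no mixed weighted objective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from chemaae.chem_io import N_BITS
from chemaae.dataset import TrainingSet
from chemaae.model import ModelParams, sigmoid

logger = logging.getLogger(__name__)

EPS = 1e-7

STEP_NAMES = ("discriminator", "confusion", "reconstruction", "gi_regression", "manifold")


class TrainingDiverged(RuntimeError):
    def __init__(self, step: str, value: float):
        super().__init__(f"non-finite loss ({value}) at training step {step!r}")
        self.step = step


@dataclass
class TrainConfig:
    batch_size: int = 64
    epochs: int = 200
    lr_discriminator: float = 0.0025
    lr_confusion: float = 0.012
    lr_reconstruction: float = 0.005
    lr_gi: float = 0.002
    lr_manifold: float = 0.05
    manifold_batch: int = 8
    grad_clip: float = 5.0
    clamp_eps: float = EPS
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size must be >= 1 and epochs >= 0")
        if self.manifold_batch < 2:
            raise ValueError("manifold_batch must be >= 2")
        if not 0 < self.clamp_eps <= 1e-3:
            raise ValueError("clamp_eps must lie in (0, 1e-3]")
        for name in ("lr_discriminator", "lr_confusion", "lr_reconstruction", "lr_gi", "lr_manifold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class TrainLog:
    """One row per epoch: the five losses plus held-out discriminator accuracy."""

    epochs: list[int] = field(default_factory=list)
    d_loss: list[float] = field(default_factory=list)
    g_loss: list[float] = field(default_factory=list)
    recon_loss: list[float] = field(default_factory=list)
    gi_loss: list[float] = field(default_factory=list)
    manifold_loss: list[float] = field(default_factory=list)
    disc_accuracy: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": self.epochs,
                "d_loss": self.d_loss,
                "g_loss": self.g_loss,
                "recon_loss": self.recon_loss,
                "gi_loss": self.gi_loss,
                "manifold_loss": self.manifold_loss,
                "disc_accuracy": self.disc_accuracy,
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(Path(path), sep="\t", index=False)


def _clip_grads(dW: list[np.ndarray], db: list[np.ndarray], max_norm: float) -> None:
    """Scale a step's gradients in place so their global norm is <= max_norm.

    Plain SGD on the adversarial steps can overshoot badly once the
    discriminator saturates; clipping bounds each update without changing
    its direction.
    """
    if max_norm <= 0:
        return
    total = np.sqrt(sum(float((g**2).sum()) for g in dW + db))
    if total > max_norm:
        scale = max_norm / total
        for g in dW:
            g *= scale
        for g in db:
            g *= scale


def _clamp(p: np.ndarray, eps: float = EPS) -> np.ndarray:
    return np.clip(p, eps, 1.0 - eps)


def reconstruction_loss(
    probs: np.ndarray,
    lconc_pred: np.ndarray,
    target_bits: np.ndarray,
    target_lconc: np.ndarray,
    eps: float = EPS,
) -> float:
    """Sum over bits of logloss plus squared LCONC error, averaged over the batch."""
    p = _clamp(np.atleast_2d(probs), eps)
    b = np.atleast_2d(target_bits).astype(np.float64)
    if p.shape != b.shape or p.shape[1] != N_BITS:
        raise ValueError("probability/bit shapes must match and have 166 columns")
    bce = -(b * np.log(p) + (1.0 - b) * np.log(1.0 - p)).sum(axis=1)
    mse = (np.atleast_1d(lconc_pred) - np.atleast_1d(target_lconc)) ** 2
    loss = float(np.mean(bce + mse))
    if not np.isfinite(loss):
        raise TrainingDiverged("reconstruction", loss)
    return loss


def gi_regression_loss(gi_pred: np.ndarray, target_gi: np.ndarray) -> float:
    """Mean squared error between the GI latent neuron and the measured GI."""
    err = np.atleast_1d(gi_pred) - np.atleast_1d(target_gi)
    return float(np.mean(err**2))


def _cosine_stats(reps: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean pairwise cosine similarity within each group, plus gradient wrt reps.

    ``reps`` has shape (G, M, R): G fingerprints, each encoded at M
    concentrations. Zero-norm representations contribute similarity 0.
    """
    G, M, _ = reps.shape
    norms = np.linalg.norm(reps, axis=2, keepdims=True)
    degenerate = norms[..., 0] <= 0.0
    if degenerate.any():
        logger.warning("manifold step: %d zero-norm representations, pairs scored 0", int(degenerate.sum()))
    safe = np.maximum(norms, 1e-12)
    U = reps / safe
    U[degenerate] = 0.0
    S = U @ np.transpose(U, (0, 2, 1))
    diag = np.einsum("gmm->gm", S)
    mean_sim = float((S.sum(axis=(1, 2)) - diag.sum(axis=1)).mean() / (M * (M - 1)))
    # d/dr_i of the ordered-pair mean: pairs (i,j) and (j,i) both contribute.
    row_sums = S.sum(axis=2) - diag  # sum_{j != i} s_ij
    u_sums = U.sum(axis=1, keepdims=True) - U  # sum_{j != i} u_j
    grad = (u_sums - row_sums[..., None] * U) / safe
    grad *= 2.0 / (G * M * (M - 1))
    grad[degenerate] = 0.0
    return mean_sim, grad


def manifold_loss_from_representations(reps: np.ndarray) -> float:
    """1 - mean pairwise cosine similarity of an (M, R) stack of representations.

    0 for identical (parallel) vectors, 1 for orthogonal pairs, 2 for
    antiparallel pairs.
    """
    reps = np.atleast_2d(np.asarray(reps, dtype=np.float64))
    if reps.shape[0] < 2:
        raise ValueError("need at least two representations")
    mean_sim, _ = _cosine_stats(reps[None, :, :])
    return 1.0 - mean_sim


def manifold_loss(params: ModelParams, fingerprint: np.ndarray, lconc_draws: np.ndarray) -> float:
    """1 - mean pairwise cosine similarity of one fingerprint's representations
    across the drawn concentrations. 0 when all representations are parallel."""
    fp = np.asarray(fingerprint).reshape(1, N_BITS)
    draws = np.asarray(lconc_draws, dtype=np.float64).ravel()
    if draws.size < 2:
        raise ValueError("manifold loss needs at least two concentration draws")
    from chemaae.model import encode

    _, reps = encode(params, np.repeat(fp, draws.size, axis=0), draws)
    mean_sim, _ = _cosine_stats(reps[None, :, :])
    return 1.0 - mean_sim


def adversarial_losses(
    params: ModelParams, representations: np.ndarray, prior_samples: np.ndarray, eps: float = EPS
) -> tuple[float, float]:
    """(d_loss, g_loss) binary cross-entropies with prior labelled 1, encoded 0."""
    from chemaae.model import discriminate

    s_prior = _clamp(discriminate(params, prior_samples), eps)
    s_enc = _clamp(discriminate(params, representations), eps)
    d_loss = float(-(np.log(s_prior).mean() + np.log(1.0 - s_enc).mean()) / 2.0)
    g_loss = float(-np.log(s_enc).mean())
    if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
        raise TrainingDiverged("adversarial", d_loss)
    return d_loss, g_loss


def _bce_logit_grad(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean BCE of sigmoid(logits) against labels, and its gradient wrt logits."""
    p = sigmoid(logits)
    pc = _clamp(p)
    loss = float(-np.mean(labels * np.log(pc) + (1.0 - labels) * np.log(1.0 - pc)))
    return loss, (p - labels) / logits.size


def train_iteration(
    params: ModelParams,
    batch_X: np.ndarray,
    batch_lconc: np.ndarray,
    batch_gi: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Run the five updates (a-e) on one minibatch, in place.

    Returns the five loss values measured before each respective update.
    Raises :class:`TrainingDiverged` naming the step if a loss goes non-finite.
    """
    if params.norm_stats is None:
        raise ValueError("params.norm_stats required for the manifold step")
    B = batch_X.shape[0]
    repr_width = params.config.latent_width - 1
    x_in = np.hstack([batch_X.astype(np.float64), np.asarray(batch_lconc, dtype=np.float64)[:, None]])
    losses: dict[str, float] = {}

    # (a) discriminator: prior = 1, encoded (detached) = 0
    code, _ = params.encoder.forward(x_in)
    reps = code[:, 1:]
    prior = rng.standard_normal((B, repr_width))
    d_in = np.vstack([prior, reps])
    labels = np.concatenate([np.ones(B), np.zeros(B)])
    logit, d_cache = params.discriminator.forward(d_in)
    d_loss, g_logit = _bce_logit_grad(logit[:, 0], labels)
    _check_finite("discriminator", d_loss)
    dW, db, _ = params.discriminator.backward(d_cache, g_logit[:, None])
    _clip_grads(dW, db, config.grad_clip)
    params.discriminator.sgd_step(dW, db, config.lr_discriminator)
    losses["d_loss"] = d_loss

    # (b) encoder confusion: encoded representations should score as prior (1)
    code, e_cache = params.encoder.forward(x_in)
    logit, d_cache = params.discriminator.forward(code[:, 1:])
    g_loss, g_logit = _bce_logit_grad(logit[:, 0], np.ones(B))
    _check_finite("confusion", g_loss)
    _, _, g_rep = params.discriminator.backward(d_cache, g_logit[:, None])
    g_code = np.zeros_like(code)
    g_code[:, 1:] = g_rep
    dW, db, _ = params.encoder.backward(e_cache, g_code)
    _clip_grads(dW, db, config.grad_clip)
    params.encoder.sgd_step(dW, db, config.lr_confusion)
    losses["g_loss"] = g_loss

    # (c) joint reconstruction: logloss over bits + squared LCONC error
    code, e_cache = params.encoder.forward(x_in)
    out, dec_cache = params.decoder.forward(code)
    probs = sigmoid(out[:, :N_BITS])
    lconc_pred = out[:, N_BITS]
    recon = reconstruction_loss(probs, lconc_pred, batch_X, batch_lconc, config.clamp_eps)
    g_out = np.empty_like(out)
    g_out[:, :N_BITS] = (probs - batch_X) / B
    g_out[:, N_BITS] = 2.0 * (lconc_pred - batch_lconc) / B
    dWd, dbd, g_code = params.decoder.backward(dec_cache, g_out)
    dWe, dbe, _ = params.encoder.backward(e_cache, g_code)
    _clip_grads(dWd, dbd, config.grad_clip)
    _clip_grads(dWe, dbe, config.grad_clip)
    params.decoder.sgd_step(dWd, dbd, config.lr_reconstruction)
    params.encoder.sgd_step(dWe, dbe, config.lr_reconstruction)
    losses["recon_loss"] = recon

    # (d) GI regression on the dedicated latent neuron
    code, e_cache = params.encoder.forward(x_in)
    gi_loss = gi_regression_loss(code[:, 0], batch_gi)
    _check_finite("gi_regression", gi_loss)
    g_code = np.zeros_like(code)
    g_code[:, 0] = 2.0 * (code[:, 0] - batch_gi) / B
    dW, db, _ = params.encoder.backward(e_cache, g_code)
    _clip_grads(dW, db, config.grad_clip)
    params.encoder.sgd_step(dW, db, config.lr_gi)
    losses["gi_loss"] = gi_loss

    # (e) manifold: same fingerprint, concentrations ~ N(dataset mean, var)
    M = config.manifold_batch
    mu = params.norm_stats.lconc_mean
    sd = np.sqrt(params.norm_stats.lconc_var)
    draws = rng.normal(mu, sd, size=(B, M))
    x_rep = np.repeat(batch_X.astype(np.float64), M, axis=0)
    x_man = np.hstack([x_rep, draws.reshape(-1, 1)])
    code, e_cache = params.encoder.forward(x_man)
    reps = code[:, 1:].reshape(B, M, repr_width)
    mean_sim, g_reps = _cosine_stats(reps)
    man_loss = 1.0 - mean_sim
    _check_finite("manifold", man_loss)
    g_code = np.zeros_like(code)
    g_code[:, 1:] = -g_reps.reshape(B * M, repr_width)  # minimize 1 - similarity
    dW, db, _ = params.encoder.backward(e_cache, g_code)
    _clip_grads(dW, db, config.grad_clip)
    params.encoder.sgd_step(dW, db, config.lr_manifold)
    losses["manifold_loss"] = man_loss

    return losses


def _check_finite(step: str, value: float) -> None:
    if not np.isfinite(value):
        raise TrainingDiverged(step, value)


def discriminator_accuracy(params: ModelParams, X: np.ndarray, lconc: np.ndarray, rng: np.random.Generator) -> float:
    """Held-out accuracy at threshold 0.5 on prior (label 1) vs encoded (label 0)."""
    from chemaae.model import discriminate, encode

    _, reps = encode(params, X, lconc)
    prior = rng.standard_normal(reps.shape)
    s_prior = discriminate(params, prior)
    s_enc = discriminate(params, reps)
    return float(((s_prior >= 0.5).sum() + (s_enc < 0.5).sum()) / (2 * len(X)))


def fit(
    training_set: TrainingSet,
    params: ModelParams,
    config: TrainConfig | None = None,
) -> tuple[ModelParams, TrainLog]:
    """Train in place for ``config.epochs`` epochs of shuffled minibatches.

    A ``val_fraction`` tail of a seeded permutation is held out and used only
    for the per-epoch discriminator-accuracy diagnostic. With ``epochs=0``
    the parameters are returned untouched.
    """
    config = config or TrainConfig()
    params.norm_stats = training_set.norm_stats
    rng = np.random.default_rng(config.seed)
    n = len(training_set)
    perm = rng.permutation(n)
    n_val = int(round(n * config.val_fraction))
    val_idx, train_idx = perm[n - n_val :], perm[: n - n_val]
    X, lconc, gi = training_set.X, training_set.lconc, training_set.gi
    log = TrainLog()

    for epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        sums = dict.fromkeys(("d_loss", "g_loss", "recon_loss", "gi_loss", "manifold_loss"), 0.0)
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            if len(idx) < 2:
                continue  # manifold/adversarial terms need at least a pair
            losses = train_iteration(params, X[idx], lconc[idx], gi[idx], config, rng)
            for k, v in losses.items():
                sums[k] += v
            n_batches += 1
        if n_batches == 0:
            raise ValueError("training set too small for the configured batch size")
        if n_val >= 2:
            acc = discriminator_accuracy(params, X[val_idx], lconc[val_idx], rng)
        else:
            acc = float("nan")
        log.epochs.append(epoch)
        for k in sums:
            getattr(log, k).append(sums[k] / n_batches)
        log.disc_accuracy.append(acc)
        if epoch % 50 == 0 or epoch == config.epochs - 1:
            logger.info(
                "epoch %d: recon=%.3f gi=%.1f manifold=%.4f d=%.3f g=%.3f acc=%.2f",
                epoch, sums["recon_loss"] / n_batches, sums["gi_loss"] / n_batches,
                sums["manifold_loss"] / n_batches, sums["d_loss"] / n_batches,
                sums["g_loss"] / n_batches, acc,
            )
    return params, log
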