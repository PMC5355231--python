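"""Encoder, decoder and discriminator networks of the adversarial autoencoder.

Architecture (defaults):

* encoder  167 -> 128 -> 64 -> 5   (166 fingerprint bits + 1 LCONC neuron in;
  latent = 1 GI neuron + 4-dim representation out, both linear)
* decoder  5 -> 64 -> 128 -> 167   (166 bit logits -> logistic probabilities,
  plus 1 linear LCONC output)
* discriminator  4 -> 64 -> 64 -> 1 (logistic score that a representation
  came from the prior; the GI neuron never reaches it)

Hidden units are leaky rectifiers. All forward/backward passes are plain
NumPy; layers cache activations so the training module can drive exact
gradient updates for each of the five training steps separately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from chemaae.chem_io import N_BITS
from chemaae.dataset import NormStats

LATENT_WIDTH = 5
REPR_WIDTH = 4
LEAKY_SLOPE = 0.1


@dataclass(frozen=True)
class ModelConfig:
    encoder_widths: tuple[int, ...] = (128, 64)
    decoder_widths: tuple[int, ...] = (64, 128)
    latent_width: int = LATENT_WIDTH
    discriminator_widths: tuple[int, ...] = (64, 64)
    leaky_slope: float = LEAKY_SLOPE
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "encoder_widths": list(self.encoder_widths),
            "decoder_widths": list(self.decoder_widths),
            "latent_width": self.latent_width,
            "discriminator_widths": list(self.discriminator_widths),
            "leaky_slope": self.leaky_slope,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            encoder_widths=tuple(d["encoder_widths"]),
            decoder_widths=tuple(d["decoder_widths"]),
            latent_width=int(d["latent_width"]),
            discriminator_widths=tuple(d["discriminator_widths"]),
            leaky_slope=float(d["leaky_slope"]),
            seed=int(d["seed"]),
        )


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class MLP:
    """Fully connected stack with leaky-rectifier hidden units and linear output.

    ``forward`` returns the linear output and a cache; ``backward`` consumes
    the cache and the gradient at the output, accumulates parameter
    gradients, and returns the gradient at the input.
    """

    def __init__(self, widths: Sequence[int], rng: np.random.Generator, leaky_slope: float = LEAKY_SLOPE):
        self.widths = tuple(widths)
        self.leaky_slope = leaky_slope
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for n_in, n_out in zip(widths[:-1], widths[1:]):
            # fan-in scaled init, suited to rectifier hidden units
            self.W.append(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)))
            self.b.append(np.zeros(n_out))

    @property
    def n_layers(self) -> int:
        return len(self.W)

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        x = np.asarray(x, dtype=np.float64)
        cache = [x]
        for i in range(self.n_layers):
            z = cache[-1] @ self.W[i] + self.b[i]
            if i < self.n_layers - 1:
                z = np.where(z > 0, z, self.leaky_slope * z)
            cache.append(z)
        return cache[-1], cache

    def backward(self, cache: list[np.ndarray], grad_out: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
        """Return (dW list, db list, gradient wrt the input batch)."""
        g = np.asarray(grad_out, dtype=np.float64)
        dW = [np.empty(0)] * self.n_layers
        db = [np.empty(0)] * self.n_layers
        for i in range(self.n_layers - 1, -1, -1):
            a_in = cache[i]
            dW[i] = a_in.T @ g
            db[i] = g.sum(axis=0)
            g = g @ self.W[i].T
            if i > 0:
                # cache[i] holds the post-activation of layer i-1
                g = g * np.where(cache[i] > 0, 1.0, self.leaky_slope)
        return dW, db, g

    def sgd_step(self, dW: list[np.ndarray], db: list[np.ndarray], lr: float) -> None:
        for i in range(self.n_layers):
            self.W[i] -= lr * dW[i]
            self.b[i] -= lr * db[i]

    def params_flat(self) -> np.ndarray:
        return np.concatenate([w.ravel() for w in self.W] + [b.ravel() for b in self.b])


@dataclass
class ModelParams:
    """All trainable weights plus the config and dataset moments they were built with."""

    config: ModelConfig
    encoder: MLP
    decoder: MLP
    discriminator: MLP
    norm_stats: NormStats | None = None

    def snapshot(self) -> dict[str, np.ndarray]:
        """Flat copies of each network's parameters (for step-isolation audits)."""
        return {
            "encoder": self.encoder.params_flat().copy(),
            "decoder": self.decoder.params_flat().copy(),
            "discriminator": self.discriminator.params_flat().copy(),
        }

    def save(self, path: str | Path) -> None:
        arrays: dict[str, np.ndarray] = {}
        for name, net in (("enc", self.encoder), ("dec", self.decoder), ("dis", self.discriminator)):
            for i, (w, b) in enumerate(zip(net.W, net.b)):
                arrays[f"{name}_W{i}"] = w
                arrays[f"{name}_b{i}"] = b
        meta = {
            "config": self.config.to_dict(),
            "norm_stats": self.norm_stats.to_dict() if self.norm_stats else None,
        }
        np.savez_compressed(Path(path), meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        with np.load(Path(path)) as data:
            meta = json.loads(str(data["meta"]))
            config = ModelConfig.from_dict(meta["config"])
            params = init_model(config)
            for name, net in (("enc", params.encoder), ("dec", params.decoder), ("dis", params.discriminator)):
                for i in range(net.n_layers):
                    net.W[i] = data[f"{name}_W{i}"]
                    net.b[i] = data[f"{name}_b{i}"]
            if meta["norm_stats"] is not None:
                params.norm_stats = NormStats(**meta["norm_stats"])
            return params


def init_model(config: ModelConfig | None = None, norm_stats: NormStats | None = None) -> ModelParams:
    """Build the three networks with seeded fan-in initialization."""
    config = config or ModelConfig()
    if config.latent_width != LATENT_WIDTH:
        import logging

        logging.getLogger(__name__).warning(
            "latent width %d differs from the reference architecture (5)", config.latent_width
        )
    rng = np.random.default_rng(config.seed)
    repr_width = config.latent_width - 1
    encoder = MLP((N_BITS + 1, *config.encoder_widths, config.latent_width), rng, config.leaky_slope)
    decoder = MLP((config.latent_width, *config.decoder_widths, N_BITS + 1), rng, config.leaky_slope)
    discriminator = MLP((repr_width, *config.discriminator_widths, 1), rng, config.leaky_slope)
    return ModelParams(config=config, encoder=encoder, decoder=decoder,
                       discriminator=discriminator, norm_stats=norm_stats)


def _encoder_input(fingerprints: np.ndarray, lconc: np.ndarray) -> np.ndarray:
    fp = np.atleast_2d(np.asarray(fingerprints))
    if fp.shape[1] != N_BITS:
        raise ValueError(f"fingerprints must have {N_BITS} columns")
    if not np.isin(fp, (0, 1)).all():
        raise ValueError("fingerprint inputs must be binary")
    lc = np.atleast_1d(np.asarray(lconc, dtype=np.float64))
    if lc.shape[0] != fp.shape[0]:
        raise ValueError("fingerprint/lconc batch sizes differ")
    return np.hstack([fp.astype(np.float64), lc[:, None]])


def encode(params: ModelParams, fingerprints: np.ndarray, lconc: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
    """Map (fingerprint, LCONC) batches to latent codes.

    Returns ``(gi, representation)`` where ``gi`` has shape (N,) and
    ``representation`` has shape (N, 4). Both latent heads are linear.
    """
    if np.isscalar(lconc):
        lconc = np.full(np.atleast_2d(fingerprints).shape[0], float(lconc))
    code, _ = params.encoder.forward(_encoder_input(fingerprints, lconc))
    return code[:, 0], code[:, 1:]


def decode(params: ModelParams, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map latent codes to (probs, lconc): 166 logistic probabilities + linear LCONC.

    Probabilities are strictly inside (0, 1) for finite weights.
    """
    codes = np.atleast_2d(np.asarray(codes, dtype=np.float64))
    if codes.shape[1] != params.config.latent_width:
        raise ValueError(f"codes must have width {params.config.latent_width}")
    out, _ = params.decoder.forward(codes)
    return sigmoid(out[:, :N_BITS]), out[:, N_BITS]


def discriminate(params: ModelParams, representations: np.ndarray) -> np.ndarray:
    """Logistic score in (0, 1) that each 4-vector came from the prior."""
    reps = np.atleast_2d(np.asarray(representations, dtype=np.float64))
    if reps.shape[1] != params.config.latent_width - 1:
        raise ValueError(
            f"discriminator input must have width {params.config.latent_width - 1} "
            "(the GI neuron is never discriminated)"
        )
    logit, _ = params.discriminator.forward(reps)
    return sigmoid(logit[:, 0])


def latent_codes(gi: np.ndarray, representations: np.ndarray) -> np.ndarray:
    """Assemble (N, 5) latent matrices from the (gi, representation) split."""
    gi = np.atleast_1d(np.asarray(gi, dtype=np.float64))
    reps = np.atleast_2d(np.asarray(representations, dtype=np.float64))
    return np.hstack([gi[:, None], reps])
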