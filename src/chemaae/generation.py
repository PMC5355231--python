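"""Prior sampling, decoding and concentration filtering of generated profiles.

The generation protocol samples latent codes whose GI neuron follows a
chosen normal (default N(5, 1)) and whose 4-dim representation follows the
4-D standard normal the discriminator imposed during training, decodes each
code into 166 Bernoulli probabilities plus a concentration, and keeps only
profiles whose decoded LCONC falls strictly below a log10-molar threshold
(default -5.0, i.e. concentrations below 10 uM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from chemaae.chem_io import N_BITS
from chemaae.model import ModelParams, decode, latent_codes

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PriorSpec:
    n_samples: int = 640
    gi_mean: float = 5.0
    gi_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.gi_sd <= 0:
            raise ValueError("gi_sd must be positive")


@dataclass
class GeneratedProfiles:
    """Decoded profiles: per-bit probabilities, decoded LCONC, original sample index."""

    probs: np.ndarray  # (N, 166), strictly inside (0, 1)
    lconc: np.ndarray  # (N,)
    indices: np.ndarray  # (N,) original sample indices

    def __len__(self) -> int:
        return self.probs.shape[0]

    def save(self, path: str | Path) -> None:
        """Delimited text: index, decoded lconc, 166 probabilities at 6 decimals."""
        with open(Path(path), "w") as fh:
            fh.write("index\tlconc\t" + "\t".join(f"p{i}" for i in range(1, N_BITS + 1)) + "\n")
            for idx, lc, row in zip(self.indices, self.lconc, self.probs):
                fh.write(f"{idx}\t{lc:.6f}\t" + "\t".join(f"{p:.6f}" for p in row) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "GeneratedProfiles":
        import warnings

        with warnings.catch_warnings():
            # an empty profile table (nothing passed the filter) is valid
            warnings.simplefilter("ignore", UserWarning)
            data = np.loadtxt(Path(path), skiprows=1, ndmin=2)
        if data.size == 0:
            data = data.reshape(0, N_BITS + 2)
        return cls(
            probs=data[:, 2:], lconc=data[:, 1], indices=data[:, 0].astype(int)
        )


def sample_prior(spec: PriorSpec, repr_width: int = 4) -> np.ndarray:
    """Draw ``n_samples`` latent codes: GI ~ N(gi_mean, gi_sd^2), representation
    ~ standard normal. Returns an (N, 1 + repr_width) matrix, seeded."""
    rng = np.random.default_rng(spec.seed)
    gi = rng.normal(spec.gi_mean, spec.gi_sd, size=spec.n_samples)
    reps = rng.standard_normal((spec.n_samples, repr_width))
    return latent_codes(gi, reps)


def generate_profiles(params: ModelParams, codes: np.ndarray) -> GeneratedProfiles:
    """Decode latent codes into probability profiles, order preserved."""
    codes = np.atleast_2d(codes)
    probs, lconc = decode(params, codes)
    return GeneratedProfiles(probs=probs, lconc=lconc, indices=np.arange(codes.shape[0]))


def filter_by_lconc(profiles: GeneratedProfiles, threshold: float = -5.0) -> GeneratedProfiles:
    """Keep profiles with decoded LCONC strictly below ``threshold`` (boundary excluded).

    Order and original sample indices are preserved; an empty result is
    valid and logged as a warning.
    """
    keep = profiles.lconc < threshold
    if not keep.any():
        logger.warning("no generated profile has LCONC < %.3f", threshold)
    return GeneratedProfiles(
        probs=profiles.probs[keep], lconc=profiles.lconc[keep], indices=profiles.indices[keep]
    )
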