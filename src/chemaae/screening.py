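"""Bernoulli-likelihood screening of fingerprint libraries against profiles.

Each generated profile is a vector of 166 per-bit probabilities; a library
fingerprint b is scored by the independent-Bernoulli log-likelihood
``sum_i b_i ln p_i + (1 - b_i) ln(1 - p_i)`` (higher = better match). The
library is streamed in chunks so arbitrarily large collections never need
to fit in memory; all profiles are scored in a single pass. Ties are broken
by library order (first occurrence wins).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from chemaae.chem_io import N_BITS, stream_fingerprint_matrix

logger = logging.getLogger(__name__)

EPS = 1e-7


@dataclass(frozen=True)
class ScreenHit:
    compound_id: str
    log_likelihood: float
    rank: int
    profile_index: int


def bernoulli_loglik(probs: np.ndarray, bits: np.ndarray, eps: float = EPS) -> float:
    """Log-likelihood of one binary fingerprint under one probability profile."""
    p = np.clip(np.asarray(probs, dtype=np.float64), eps, 1.0 - eps)
    b = np.asarray(bits, dtype=np.float64)
    if p.shape != (N_BITS,) or b.shape != (N_BITS,):
        raise ValueError(f"probs and bits must both have length {N_BITS}")
    return float(b @ np.log(p) + (1.0 - b) @ np.log(1.0 - p))


def _loglik_matrix(chunk_bits: np.ndarray, probs: np.ndarray, eps: float = EPS) -> np.ndarray:
    """(C, P) log-likelihoods of C fingerprints under P profiles."""
    p = np.clip(probs, eps, 1.0 - eps)
    log_p = np.log(p)
    log_q = np.log(1.0 - p)
    return chunk_bits.astype(np.float64) @ (log_p - log_q).T + log_q.sum(axis=1)


def screen_library(
    probs: np.ndarray,
    library: Iterable[tuple[Sequence[str], np.ndarray]],
    k: int = 10,
) -> list[list[ScreenHit]]:
    """Top-``k`` hits per profile over a chunk-streamed library.

    ``probs`` is (P, 166) — one row per profile; ``library`` yields
    ``(ids, bits)`` chunks (e.g. from :func:`chemaae.chem_io.stream_fingerprint_matrix`).
    Only O(P * k) candidates are retained between chunks, so the result is
    identical for any chunk size. If the library holds fewer than ``k``
    compounds, all are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    n_profiles = probs.shape[0]
    cand_scores = [np.empty(0)] * n_profiles
    cand_seq = [np.empty(0, dtype=np.int64)] * n_profiles
    cand_ids: list[list[str]] = [[] for _ in range(n_profiles)]
    offset = 0
    for ids, bits in library:
        scores = _loglik_matrix(bits, probs)  # (C, P)
        seq = np.arange(offset, offset + len(ids), dtype=np.int64)
        offset += len(ids)
        for j in range(n_profiles):
            s = np.concatenate([cand_scores[j], scores[:, j]])
            q = np.concatenate([cand_seq[j], seq])
            names = cand_ids[j] + list(ids)
            # stable selection: highest score first, earlier library position on ties
            order = np.lexsort((q, -s))[:k]
            cand_scores[j] = s[order]
            cand_seq[j] = q[order]
            cand_ids[j] = [names[i] for i in order]
    if offset == 0:
        raise ValueError("empty library")
    if offset < k:
        logger.warning("library holds %d compounds, fewer than k=%d; returning all", offset, k)
    return [
        [
            ScreenHit(compound_id=cid, log_likelihood=float(s), rank=r + 1, profile_index=j)
            for r, (cid, s) in enumerate(zip(cand_ids[j], cand_scores[j]))
        ]
        for j in range(n_profiles)
    ]


def screen_library_file(
    probs: np.ndarray, library_path: str | Path, k: int = 10, chunk_size: int = 4096
) -> list[list[ScreenHit]]:
    """Screen against a text fingerprint-matrix file, streamed."""
    return screen_library(probs, stream_fingerprint_matrix(library_path, chunk_size), k=k)


@dataclass(frozen=True)
class UniqueHit:
    compound_id: str
    best_log_likelihood: float
    best_rank: int
    n_profiles: int


def collect_unique_hits(hit_lists: Sequence[Sequence[ScreenHit]]) -> list[UniqueHit]:
    """Deduplicate hits across profiles by compound id.

    Records the best (highest) log-likelihood, the best (lowest) rank, and
    how many profiles selected each compound. Sorted by best log-likelihood
    descending, then id.
    """
    best: dict[str, UniqueHit] = {}
    for hits in hit_lists:
        for h in hits:
            prev = best.get(h.compound_id)
            if prev is None:
                best[h.compound_id] = UniqueHit(h.compound_id, h.log_likelihood, h.rank, 1)
            else:
                best[h.compound_id] = UniqueHit(
                    h.compound_id,
                    max(prev.best_log_likelihood, h.log_likelihood),
                    min(prev.best_rank, h.rank),
                    prev.n_profiles + 1,
                )
    return sorted(best.values(), key=lambda u: (-u.best_log_likelihood, u.compound_id))


def hits_to_frame(hit_lists: Sequence[Sequence[ScreenHit]]) -> pd.DataFrame:
    rows = [
        (h.profile_index, h.rank, h.compound_id, h.log_likelihood)
        for hits in hit_lists
        for h in hits
    ]
    return pd.DataFrame(rows, columns=["profile_index", "rank", "compound_id", "log_likelihood"])


def unique_hits_to_frame(unique: Sequence[UniqueHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(u.compound_id, u.best_log_likelihood, u.best_rank, u.n_profiles) for u in unique],
        columns=["compound_id", "best_log_likelihood", "best_rank", "n_profiles"],
    )
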