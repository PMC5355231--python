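"""Training-set assembly from dose-response tables, and the synthetic benchmark.

A training row is one assay record — one (compound, concentration) pair —
joined to that compound's fingerprint, so the same fingerprint legitimately
appears at several concentrations. ``norm_stats`` records the mean/variance
of the raw LCONC and GI columns; the concentration moments drive the
manifold training step, which encodes a fixed fingerprint at concentrations
drawn from Normal(lconc_mean, lconc_var).

The synthetic generator emulates a single-cell-line dose-response release:
fingerprints are noisy copies of a few prototype bit patterns, LCONC is
normal on the log10-molar scale, and GI is a known linear function of
fingerprint bits plus a dose slope plus Gaussian noise. The generating
ground truth is returned so recovery tests can verify the pipeline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from chemaae.chem_io import N_BITS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssayRecord:
    """One dose-response measurement.

    ``lconc`` is log10 molar concentration; ``gi`` is growth-inhibition
    percent, where negative values indicate net reduction of tumor cells.
    """

    compound_id: str
    lconc: float
    gi: float


@dataclass
class NormStats:
    lconc_mean: float
    lconc_var: float
    gi_mean: float
    gi_var: float

    def to_dict(self) -> dict[str, float]:
        return {
            "lconc_mean": self.lconc_mean,
            "lconc_var": self.lconc_var,
            "gi_mean": self.gi_mean,
            "gi_var": self.gi_var,
        }

    @classmethod
    def from_columns(cls, lconc: np.ndarray, gi: np.ndarray) -> "NormStats":
        return cls(
            lconc_mean=float(np.mean(lconc)),
            lconc_var=float(np.var(lconc)),
            gi_mean=float(np.mean(gi)),
            gi_var=float(np.var(gi)),
        )


@dataclass
class TrainingSet:
    """Aligned arrays: N x 166 binary fingerprints, LCONC, GI, compound ids."""

    X: np.ndarray
    lconc: np.ndarray
    gi: np.ndarray
    ids: np.ndarray
    norm_stats: NormStats

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.uint8)
        self.lconc = np.asarray(self.lconc, dtype=np.float64)
        self.gi = np.asarray(self.gi, dtype=np.float64)
        self.ids = np.asarray(self.ids, dtype=str)
        n = self.X.shape[0]
        if self.X.ndim != 2 or self.X.shape[1] != N_BITS:
            raise ValueError(f"X must be N x {N_BITS}")
        if not (len(self.lconc) == len(self.gi) == len(self.ids) == n):
            raise ValueError("all training-set arrays must share length N")
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("fingerprint rows must be binary")

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, idx: np.ndarray | slice) -> "TrainingSet":
        """Row subset with norm_stats recomputed from the retained rows."""
        X, lconc, gi, ids = self.X[idx], self.lconc[idx], self.gi[idx], self.ids[idx]
        return TrainingSet(X=X, lconc=lconc, gi=gi, ids=ids,
                           norm_stats=NormStats.from_columns(lconc, gi))

    @property
    def n_compounds(self) -> int:
        """Distinct compounds (rows may repeat a compound at several doses)."""
        return len(np.unique(self.ids))

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            Path(path),
            X=self.X,
            lconc=self.lconc,
            gi=self.gi,
            ids=self.ids,
            norm_stats=json.dumps(self.norm_stats.to_dict()),
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainingSet":
        with np.load(Path(path)) as data:
            stats = NormStats(**json.loads(str(data["norm_stats"])))
            return cls(X=data["X"], lconc=data["lconc"], gi=data["gi"], ids=data["ids"], norm_stats=stats)


def load_dose_response(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    cell_line: str | None = None,
    sep: str | None = None,
) -> tuple[list[AssayRecord], int]:
    """Load assay records from a delimited table.

    ``column_map`` maps the roles ``id``, ``lconc``, ``gi`` (and optionally
    ``cell_line``) to column names in the file. Rows with non-finite LCONC
    or GI are dropped and counted; the cell-line filter, if requested, is
    applied first. Returns ``(records, n_dropped)``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dose-response table not found: {path}")
    column_map = dict(column_map or {"id": "id", "lconc": "lconc", "gi": "gi"})
    df = pd.read_csv(path, sep=sep, engine="python")
    required = ["id", "lconc", "gi"] + (["cell_line"] if cell_line is not None else [])
    for role in required:
        col = column_map.get(role)
        if col is None or col not in df.columns:
            raise ValueError(f"required column for role {role!r} ({col!r}) missing from {path}")
    if cell_line is not None:
        df = df[df[column_map["cell_line"]].astype(str) == cell_line]
    n_in = len(df)
    lconc = pd.to_numeric(df[column_map["lconc"]], errors="coerce")
    gi = pd.to_numeric(df[column_map["gi"]], errors="coerce")
    keep = np.isfinite(lconc.to_numpy(dtype=float, na_value=np.nan)) & np.isfinite(
        gi.to_numpy(dtype=float, na_value=np.nan)
    )
    n_dropped = int(n_in - keep.sum())
    records = [
        AssayRecord(compound_id=str(i), lconc=float(c), gi=float(g))
        for i, c, g in zip(df[column_map["id"]][keep], lconc[keep], gi[keep])
    ]
    if not records:
        raise ValueError(f"no usable dose-response records in {path}")
    if n_dropped:
        logger.info("dropped %d rows with non-finite LCONC/GI", n_dropped)
    n_compounds = len({r.compound_id for r in records})
    logger.info("loaded %d assay rows covering %d distinct compounds", len(records), n_compounds)
    return records, n_dropped


def build_training_set(
    records: Sequence[AssayRecord], fingerprints: Mapping[str, np.ndarray]
) -> tuple[TrainingSet, int]:
    """Join assay records to fingerprints: one training row per record.

    Records whose compound id has no fingerprint are dropped and counted.
    Returns ``(training_set, n_dropped)``.
    """
    rows, lconc, gi, ids = [], [], [], []
    n_dropped = 0
    for rec in records:
        fp = fingerprints.get(rec.compound_id)
        if fp is None:
            n_dropped += 1
            continue
        rows.append(np.asarray(fp, dtype=np.uint8))
        lconc.append(rec.lconc)
        gi.append(rec.gi)
        ids.append(rec.compound_id)
    if not rows:
        raise ValueError("empty join: no assay record has a matching fingerprint")
    if n_dropped:
        logger.info("dropped %d records without a fingerprint", n_dropped)
    X = np.vstack(rows)
    lconc_arr = np.asarray(lconc)
    gi_arr = np.asarray(gi)
    ts = TrainingSet(
        X=X, lconc=lconc_arr, gi=gi_arr, ids=np.asarray(ids),
        norm_stats=NormStats.from_columns(lconc_arr, gi_arr),
    )
    return ts, n_dropped


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic dose-response benchmark.

    Defaults emulate a single-cell-line screen: ~500 compounds falling into
    a few structural families (prototypes), assay concentrations around
    1 µM (lconc mean -6, SD 1.4 on the log10-molar scale, spanning the
    usual 10 nM - 100 µM dose range), and GI driven by ten designated
    fingerprint bits with weights of about +/-20 GI points plus a dose
    slope of -15 GI points per tenfold concentration increase.
    """

    n_compounds: int = 500
    n_prototypes: int = 4
    bit_flip_rate: float = 0.05
    prototype_density: float = 0.3
    lconc_mean: float = -6.0
    lconc_sd: float = 1.4
    n_gi_bits: int = 10
    gi_coefficient_scale: float = 20.0
    gi_coefficients: np.ndarray | None = None  # full 166-vector; overrides the two fields above
    gi_dose_slope: float = -15.0
    gi_intercept: float = -50.0
    gi_noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        if not 0.0 <= self.bit_flip_rate < 0.5:
            raise ValueError("bit_flip_rate must lie in [0, 0.5)")
        if self.lconc_sd <= 0:
            raise ValueError("lconc_sd must be positive")
        if self.gi_noise_sd < 0:
            raise ValueError("gi_noise_sd must be non-negative")


@dataclass
class SyntheticTruth:
    """Generating ground truth, kept for recovery tests."""

    prototypes: np.ndarray
    assignments: np.ndarray
    gi_coefficients: np.ndarray
    gi_dose_slope: float
    gi_intercept: float


def generate_synthetic(spec: SyntheticSpec) -> tuple[TrainingSet, SyntheticTruth]:
    """Draw a fully reproducible synthetic training set.

    Each compound picks a prototype uniformly, flips each bit independently
    with ``bit_flip_rate``, draws LCONC ~ Normal(lconc_mean, lconc_sd^2),
    and gets ``gi = coeffs . bits + gi_dose_slope * lconc + gi_intercept + noise``.
    """
    rng = np.random.default_rng(spec.seed)
    prototypes = (rng.random((spec.n_prototypes, N_BITS)) < spec.prototype_density).astype(np.uint8)
    assignments = rng.integers(0, spec.n_prototypes, size=spec.n_compounds)
    X = prototypes[assignments]
    flips = rng.random(X.shape) < spec.bit_flip_rate
    X = np.where(flips, 1 - X, X).astype(np.uint8)

    if spec.gi_coefficients is not None:
        coeffs = np.asarray(spec.gi_coefficients, dtype=float)
        if coeffs.shape != (N_BITS,):
            raise ValueError(f"gi_coefficients must have shape ({N_BITS},)")
    else:
        coeffs = np.zeros(N_BITS)
        active = rng.choice(N_BITS, size=spec.n_gi_bits, replace=False)
        coeffs[active] = rng.choice([-1.0, 1.0], size=spec.n_gi_bits) * spec.gi_coefficient_scale

    lconc = rng.normal(spec.lconc_mean, spec.lconc_sd, size=spec.n_compounds)
    noise = rng.normal(0.0, spec.gi_noise_sd, size=spec.n_compounds) if spec.gi_noise_sd > 0 else 0.0
    gi = X @ coeffs + spec.gi_dose_slope * lconc + spec.gi_intercept + noise

    ids = np.array([f"syn{i:05d}" for i in range(spec.n_compounds)])
    ts = TrainingSet(
        X=X, lconc=lconc, gi=gi, ids=ids, norm_stats=NormStats.from_columns(lconc, gi)
    )
    truth = SyntheticTruth(
        prototypes=prototypes, assignments=assignments,
        gi_coefficients=coeffs, gi_dose_slope=spec.gi_dose_slope,
        gi_intercept=spec.gi_intercept,
    )
    return ts, truth


def synthetic_library(
    n_compounds: int, seed: int, n_prototypes: int = 8,
    bit_flip_rate: float = 0.1, prototype_density: float = 0.3,
) -> tuple[list[str], np.ndarray]:
    """A screening library of noisy-prototype fingerprints (ids + N x 166)."""
    rng = np.random.default_rng(seed)
    prototypes = (rng.random((n_prototypes, N_BITS)) < prototype_density).astype(np.uint8)
    X = prototypes[rng.integers(0, n_prototypes, size=n_compounds)]
    flips = rng.random(X.shape) < bit_flip_rate
    X = np.where(flips, 1 - X, X).astype(np.uint8)
    ids = [f"lib{i:06d}" for i in range(n_compounds)]
    return ids, X
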