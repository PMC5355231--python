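"""SMILES parsing, MACCS featurization and fingerprint-matrix I/O.

Fingerprints are the 166 public MACCS substructure keys computed with RDKit;
key *i* (1-based in the MACCS definition) maps to vector position ``i - 1``.
The fingerprint matrix format is delimited text — one header line, then one
row per compound: an identifier followed by 166 ``0``/``1`` columns — plus an
optional compact ``.npz`` container. Both round-trip losslessly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys

logger = logging.getLogger(__name__)

N_BITS = 166

# RDKit warns loudly on every unparseable SMILES; rejections are reported
# by this module instead.
RDLogger.DisableLog("rdApp.error")


class FeaturizationError(ValueError):
    """A SMILES string could not be turned into a fingerprint."""

    def __init__(self, mol_id: str, smiles: str):
        self.mol_id = mol_id
        self.smiles = smiles
        super().__init__(f"cannot featurize molecule {mol_id!r}: SMILES {smiles!r} is not parseable")


@dataclass(frozen=True)
class Molecule:
    """A molecule record: opaque identifier plus SMILES string."""

    id: str
    smiles: str


@dataclass(frozen=True)
class SmilesDialect:
    """Column layout of a SMILES file (0-based indices, whitespace-delimited)."""

    smiles_col: int = 0
    id_col: int = 1
    delimiter: str | None = None  # None = any whitespace


@dataclass
class ParseReport:
    n_parsed: int = 0
    n_rejected: int = 0
    rejected_lines: list[int] | None = None


def parse_smiles_file(
    path: str | Path, dialect: SmilesDialect | None = None
) -> tuple[list[Molecule], ParseReport]:
    """Read molecules from a SMILES file, one per line.

    Lines without enough columns are rejected and counted, never fatal.
    A missing id column yields an automatic ``line<N>`` identifier.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        If no line yields a molecule.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"SMILES file not found: {path}")
    dialect = dialect or SmilesDialect()
    mols: list[Molecule] = []
    report = ParseReport(rejected_lines=[])
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split(dialect.delimiter)
        if len(fields) <= dialect.smiles_col or not fields[dialect.smiles_col]:
            report.n_rejected += 1
            report.rejected_lines.append(lineno)
            continue
        smiles = fields[dialect.smiles_col]
        mol_id = fields[dialect.id_col] if len(fields) > dialect.id_col else f"line{lineno}"
        if Chem.MolFromSmiles(smiles) is None:
            report.n_rejected += 1
            report.rejected_lines.append(lineno)
            logger.warning("rejected unparseable SMILES at line %d (id=%s)", lineno, mol_id)
            continue
        mols.append(Molecule(id=mol_id, smiles=smiles))
        report.n_parsed += 1
    if not mols:
        raise ValueError(f"no parseable molecules in {path}")
    if report.n_rejected:
        logger.info("parsed %d molecules, rejected %d lines", report.n_parsed, report.n_rejected)
    return mols, report


def maccs_fingerprint(mol: Molecule) -> np.ndarray:
    """Compute the 166-bit MACCS key fingerprint of a molecule.

    Deterministic: identical SMILES give identical bits. RDKit's MACCS
    vector has 167 positions with position 0 unused; positions 1..166
    map to output indices 0..165.
    """
    rdmol = Chem.MolFromSmiles(mol.smiles)
    if rdmol is None:
        raise FeaturizationError(mol.id, mol.smiles)
    keys = MACCSkeys.GenMACCSKeys(rdmol)
    bits = np.zeros(N_BITS, dtype=np.uint8)
    for idx in keys.GetOnBits():
        if 1 <= idx <= N_BITS:
            bits[idx - 1] = 1
    return bits


def _check_matrix(ids: Sequence[str], X: np.ndarray) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != N_BITS:
        raise ValueError(f"fingerprint matrix must be N x {N_BITS}, got shape {X.shape}")
    if len(ids) != X.shape[0]:
        raise ValueError("number of ids does not match number of rows")
    if X.shape[0] == 0:
        raise ValueError("refusing to write an empty fingerprint matrix")
    if not np.isin(X, (0, 1)).all():
        raise ValueError("fingerprint matrix entries must be 0 or 1")
    return X.astype(np.uint8)


def write_fingerprint_matrix(ids: Sequence[str], X: np.ndarray, path: str | Path) -> None:
    """Write an id column plus 166 0/1 columns; ``.npz`` paths use the binary container."""
    path = Path(path)
    X = _check_matrix(ids, X)
    if path.suffix == ".npz":
        np.savez_compressed(path, ids=np.asarray(ids, dtype=str), X=X)
        return
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(f"m{i}" for i in range(1, N_BITS + 1)) + "\n")
        for mol_id, row in zip(ids, X):
            fh.write(str(mol_id) + "\t" + "\t".join(map(str, row)) + "\n")


def read_fingerprint_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Inverse of :func:`write_fingerprint_matrix`; validates row widths."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as data:
            return [str(i) for i in data["ids"]], data["X"].astype(np.uint8)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for ids_chunk, X_chunk in stream_fingerprint_matrix(path, chunk_size=8192):
        ids.extend(ids_chunk)
        rows.append(X_chunk)
    return ids, np.vstack(rows)


def stream_fingerprint_matrix(
    path: str | Path, chunk_size: int = 4096
) -> Iterator[tuple[list[str], np.ndarray]]:
    """Yield ``(ids, X)`` chunks of a text fingerprint matrix without loading it whole."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id"):
            raise ValueError(f"{path}: missing fingerprint-matrix header")
        ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.split()
            if len(fields) != N_BITS + 1:
                raise ValueError(f"{path}:{lineno}: expected {N_BITS + 1} columns, got {len(fields)}")
            ids.append(fields[0])
            try:
                rows.append([int(v) for v in fields[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer fingerprint entry") from exc
            if len(ids) == chunk_size:
                yield ids, _as_bits(rows, path, lineno)
                ids, rows = [], []
        if ids:
            yield ids, _as_bits(rows, path, lineno)


def _as_bits(rows: list[list[int]], path: Path, lineno: int) -> np.ndarray:
    X = np.asarray(rows, dtype=np.int64)
    if not np.isin(X, (0, 1)).all():
        raise ValueError(f"{path}: non-binary fingerprint entries near line {lineno}")
    return X.astype(np.uint8)
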