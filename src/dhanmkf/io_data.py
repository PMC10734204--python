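"""Readers/writers for the external formats and cross-validation plumbing.

The association matrix is a labeled 0/1 table (circRNAs on rows, drugs on
columns).  Cross-validation follows the balanced-sampling protocol used for
bipartite link prediction: known associations are the positives, a matching
number of unknown pairs is drawn as negatives, positives are partitioned
into folds, and each fold's positives are masked out of the training matrix.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Pair = tuple[int, int]


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


class MissingDataError(KeyError):
    """Raised when required entity records are absent from an input file."""


@dataclass(frozen=True)
class EntityIndex:
    """Ordered bijection between entity identifiers and matrix positions."""

    ids: tuple[str, ...]
    kind: str  # "circRNA" | "drug"

    def __post_init__(self) -> None:
        if len(self.ids) == 0:
            raise FormatError(f"empty {self.kind} index")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if list(self.ids).count(i) > 1})
            raise FormatError(f"duplicate {self.kind} ids: {dupes}")

    def __len__(self) -> int:
        return len(self.ids)

    def position(self, entity_id: str) -> int:
        try:
            return self.ids.index(entity_id)
        except ValueError:
            raise MissingDataError(f"unknown {self.kind} id {entity_id!r}") from None


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary circRNA x drug association matrix with labeled axes."""

    values: np.ndarray
    row_index: EntityIndex
    col_index: EntityIndex

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.shape != (len(self.row_index), len(self.col_index)):
            raise FormatError(
                f"matrix shape {vals.shape} does not match indices "
                f"({len(self.row_index)}, {len(self.col_index)})"
            )
        if not np.isin(vals, (0, 1)).all():
            bad = sorted(set(np.unique(vals)) - {0, 1})
            raise FormatError(f"association matrix must be binary; found {bad}")
        object.__setattr__(self, "values", vals.astype(np.int8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def n_positives(self) -> int:
        return int(self.values.sum())

    def positive_pairs(self) -> list[Pair]:
        rows, cols = np.nonzero(self.values)
        return list(zip(rows.tolist(), cols.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.row_index.ids), columns=list(self.col_index.ids)
        )


@dataclass
class SplitSpec:
    """Fold assignment for cross-validation over balanced pair samples."""

    fold_count: int
    seed: int
    held_out_pairs: list[list[tuple[int, int, int]]] = field(default_factory=list)

    def fold_positives(self, k: int) -> list[Pair]:
        return [(i, j) for i, j, y in self.held_out_pairs[k] if y == 1]

    def fold_negatives(self, k: int) -> list[Pair]:
        return [(i, j) for i, j, y in self.held_out_pairs[k] if y == 0]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "fold_count": self.fold_count,
            "seed": self.seed,
            "held_out_pairs": [
                [[int(i), int(j), int(y)] for i, j, y in fold]
                for fold in self.held_out_pairs
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitSpec":
        payload = json.loads(Path(path).read_text())
        return cls(
            fold_count=payload["fold_count"],
            seed=payload["seed"],
            held_out_pairs=[
                [(int(i), int(j), int(y)) for i, j, y in fold]
                for fold in payload["held_out_pairs"]
            ],
        )


def _read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    # TSV by default; comma dialect autodetected.
    return pd.read_csv(path, sep=None, engine="python", index_col=index_col)


def load_association_matrix(path: str | Path) -> AssociationMatrix:
    """Read a labeled 0/1 table (rows: circRNA ids, columns: drug ids)."""
    frame = _read_table(path)
    if frame.empty:
        raise FormatError(f"{path}: empty association table")
    if frame.index.has_duplicates:
        raise FormatError(f"{path}: duplicate circRNA ids {sorted(frame.index[frame.index.duplicated()])}")
    if frame.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate drug ids")
    values = frame.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise FormatError(f"{path}: association entries must be 0/1")
    return AssociationMatrix(
        values=values,
        row_index=EntityIndex(tuple(str(i) for i in frame.index), "circRNA"),
        col_index=EntityIndex(tuple(str(c) for c in frame.columns), "drug"),
    )


def write_association_matrix(matrix: AssociationMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def load_sequences(path: str | Path, index: EntityIndex) -> dict[str, str]:
    """Read FASTA records for every id in *index*.

    Extra records are ignored with a warning; duplicate headers keep the
    first record seen.
    """
    from Bio import SeqIO

    records: dict[str, str] = {}
    extra: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            logger.warning("duplicate FASTA header %r: keeping first record", rec.id)
            continue
        if rec.id in index.ids:
            records[rec.id] = str(rec.seq).upper()
        else:
            extra.append(rec.id)
    if extra:
        logger.warning("ignoring %d FASTA records not in the %s index", len(extra), index.kind)
    missing = [i for i in index.ids if i not in records or not records[i]]
    if missing:
        raise MissingDataError(f"FASTA {path} missing sequences for ids: {missing}")
    return {i: records[i] for i in index.ids}


def load_smiles_table(path: str | Path, index: EntityIndex) -> dict[str, str]:
    """Read a two-column (id, smiles) table covering every drug id."""
    frame = _read_table(path, index_col=None)
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (id, smiles)")
    mapping = {str(r): str(s) for r, s in zip(frame.iloc[:, 0], frame.iloc[:, 1])}
    missing = [i for i in index.ids if i not in mapping]
    if missing:
        raise MissingDataError(f"SMILES table {path} missing drugs: {missing}")
    return {i: mapping[i] for i in index.ids}


def load_fingerprint_table(path: str | Path, index: EntityIndex) -> dict[str, np.ndarray]:
    """Read a two-column (id, bitstring) table of binary fingerprints."""
    frame = _read_table(path, index_col=None)
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (id, bits)")
    mapping: dict[str, np.ndarray] = {}
    for r, bits in zip(frame.iloc[:, 0], frame.iloc[:, 1]):
        bitstr = str(bits)
        if set(bitstr) - {"0", "1"}:
            raise FormatError(f"{path}: fingerprint for {r!r} is not a 0/1 string")
        mapping[str(r)] = np.frombuffer(bitstr.encode(), dtype=np.uint8) - ord("0")
    missing = [i for i in index.ids if i not in mapping]
    if missing:
        raise MissingDataError(f"fingerprint table {path} missing drugs: {missing}")
    return {i: mapping[i] for i in index.ids}


def load_partition_labels(path: str | Path, index: EntityIndex) -> dict[str, str]:
    """Read a two-column (id, head|tail) override for node typing."""
    frame = _read_table(path, index_col=None)
    mapping = {str(r): str(lbl).strip().lower() for r, lbl in zip(frame.iloc[:, 0], frame.iloc[:, 1])}
    bad = {i: v for i, v in mapping.items() if v not in ("head", "tail")}
    if bad:
        raise FormatError(f"{path}: labels must be head|tail, got {bad}")
    missing = [i for i in index.ids if i not in mapping]
    if missing:
        raise MissingDataError(f"partition file {path} missing ids: {missing}")
    return {i: mapping[i] for i in index.ids}


def drop_isolated(matrix: AssociationMatrix) -> AssociationMatrix:
    """Remove zero-degree rows and columns (the curated-variant convention)."""
    keep_r = matrix.values.sum(axis=1) > 0
    keep_c = matrix.values.sum(axis=0) > 0
    if keep_r.all() and keep_c.all():
        return matrix
    return AssociationMatrix(
        values=matrix.values[np.ix_(keep_r, keep_c)],
        row_index=EntityIndex(
            tuple(i for i, k in zip(matrix.row_index.ids, keep_r) if k), "circRNA"
        ),
        col_index=EntityIndex(
            tuple(i for i, k in zip(matrix.col_index.ids, keep_c) if k), "drug"
        ),
    )


def warn_isolated(matrix: AssociationMatrix) -> list[str]:
    """Return (and warn about) ids with zero degree; they stay by default."""
    iso = [i for i, d in zip(matrix.row_index.ids, matrix.values.sum(axis=1)) if d == 0]
    iso += [i for i, d in zip(matrix.col_index.ids, matrix.values.sum(axis=0)) if d == 0]
    if iso:
        warnings.warn(
            f"{len(iso)} isolated nodes kept; their interaction-profile rows are uninformative",
            stacklevel=2,
        )
    return iso


def mask_positives(
    matrix: AssociationMatrix, split: SplitSpec, fold: int
) -> AssociationMatrix:
    """Zero out fold *fold*'s held-out positives; everything else unchanged."""
    if not 0 <= fold < split.fold_count:
        raise IndexError(f"fold {fold} out of range for {split.fold_count} folds")
    values = matrix.values.copy()
    for i, j in split.fold_positives(fold):
        values[i, j] = 0
    return AssociationMatrix(values, matrix.row_index, matrix.col_index)


def sample_negatives(
    matrix: AssociationMatrix,
    n: int,
    seed: int,
    exclude: Iterable[Pair] = (),
) -> list[Pair]:
    """Draw *n* distinct zero-entry pairs uniformly without replacement."""
    zero_r, zero_c = np.nonzero(matrix.values == 0)
    pool = list(zip(zero_r.tolist(), zero_c.tolist()))
    excluded = set(exclude)
    if excluded:
        pool = [p for p in pool if p not in excluded]
    if n > len(pool):
        raise ValueError(f"requested {n} negatives but only {len(pool)} zero pairs available")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n, replace=False)
    return [pool[k] for k in sorted(chosen.tolist())]


def make_cv_folds(matrix: AssociationMatrix, k: int = 5, seed: int = 0) -> SplitSpec:
    """Partition positives into *k* folds; draw matching negatives per fold.

    Negatives are sampled with a fold-derived seed (seed + fold id) and are
    disjoint across folds so that no evaluation pair appears in another
    fold's training sample.
    """
    if k < 2:
        raise ValueError(f"fold count must be >= 2, got {k}")
    positives = matrix.positive_pairs()
    if len(positives) < k:
        raise ValueError(f"need at least {k} positives, found {len(positives)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    fold_pos: list[list[Pair]] = [[] for _ in range(k)]
    for rank, idx in enumerate(order.tolist()):
        fold_pos[rank % k].append(positives[idx])
    taken: set[Pair] = set()
    held_out: list[list[tuple[int, int, int]]] = []
    for f in range(k):
        negs = sample_negatives(matrix, len(fold_pos[f]), seed + f, exclude=taken)
        taken.update(negs)
        held_out.append(
            [(i, j, 1) for i, j in fold_pos[f]] + [(i, j, 0) for i, j in negs]
        )
    return SplitSpec(fold_count=k, seed=seed, held_out_pairs=held_out)


def training_pairs(split: SplitSpec, fold: int) -> tuple[list[Pair], np.ndarray]:
    """Union of the other folds' balanced samples, with 0/1 labels."""
    pairs: list[Pair] = []
    labels: list[int] = []
    for f in range(split.fold_count):
        if f == fold:
            continue
        for i, j, y in split.held_out_pairs[f]:
            pairs.append((i, j))
            labels.append(y)
    return pairs, np.asarray(labels, dtype=np.int8)
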