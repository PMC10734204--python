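"""Primary similarity matrices.

Four similarity sources feed the pipeline:

* CSS — circRNA host-gene sequence similarity, the indel-weighted
  Levenshtein "ratio" (substitution cost 2): ``1 - D_indel/(|a|+|b|)``.
* DSS — drug structural similarity, Tanimoto coefficient over path-based
  topological fingerprints.
* CGS / DGS — Gaussian interaction-profile (GIP) kernels over the rows /
  columns of the training association matrix, bandwidth scaled so the mean
  squared profile norm maps to alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform

from .io_data import AssociationMatrix, EntityIndex, FormatError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GipParams:
    """Bandwidth of a GIP kernel: gamma = alpha / mean squared profile norm."""

    alpha: float
    gamma: float


def _lcs_length(a: str, b: str) -> int:
    """Longest-common-subsequence length, row-vectorized DP.

    Uses the monotone-row identity
    ``L[i][j] = max(L[i-1][j], L[i-1][j-1] + match, L[i][j-1])``
    so each row is a cumulative maximum of vector candidates.
    """
    if not a or not b:
        return 0
    bv = np.frombuffer(b.encode("latin-1"), dtype=np.uint8)
    av = np.frombuffer(a.encode("latin-1"), dtype=np.uint8)
    prev = np.zeros(len(b) + 1, dtype=np.int32)
    for ca in av:
        cand = np.where(bv == ca, prev[:-1] + 1, 0)
        curr = np.maximum.accumulate(np.maximum(prev[1:], cand))
        prev[1:] = curr
    return int(prev[-1])


def levenshtein_ratio(a: str, b: str) -> float:
    """Similarity ``1 - D/(|a|+|b|)`` with indel cost 1, substitution cost 2.

    With substitutions costed as delete+insert the distance reduces to
    ``|a| + |b| - 2*LCS(a, b)``, so the ratio is ``2*LCS/(|a|+|b|)``.
    Two empty strings are identical by convention (ratio 1, logged).
    """
    if a is None or b is None:
        raise ValueError("sequences must be non-null")
    total = len(a) + len(b)
    if total == 0:
        logger.info("levenshtein_ratio of two empty strings: defined as 1.0")
        return 1.0
    return 2.0 * _lcs_length(a, b) / total


def sequence_similarity_matrix(
    sequences: dict[str, str], index: EntityIndex
) -> np.ndarray:
    """Pairwise Levenshtein-ratio matrix (CSS): symmetric, unit diagonal."""
    missing = [i for i in index.ids if i not in sequences]
    if missing:
        raise KeyError(f"missing sequences for: {missing}")
    n = len(index)
    seqs = [sequences[i] for i in index.ids]
    vals = np.empty(n * (n - 1) // 2) if n > 1 else np.empty(0)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            vals[k] = levenshtein_ratio(seqs[i], seqs[j])
            k += 1
    css = squareform(vals) if n > 1 else np.zeros((1, 1))
    np.fill_diagonal(css, 1.0)
    return css


def drug_fingerprint(smiles: str, n_bits: int = 2048, family: str = "topological") -> np.ndarray:
    """Binary fingerprint of a molecule given as SMILES.

    ``family='topological'`` is the path-based (Daylight-like) fingerprint;
    ``'morgan'`` (radius 2) is available as an alternative.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FormatError(f"unparsable SMILES: {smiles!r}")
    if family == "topological":
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=n_bits)
    elif family == "morgan":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    else:
        raise ValueError(f"unknown fingerprint family {family!r}")
    return np.asarray(gen.GetFingerprint(mol), dtype=np.uint8)


def tanimoto(fa: np.ndarray, fb: np.ndarray) -> float:
    """Jaccard similarity of two equal-length bit sets.

    Two empty sets are identical by convention (similarity 1, logged).
    """
    fa = np.asarray(fa, dtype=bool)
    fb = np.asarray(fb, dtype=bool)
    if fa.shape != fb.shape:
        raise ValueError(f"fingerprint length mismatch: {fa.shape} vs {fb.shape}")
    union = int(np.logical_or(fa, fb).sum())
    if union == 0:
        logger.info("tanimoto of two empty fingerprints: defined as 1.0")
        return 1.0
    return int(np.logical_and(fa, fb).sum()) / union


def structure_similarity_matrix(
    fingerprints: dict[str, np.ndarray], index: EntityIndex
) -> np.ndarray:
    """Pairwise Tanimoto matrix (DSS): symmetric, unit diagonal."""
    missing = [i for i in index.ids if i not in fingerprints]
    if missing:
        raise KeyError(f"missing fingerprints for: {missing}")
    fps = np.stack([np.asarray(fingerprints[i], dtype=bool) for i in index.ids])
    inter = (fps[:, None, :] & fps[None, :, :]).sum(axis=2).astype(float)
    union = (fps[:, None, :] | fps[None, :, :]).sum(axis=2).astype(float)
    dss = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(dss, 1.0)
    return dss


def _profiles(y_train: AssociationMatrix | np.ndarray, axis: str) -> np.ndarray:
    values = y_train.values if isinstance(y_train, AssociationMatrix) else np.asarray(y_train)
    if axis == "rows":
        return values.astype(float)
    if axis == "cols":
        return values.T.astype(float)
    raise ValueError(f"axis must be 'rows' or 'cols', got {axis!r}")


def gip_bandwidth(
    y_train: AssociationMatrix | np.ndarray, axis: str, alpha: float = 1.0
) -> GipParams:
    """Bandwidth gamma = alpha / (mean over entities of ||profile||^2)."""
    profiles = _profiles(y_train, axis)
    mean_sq = float((profiles**2).sum(axis=1).mean())
    if mean_sq == 0.0:
        raise ZeroDivisionError(
            "all interaction profiles are zero: GIP bandwidth undefined"
        )
    return GipParams(alpha=alpha, gamma=alpha / mean_sq)


def gip_kernel(
    y_train: AssociationMatrix | np.ndarray, axis: str, params: GipParams
) -> np.ndarray:
    """GIP kernel K(i,j) = exp(-gamma * ||profile_i - profile_j||^2)."""
    profiles = _profiles(y_train, axis)
    sq = (profiles**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * profiles @ profiles.T
    np.maximum(d2, 0.0, out=d2)
    kern = np.exp(-params.gamma * d2)
    kern = 0.5 * (kern + kern.T)
    np.fill_diagonal(kern, 1.0)
    return kern
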