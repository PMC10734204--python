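"""Nonlinear cross-diffusion fusion of two similarity matrices.

Two similarity views of the same entities (e.g. sequence similarity and the
interaction-profile kernel) are fused by iterated diffusion through fixed
KNN-truncated local affinity operators: each view is propagated through the
other view's local operator and row-normalized, until the relative Frobenius
change of both chains falls below tolerance.  The fused matrix is the
symmetrized average of the two converged chains.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class FusionConfig:
    k_neighbors: int | None = None  # default ceil(N/3) capped at 20
    tol: float = 1e-6
    max_iter: int = 100

    def resolve_k(self, n: int) -> int:
        if self.k_neighbors is None:
            return min(int(np.ceil(n / 3)), 20)
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.k_neighbors > n:
            warnings.warn(f"k_neighbors={self.k_neighbors} > N={n}; clipped", stacklevel=2)
            return n
        return self.k_neighbors


def row_normalize(s: np.ndarray) -> np.ndarray:
    """Scale each row to sum 1; an all-zero row becomes uniform (logged)."""
    s = np.asarray(s, dtype=float)
    if (s < 0).any():
        raise ValueError("similarity matrix must be nonnegative")
    sums = s.sum(axis=1, keepdims=True)
    zero = sums[:, 0] == 0
    if zero.any():
        logger.info("row_normalize: %d all-zero rows set to uniform", int(zero.sum()))
    out = np.divide(s, sums, out=np.full_like(s, 1.0 / s.shape[1]), where=sums > 0)
    return out


def knn_local_affinity(s: np.ndarray, k: int) -> np.ndarray:
    """KNN-truncated local operator: row i keeps its k most-similar
    entities (self force-included), renormalized to sum 1."""
    s = np.asarray(s, dtype=float)
    n = s.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        warnings.warn(f"k={k} > N={n}; clipped to N", stacklevel=2)
        k = n
    out = np.zeros_like(s)
    for i in range(n):
        row = s[i].copy()
        row[i] = np.inf  # self always belongs to the neighborhood
        order = np.argsort(-row, kind="stable")
        keep = order[:k]
        vals = s[i, keep]
        total = vals.sum()
        if total == 0:
            out[i, keep] = 1.0 / k
        else:
            out[i, keep] = vals / total
    return out


def _diffusion_normalize(p: np.ndarray) -> np.ndarray:
    """Structure-preserving normalization used inside the iteration.

    Off-diagonal row mass is scaled to 1/2 and the diagonal reset to 1/2
    (rows whose off-diagonal mass is zero keep a pure self-loop).  This is
    the standard convergent form of nonlinear similarity fusion: the
    diagonal re-injection every iteration keeps the fixed point anchored to
    the local affinity structure instead of the flat stationary matrix of a
    row-stochastic averaging chain.
    """
    off = p.copy()
    np.fill_diagonal(off, 0.0)
    sums = off.sum(axis=1, keepdims=True)
    nonzero = sums[:, 0] > 0
    out = np.zeros_like(p)
    out[nonzero] = 0.5 * off[nonzero] / sums[nonzero]
    out[np.diag_indices_from(out)] = np.where(nonzero, 0.5, 1.0)
    return out


def snf_fuse(
    s1: np.ndarray,
    s2: np.ndarray,
    cfg: FusionConfig | None = None,
) -> tuple[np.ndarray, dict]:
    """Cross-diffuse two similarity views into one fused matrix.

    The local operators are computed once from the initial matrices and
    held fixed; the two chains are updated alternately (Gauss-Seidel order:
    ``S1 <- C1 S2 C1^T`` then ``S2 <- C2 S1 C2^T`` with the fresh S1) and
    renormalized after every update with the diagonal-reinforced form (see
    :func:`_diffusion_normalize`).  Convergence requires the relative
    Frobenius change of *both* chains below ``tol``.  Returns the
    symmetrized average and an info dict with iteration count and flag.
    """
    cfg = cfg or FusionConfig()
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape or s1.shape[0] != s1.shape[1]:
        raise ValueError(f"inputs must be square and same shape: {s1.shape} vs {s2.shape}")
    n = s1.shape[0]
    k = cfg.resolve_k(n)

    c1 = knn_local_affinity(s1, k)
    c2 = knn_local_affinity(s2, k)
    p1 = row_normalize(s1)
    p2 = row_normalize(s2)

    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        n1 = _diffusion_normalize(c1 @ p2 @ c1.T)
        n2 = _diffusion_normalize(c2 @ n1 @ c2.T)
        r1 = np.linalg.norm(n1 - p1) / max(np.linalg.norm(p1), 1e-300)
        r2 = np.linalg.norm(n2 - p2) / max(np.linalg.norm(p2), 1e-300)
        p1, p2 = n1, n2
        if r1 < cfg.tol and r2 < cfg.tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"cross-diffusion did not converge in {cfg.max_iter} iterations", stacklevel=2)

    fused = 0.5 * (p1 + p2)
    fused = 0.5 * (fused + fused.T)
    return fused, {"iterations": it, "converged": converged, "k_neighbors": k}
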