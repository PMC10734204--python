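"""Multi-kernel fusion and the Dual Laplacian Regularized Least Squares solver.

Each embedding matrix in the stack yields a Gaussian kernel
``K_l(i,j) = exp(-gamma * ||H^(l)(i) - H^(l)(j)||^2)`` with one shared
bandwidth; the fused kernel is their unweighted mean.  Associations are then
scored by minimizing

    J = ||IC a_c + (ID a_d)^T - 2 Y||_F^2
        + phi_c tr(a_c^T L_c a_c) + phi_d tr(a_d^T L_d a_d)

over the two coefficient matrices, where L are normalized graph Laplacians
of the fused kernels.  J is a convex quadratic in each block, so the blocks
are updated by exact closed-form alternation; the prediction is
``F = (IC a_c + (ID a_d)^T) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .autodiff import Tensor


# ---------------------------------------------------------------------------
# kernels over embedding stacks
# ---------------------------------------------------------------------------

def gaussian_kernel(embedding: np.ndarray, gamma: float) -> np.ndarray:
    """exp(-gamma * squared euclidean distances) between embedding rows."""
    x = np.asarray(embedding, dtype=float)
    sq = (x**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * x @ x.T
    np.maximum(d2, 0.0, out=d2)
    kern = np.exp(-gamma * d2)
    kern = 0.5 * (kern + kern.T)
    np.fill_diagonal(kern, 1.0)
    return kern


def embedding_gip_kernels(
    stack: list[np.ndarray], gamma: float = 1.0 / 75.0
) -> list[np.ndarray]:
    """One Gaussian kernel per embedding layer, shared bandwidth gamma."""
    if not stack:
        raise ValueError("empty embedding stack")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return [gaussian_kernel(h, gamma) for h in stack]


def fuse_kernels(kernels: list[np.ndarray]) -> np.ndarray:
    """Unweighted mean of the per-layer kernels (weights 1/(K+1))."""
    if not kernels:
        raise ValueError("cannot fuse an empty kernel set")
    return np.mean(np.stack(kernels), axis=0)


def gaussian_kernel_ad(embedding: Tensor, gamma: float) -> Tensor:
    """Differentiable Gaussian kernel over embedding rows (training path)."""
    sq = (embedding**2.0).sum(axis=1, keepdims=True)  # (N,1)
    d2 = sq + sq.T - 2.0 * (embedding @ embedding.T)
    return (d2 * (-gamma)).exp()


def fuse_kernels_ad(kernels: list[Tensor]) -> Tensor:
    acc = kernels[0]
    for k in kernels[1:]:
        acc = acc + k
    return acc * (1.0 / len(kernels))


# ---------------------------------------------------------------------------
# DLapRLS
# ---------------------------------------------------------------------------

@dataclass
class DLapRLSState:
    """Coefficients and graph structure of the dual-space solver."""

    alpha_c: np.ndarray  # (N_c, N_d)
    alpha_d: np.ndarray  # (N_d, N_c)
    lap_c: np.ndarray
    lap_d: np.ndarray
    phi_c: float = 1.0 / 120.0
    phi_d: float = 1.0 / 120.0
    jitter: float = 1e-8
    history: list[float] = field(default_factory=list)


def normalized_laplacian(kernel: np.ndarray) -> np.ndarray:
    """L = V^{-1/2} (V - K) V^{-1/2} with V = diag(row sums of K)."""
    k = np.asarray(kernel, dtype=float)
    sums = k.sum(axis=1)
    if (sums <= 0).any():
        raise ValueError("kernel has a zero (or negative) row sum; Laplacian undefined")
    inv_sqrt = 1.0 / np.sqrt(sums)
    lap = -k * np.outer(inv_sqrt, inv_sqrt)
    lap[np.diag_indices_from(lap)] += 1.0
    return lap


def laplacian_trace_ad(kernel: Tensor, gram: np.ndarray) -> Tensor:
    """tr(a^T L a) with a held constant, differentiable in the kernel.

    Uses L = I - V^{-1/2} K V^{-1/2} and tr(a^T L a) = sum(L * (a a^T)),
    where ``gram = a a^T`` is precomputed.
    """
    sums = kernel.sum(axis=1, keepdims=True)
    inv_sqrt = sums**-0.5
    norm_k = kernel * inv_sqrt * inv_sqrt.T
    diag_term = float(np.trace(gram))
    return Tensor(diag_term) + (norm_k * Tensor(gram)).sum() * -1.0


def make_state(
    ic: np.ndarray,
    id_: np.ndarray,
    phi_c: float = 1.0 / 120.0,
    phi_d: float = 1.0 / 120.0,
    jitter: float = 1e-8,
    rng: np.random.Generator | None = None,
) -> DLapRLSState:
    """Random coefficient init plus Laplacians of the fused kernels."""
    rng = rng or np.random.default_rng(0)
    n_c, n_d = ic.shape[0], id_.shape[0]
    return DLapRLSState(
        alpha_c=rng.standard_normal((n_c, n_d)) * 0.01,
        alpha_d=rng.standard_normal((n_d, n_c)) * 0.01,
        lap_c=normalized_laplacian(ic),
        lap_d=normalized_laplacian(id_),
        phi_c=phi_c,
        phi_d=phi_d,
        jitter=jitter,
    )


def dlaprls_loss(
    state: DLapRLSState, ic: np.ndarray, id_: np.ndarray, y_train: np.ndarray
) -> float:
    fit = ic @ state.alpha_c + (id_ @ state.alpha_d).T - 2.0 * y_train
    return float(
        (fit**2).sum()
        + state.phi_c * np.trace(state.alpha_c.T @ state.lap_c @ state.alpha_c)
        + state.phi_d * np.trace(state.alpha_d.T @ state.lap_d @ state.alpha_d)
    )


def _spd_solve(a: np.ndarray, b: np.ndarray, jitter: float) -> np.ndarray:
    a = a + jitter * np.eye(a.shape[0])
    try:
        return scipy.linalg.solve(a, b, assume_a="pos")
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological input
        cond = np.linalg.cond(a)
        raise np.linalg.LinAlgError(
            f"DLapRLS system singular after jitter (cond={cond:.3e})"
        ) from exc


def update_alpha_c(
    state: DLapRLSState, ic: np.ndarray, id_: np.ndarray, y_train: np.ndarray
) -> np.ndarray:
    """Exact minimizer of J in alpha_c with alpha_d fixed.

    Zeroing dJ/da_c = 2 IC (IC a_c + (ID a_d)^T - 2 Y) + 2 phi_c L_c a_c
    gives the SPD normal equations
    ``(IC IC + phi_c L_c) a_c = IC [2 Y - a_d^T ID^T]``.
    """
    rhs = ic @ (2.0 * y_train - state.alpha_d.T @ id_.T)
    return _spd_solve(ic @ ic + state.phi_c * state.lap_c, rhs, state.jitter)


def update_alpha_d(
    state: DLapRLSState, ic: np.ndarray, id_: np.ndarray, y_train: np.ndarray
) -> np.ndarray:
    """Exact minimizer of J in alpha_d with alpha_c fixed:
    ``(ID ID + phi_d L_d) a_d = ID [2 Y^T - a_c^T IC^T]``."""
    rhs = id_ @ (2.0 * y_train.T - state.alpha_c.T @ ic.T)
    return _spd_solve(id_ @ id_ + state.phi_d * state.lap_d, rhs, state.jitter)


def alternate(
    state: DLapRLSState,
    ic: np.ndarray,
    id_: np.ndarray,
    y_train: np.ndarray,
    n_rounds: int = 1,
) -> DLapRLSState:
    """Alternating closed-form updates (alpha_c first), tracking J."""
    for _ in range(n_rounds):
        state.alpha_c = update_alpha_c(state, ic, id_, y_train)
        state.alpha_d = update_alpha_d(state, ic, id_, y_train)
        state.history.append(dlaprls_loss(state, ic, id_, y_train))
    return state


def predict(state: DLapRLSState, ic: np.ndarray, id_: np.ndarray) -> np.ndarray:
    """F = (IC a_c + (ID a_d)^T) / 2."""
    return 0.5 * (ic @ state.alpha_c + (id_ @ state.alpha_d).T)
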