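"""Similarity Network Fusion (SNF) by iterative KNN cross-diffusion.

Each selected view W^(v) is split into a *global* row-stochastic kernel
P^(v) (all pairwise mass, half of it kept on the diagonal) and a *local*
kernel S^(v) supported only on each drug's K nearest neighbours. The global
kernels are then diffused through each other:

    P^(v)  <-  S^(v) · mean_{u != v} P^(u) · S^(v)^T

for T iterations, with symmetrization, a diagonal regularizer and row
re-normalization after every step. Local (KNN) propagation makes the fusion
robust to the weak, noisy mass that dense similarity matrices spread over
distant drugs. The fused output is the symmetrized mean of the converged
kernels; with a single input view, fusion is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import SimilarityMatrix
from .exceptions import DegenerateInputError, DimensionError, ParameterError


@dataclass(frozen=True)
class FusionConfig:
    """K: neighbourhood size (capped at m-1); T: diffusion iterations;
    alpha_reg: diagonal regularizer added after each update."""

    K: int = 20
    T: int = 20
    alpha_reg: float = 1.0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ParameterError("K must be >= 1")
        if self.T < 1:
            raise ParameterError("T must be >= 1")
        if self.alpha_reg < 0:
            raise ParameterError("alpha_reg must be non-negative")


@dataclass(frozen=True)
class FusedSimilarity:
    """Fused m×m similarity; symmetric, finite, non-negative, positive row sums."""

    F: np.ndarray

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        if F.ndim != 2 or F.shape[0] != F.shape[1]:
            raise DimensionError("fused matrix must be square")
        if not np.isfinite(F).all() or (F < 0).any():
            raise DegenerateInputError("fused matrix must be finite and non-negative")
        if (F.sum(axis=1) <= 0).any():
            raise DegenerateInputError("fused matrix has a zero row")
        object.__setattr__(self, "F", F)

    @property
    def m(self) -> int:
        return self.F.shape[0]


def global_kernel(W: SimilarityMatrix) -> np.ndarray:
    """Row-stochastic full kernel: half the row mass on the diagonal.

    P[i, j] = W[i, j] / (2 * sum_{k != i} W[i, k]) off-diagonal, P[i, i] = 1/2.
    """
    A = W.A.astype(float)
    off = A.copy()
    np.fill_diagonal(off, 0.0)
    row = off.sum(axis=1)
    if (row == 0).any():
        raise DegenerateInputError(
            f"view {W.name!r}: a row has zero off-diagonal mass"
        )
    P = off / (2.0 * row[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def local_kernel(W: SimilarityMatrix, K: int) -> np.ndarray:
    """KNN kernel: each row keeps its K largest off-diagonal entries, renormalized.

    Ties are broken toward the lower column index, so the kernel is
    deterministic for any input.
    """
    m = W.m
    if not 1 <= K <= m - 1:
        raise ParameterError(f"K must be in [1, {m - 1}], got {K}")
    A = W.A.astype(float).copy()
    np.fill_diagonal(A, -np.inf)  # diagonal never a neighbour
    # stable sort on (-value, column) gives largest-first, low index on ties
    order = np.argsort(-A, axis=1, kind="stable")
    S = np.zeros((m, m))
    rows = np.arange(m)[:, None]
    nbr = order[:, :K]
    vals = W.A[rows, nbr]
    mass = vals.sum(axis=1)
    safe = np.where(mass > 0, mass, 1.0)
    S[rows, nbr] = vals / safe[:, None]
    return S


def _renormalize(P: np.ndarray, alpha: float) -> np.ndarray:
    """Symmetrize, add the diagonal regularizer, and restore row-stochasticity."""
    P = (P + P.T) / 2.0
    P = P + alpha * np.eye(P.shape[0])
    return P / P.sum(axis=1, keepdims=True)


def fuse(
    views: list[SimilarityMatrix],
    cfg: FusionConfig = FusionConfig(),
    return_diagnostics: bool = False,
):
    """Fuse the selected views into one matrix.

    Updates all views simultaneously each iteration, so the result is
    invariant to the order of the input list. Returns a
    :class:`FusedSimilarity` (and a diagnostics dict when requested, holding
    the worst row-sum deviation observed after each re-normalization).
    """
    if not views:
        raise ParameterError("fuse requires at least one view")
    m = views[0].m
    for v in views:
        if v.m != m:
            raise DimensionError("views have mixed dimensions")

    if len(views) == 1:
        fused = FusedSimilarity(F=views[0].A.copy())
        return (fused, {"row_sum_dev": []}) if return_diagnostics else fused

    K = min(cfg.K, m - 1)
    P = [global_kernel(v) for v in views]
    S = [local_kernel(v, K) for v in views]
    n = len(views)
    devs: list[float] = []
    for _ in range(cfg.T):
        updated = []
        for v in range(n):
            mean_others = sum(P[u] for u in range(n) if u != v) / (n - 1)
            updated.append(S[v] @ mean_others @ S[v].T)
        P = [_renormalize(Pv, cfg.alpha_reg) for Pv in updated]
        devs.append(max(abs(Pv.sum(axis=1) - 1.0).max() for Pv in P))
    F = sum(P) / n
    F = (F + F.T) / 2.0
    fused = FusedSimilarity(F=F)
    return (fused, {"row_sum_dev": devs}) if return_diagnostics else fused
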