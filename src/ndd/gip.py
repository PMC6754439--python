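"""Gaussian Interaction Profile (GIP) kernel.

Two drugs get a high GIP similarity when their interaction profiles — the
binary vectors recording which other drugs each is known to interact with —
are close in Euclidean distance:

    GIP(d_i, d_j) = exp(-gamma_d * ||Y_i - Y_j||^2)

with a data-normalized bandwidth

    gamma_d = gamma_tilde / ((1/m) * sum_i ||Y_i||^2),

i.e. the raw bandwidth is divided by the mean interaction count per drug so
the kernel scale is independent of dataset size. Because GIP is derived from
interaction labels, the pipeline computes it from a *masked* copy of Y in
which held-out test pairs are zeroed (see :func:`mask_pairs`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .data_model import InteractionMatrix, SimilarityMatrix
from .exceptions import DegenerateInputError, ParameterError


@dataclass(frozen=True)
class GIPConfig:
    """Bandwidth scale gamma_tilde (> 0); the working gamma_d is derived from Y."""

    gamma_tilde: float = 1.0

    def __post_init__(self) -> None:
        if not self.gamma_tilde > 0:
            raise ParameterError("gamma_tilde must be positive")


def gip_bandwidth(Y: InteractionMatrix, cfg: GIPConfig = GIPConfig()) -> float:
    """Return gamma_d = gamma_tilde / mean_i ||Y_i||^2.

    For binary Y the squared profile norm is drug i's interaction count, so
    the denominator is the average number of known interactions per drug.
    """
    sq_norms = (Y.Y.astype(float) ** 2).sum(axis=0)
    mean_sq = sq_norms.mean()
    if mean_sq == 0:
        raise DegenerateInputError("GIP bandwidth undefined: Y has no interactions")
    return cfg.gamma_tilde / mean_sq


def gip_similarity(
    Y: InteractionMatrix, cfg: GIPConfig = GIPConfig(), name: str = "gip"
) -> SimilarityMatrix:
    """Gaussian kernel over interaction profiles (columns of Y).

    Symmetric with unit diagonal; entries in (0, 1].
    """
    gamma = gip_bandwidth(Y, cfg)
    P = Y.Y.astype(float)  # symmetric, so columns == rows
    sq = (P**2).sum(axis=0)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (P.T @ P)
    np.maximum(d2, 0.0, out=d2)
    G = np.exp(-gamma * d2)
    G = (G + G.T) / 2.0
    np.fill_diagonal(G, 1.0)
    return SimilarityMatrix(name=name, A=G)


def mask_pairs(Y: InteractionMatrix, pairs: Iterable[tuple[int, int]]) -> InteractionMatrix:
    """Zero the given pairs in both orders, hiding their labels from training."""
    M = Y.Y.copy()
    for i, j in pairs:
        M[i, j] = 0
        M[j, i] = 0
    return InteractionMatrix(Y=M)
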