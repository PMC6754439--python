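"""Entropy-based similarity selection.

Candidate similarity views are scored by the mean Shannon entropy of their
row-normalized distributions: a view whose rows are close to uniform carries
little discriminative information (high entropy), while a view that
concentrates each drug's similarity mass on a few neighbours is informative
(low entropy). Views with entropy above ``c1 * log(m)`` are discarded as
random-like; the survivors are ranked by ascending entropy and pruned
greedily so that no two selected views have affinity S = 1/(1+D) above
``c2``, where D is the Frobenius (entrywise Euclidean) distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data_model import SimilarityMatrix
from .exceptions import (
    DegenerateInputError,
    DimensionError,
    ParameterError,
    SelectionEmptyError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds of the selection heuristic.

    c1 scales the entropy cutoff ``c1 * log(m)``; c2 is the pairwise-affinity
    cutoff above which two views count as redundant. Both default to 0.6.
    """

    c1: float = 0.6
    c2: float = 0.6
    exclude_diagonal: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.c1 < 1 and 0 < self.c2 < 1):
            raise ParameterError("c1 and c2 must lie in (0, 1)")


@dataclass(frozen=True)
class SelectionResult:
    entropies: Mapping[str, float]
    ranked: tuple[str, ...]
    selected: tuple[str, ...]
    eliminated: Mapping[str, str]
    threshold: float = field(default=float("nan"))

    def to_dict(self) -> dict:
        return {
            "entropies": dict(self.entropies),
            "entropy_threshold": self.threshold,
            "ranked": list(self.ranked),
            "selected": list(self.selected),
            "eliminated": dict(self.eliminated),
        }


def matrix_entropy(
    A: SimilarityMatrix | np.ndarray, exclude_diagonal: bool = False
) -> float:
    """Mean Shannon entropy (natural log) of the row-normalized distributions.

    Each row is normalized to p_ij = a_ij / sum_k a_ik and scored by
    -sum_j p_ij log p_ij with the 0·log 0 := 0 convention; a row summing to
    zero contributes entropy 0 with a warning. Accepts a named view or a
    bare non-negative matrix.
    """
    if isinstance(A, SimilarityMatrix):
        name, W = A.name, A.A.astype(float).copy()
    else:
        name, W = "<array>", np.asarray(A, dtype=float).copy()
        if W.ndim != 2 or (W < 0).any() or not np.isfinite(W).all():
            raise ParameterError("entropy needs a finite non-negative 2-d matrix")
    if exclude_diagonal:
        np.fill_diagonal(W, 0.0)
    row_sums = W.sum(axis=1)
    if (row_sums == 0).all():
        raise DegenerateInputError(f"view {name!r}: all rows sum to zero")
    if (row_sums == 0).any():
        logger.warning(
            "view %r: %d zero-sum rows contribute entropy 0",
            name, int((row_sums == 0).sum()),
        )
    safe = np.where(row_sums > 0, row_sums, 1.0)
    P = W / safe[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, -P * np.log(P), 0.0)
    return float(terms.sum(axis=1).mean())


def entropy_rank_filter(
    candidates: Sequence[SimilarityMatrix],
    c1: float = 0.6,
    exclude_diagonal: bool = False,
) -> list[str]:
    """Drop views with entropy > c1·log(m); sort the rest by ascending entropy.

    Ties are broken lexicographically by view name.
    """
    if not candidates:
        raise ParameterError("no candidate views")
    m = candidates[0].m
    threshold = c1 * math.log(m)
    scored = [(matrix_entropy(v, exclude_diagonal), v.name) for v in candidates]
    survivors = [sv for sv in scored if sv[0] <= threshold]
    if not survivors:
        raise SelectionEmptyError(
            f"every view exceeds the entropy threshold {threshold:.4f}"
        )
    survivors.sort()
    return [name for _, name in survivors]


def matrix_affinity(A: SimilarityMatrix, B: SimilarityMatrix) -> float:
    """S(A, B) = 1 / (1 + D(A, B)) with D the entrywise Euclidean distance."""
    if A.A.shape != B.A.shape:
        raise DimensionError(
            f"views {A.name!r} and {B.name!r} have different dimensions"
        )
    d = float(np.sqrt(((A.A - B.A) ** 2).sum()))
    return 1.0 / (1.0 + d)


def select_similarities(
    candidates: Sequence[SimilarityMatrix],
    cfg: SelectionConfig = SelectionConfig(),
) -> SelectionResult:
    """Run the full filter-rank-prune selection.

    After the entropy filter, views are taken greedily by ascending entropy;
    each time a view C is selected, every remaining view with affinity
    S(C, ·) > c2 is eliminated as redundant with C.
    """
    if not candidates:
        raise ParameterError("no candidate views")
    names = [v.name for v in candidates]
    if len(set(names)) != len(names):
        raise ParameterError("candidate view names must be unique")
    by_name = {v.name: v for v in candidates}
    m = candidates[0].m
    for v in candidates:
        if v.m != m:
            raise DimensionError("candidate views have mixed dimensions")

    threshold = cfg.c1 * math.log(m)
    entropies = {v.name: matrix_entropy(v, cfg.exclude_diagonal) for v in candidates}
    eliminated: dict[str, str] = {
        n: "high_entropy" for n, e in entropies.items() if e > threshold
    }
    ranked = sorted(
        (n for n in names if n not in eliminated), key=lambda n: (entropies[n], n)
    )
    if not ranked:
        raise SelectionEmptyError(
            f"every view exceeds the entropy threshold {threshold:.4f}"
        )

    selected: list[str] = []
    remaining = list(ranked)
    while remaining:
        chosen = remaining.pop(0)  # least entropy first (list is sorted)
        selected.append(chosen)
        kept = []
        for other in remaining:
            if matrix_affinity(by_name[chosen], by_name[other]) > cfg.c2:
                eliminated[other] = f"redundant_with:{chosen}"
            else:
                kept.append(other)
        remaining = kept
    return SelectionResult(
        entropies=entropies,
        ranked=tuple(ranked),
        selected=tuple(selected),
        eliminated=eliminated,
        threshold=threshold,
    )
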