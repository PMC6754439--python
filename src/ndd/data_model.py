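"""Core containers and delimited-text matrix I/O.

Every matrix in a run is indexed by one shared, ordered list of drug
identifiers (:class:`DrugIndex`); position ``k`` in the list corresponds to
row/column ``k`` of the interaction matrix and of every similarity view.
Loaders validate on entry so downstream stages can assume clean inputs.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .exceptions import (
    ConsistencyError,
    DimensionError,
    FormatError,
    IdentifierError,
)

logger = logging.getLogger(__name__)

#: tolerance under which a loaded matrix counts as symmetric
SYMMETRY_ATOL = 1e-8


@dataclass(frozen=True)
class DrugIndex:
    """Ordered, unique drug identifiers defining the matrix dimension m."""

    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) < 2:
            raise FormatError("a drug index needs at least 2 drugs")
        if len(set(self.ids)) != len(self.ids):
            raise IdentifierError("drug identifiers must be unique")

    @property
    def m(self) -> int:
        return len(self.ids)

    def position(self, drug_id: str) -> int:
        return self.ids.index(drug_id)

    @classmethod
    def from_file(cls, path: str | Path) -> "DrugIndex":
        """Read one identifier per line, ignoring blank lines."""
        ids = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
        return cls(tuple(ids))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.ids) + "\n")


@dataclass(frozen=True)
class InteractionMatrix:
    """Symmetric binary DDI matrix Y with zero diagonal.

    ``Y[i, j] = 1`` records a known interaction between drugs i and j; 0
    means no interaction is recorded (which is *not* evidence of absence).
    """

    Y: np.ndarray

    def __post_init__(self) -> None:
        Y = np.asarray(self.Y)
        if Y.ndim != 2 or Y.shape[0] != Y.shape[1]:
            raise DimensionError(f"interaction matrix must be square, got {Y.shape}")
        if not np.isin(Y, (0, 1)).all():
            raise FormatError("interaction matrix entries must be 0 or 1")
        if (Y != Y.T).any():
            raise ConsistencyError("interaction matrix must be symmetric")
        if np.diagonal(Y).any():
            raise ConsistencyError("interaction matrix diagonal must be zero")
        object.__setattr__(self, "Y", Y.astype(np.int8))

    @property
    def m(self) -> int:
        return self.Y.shape[0]

    @property
    def n_interacting_entries(self) -> int:
        """Number of ordered (i, j) entries equal to 1; twice the pair count."""
        return int(self.Y.sum())


@dataclass(frozen=True)
class SimilarityMatrix:
    """One named m×m drug-similarity view with entries in [0, 1]."""

    name: str
    A: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise DimensionError(f"similarity matrix must be square, got {A.shape}")
        if not np.isfinite(A).all():
            raise FormatError(f"view {self.name!r} contains non-finite entries")
        if (A < 0).any():
            raise FormatError(f"view {self.name!r} contains negative entries")
        if np.abs(A - A.T).max(initial=0.0) > SYMMETRY_ATOL:
            raise ConsistencyError(
                f"view {self.name!r} is asymmetric beyond {SYMMETRY_ATOL}"
            )
        object.__setattr__(self, "A", A)

    @property
    def m(self) -> int:
        return self.A.shape[0]


@dataclass(frozen=True)
class PairSample:
    """One ordered drug pair with its label and concatenated feature vector."""

    i: int
    j: int
    label: int
    features: np.ndarray = field(repr=False)


class PairCounts(NamedTuple):
    total: int
    positives: int
    negatives: int


def count_pair_universe(index: DrugIndex, Y: InteractionMatrix) -> PairCounts:
    """Ordered-pair bookkeeping: m² pairs split into interacting entries and the rest.

    The total counts every ordered pair including self-pairs; ``positives`` is
    the number of nonzero entries of Y (each unordered interaction contributes
    two ordered entries).
    """
    if Y.m != index.m:
        raise DimensionError(f"Y is {Y.m}×{Y.m} but index has {index.m} drugs")
    total = index.m**2
    positives = Y.n_interacting_entries
    return PairCounts(total, positives, total - positives)


# ---------------------------------------------------------------------------
# delimited-text I/O


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _read_raw_matrix(path: str | Path) -> tuple[np.ndarray, list[str] | None]:
    """Read a delimited matrix, auto-detecting delimiter and optional ID headers.

    Returns the numeric block and, when a header row/column of identifiers is
    present, the identifiers in file order.
    """
    text = Path(path).read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty file")
    delim = _sniff_delimiter(text.splitlines()[0])
    df = pd.read_csv(io.StringIO(text), sep=delim, header=None, dtype=str)
    cells = df.to_numpy(dtype=object)

    has_header_row = not all(_is_number(str(c)) for c in cells[0, 1:])
    has_header_col = not all(_is_number(str(c)) for c in cells[1:, 0])
    ids: list[str] | None = None
    if has_header_row and has_header_col:
        ids = [str(c).strip() for c in cells[0, 1:]]
        col_ids = [str(c).strip() for c in cells[1:, 0]]
        if ids != col_ids:
            raise IdentifierError(f"{path}: row and column identifiers disagree")
        block = cells[1:, 1:]
    elif has_header_row:
        ids = [str(c).strip() for c in cells[0, :]]
        block = cells[1:, :]
    elif has_header_col:
        ids = [str(c).strip() for c in cells[:, 0]]
        block = cells[:, 1:]
    else:
        block = cells
    try:
        values = block.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric entry in matrix body: {exc}") from exc
    if np.isnan(values).any():
        raise FormatError(f"{path}: missing values are not permitted")
    return values, ids


def _align_to_index(
    values: np.ndarray, ids: list[str] | None, index: DrugIndex, path: str | Path
) -> np.ndarray:
    if values.shape != (index.m, index.m):
        raise DimensionError(
            f"{path}: matrix is {values.shape[0]}×{values.shape[1]} "
            f"but the drug index has m={index.m}"
        )
    if ids is not None:
        if sorted(ids) != sorted(index.ids):
            raise IdentifierError(
                f"{path}: file identifiers are not a permutation of the drug index"
            )
        order = [ids.index(d) for d in index.ids]
        values = values[np.ix_(order, order)]
    return values


def load_similarity_matrix(
    path: str | Path, name: str, index: DrugIndex
) -> SimilarityMatrix:
    """Load and validate one similarity view, aligning rows to ``index``.

    Asymmetric input is symmetrized as (A + Aᵀ)/2 with a logged warning;
    entries must lie in [0, 1] up to a small tolerance.
    """
    values, ids = _read_raw_matrix(path)
    values = _align_to_index(values, ids, index, path)
    if (values < 0).any():
        raise FormatError(f"{path}: negative similarity entries")
    if values.max(initial=0.0) > 1 + SYMMETRY_ATOL:
        raise FormatError(f"{path}: similarity entries exceed 1")
    asym = np.abs(values - values.T).max(initial=0.0)
    if asym > SYMMETRY_ATOL:
        logger.warning(
            "view %r (%s): asymmetry up to %.3g, symmetrizing as (A+A^T)/2",
            name, path, asym,
        )
        values = (values + values.T) / 2.0
    return SimilarityMatrix(name=name, A=np.clip(values, 0.0, 1.0))


def load_interaction_matrix(path: str | Path, index: DrugIndex) -> InteractionMatrix:
    """Load the binary DDI matrix; nonzero diagonal entries are zeroed with a warning."""
    values, ids = _read_raw_matrix(path)
    values = _align_to_index(values, ids, index, path)
    if not np.isin(values, (0.0, 1.0)).all():
        raise FormatError(f"{path}: interaction entries must be 0 or 1")
    if (values != values.T).any():
        raise ConsistencyError(f"{path}: interaction matrix is asymmetric")
    Y = values.astype(np.int8)
    if np.diagonal(Y).any():
        logger.warning("%s: zeroing %d nonzero diagonal entries", path, int(np.diagonal(Y).sum()))
        np.fill_diagonal(Y, 0)
    return InteractionMatrix(Y=Y)


def write_matrix(
    A: np.ndarray, path: str | Path, index: DrugIndex | None = None, delimiter: str = ","
) -> None:
    """Write a matrix as delimited text, optionally with an ID header row/column.

    Uses 17 significant digits so a write→load round trip is lossless.
    """
    A = np.asarray(A, dtype=float)
    with open(path, "w") as fh:
        if index is not None:
            fh.write(delimiter.join(["id", *index.ids]) + "\n")
            for drug, row in zip(index.ids, A):
                fh.write(drug + delimiter)
                fh.write(delimiter.join(f"{v:.17g}" for v in row) + "\n")
        else:
            for row in A:
                fh.write(delimiter.join(f"{v:.17g}" for v in row) + "\n")
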