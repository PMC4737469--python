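"""Connectivity matrices: the symmetric weighted adjacency of fiber counts.

A subject's white-matter network is a symmetric, zero-diagonal, nonnegative
90 x 90 matrix whose entry (i, j) is the number of reconstructed streamlines
connecting regions i and j.  Files use 1-based atlas indices; internally the
array is 0-based and that offset is never exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import N_NODES, RoiAtlas, load_atlas

__all__ = [
    "MatrixError",
    "ConnectivityMatrix",
    "read_matrix",
    "write_matrix",
    "binary_difference",
]

_SYMMETRY_TOL = 1e-9


class MatrixError(ValueError):
    """Raised when a matrix violates the connectivity contract."""


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric nonnegative weighted adjacency in atlas node order.

    ``weights[i, j]`` is the fiber count between atlas regions ``i+1`` and
    ``j+1``.  Validation (symmetry, zero diagonal, nonnegativity) runs at
    construction; the array is copied and frozen.
    """

    weights: np.ndarray
    n_nodes: int = field(init=False)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise MatrixError(f"weights must be square, got shape {w.shape}")
        if not np.allclose(w, w.T, atol=_SYMMETRY_TOL, rtol=0.0):
            i, j = np.unravel_index(np.argmax(np.abs(w - w.T)), w.shape)
            raise MatrixError(
                f"matrix is asymmetric at ({i + 1}, {j + 1}): "
                f"{w[i, j]} vs {w[j, i]}"
            )
        if np.any(np.diag(w) != 0):
            raise MatrixError("matrix diagonal must be zero")
        if np.any(w < 0):
            i, j = np.unravel_index(np.argmin(w), w.shape)
            raise MatrixError(f"negative weight {w[i, j]} at ({i + 1}, {j + 1})")
        w = (w + w.T) / 2.0  # exact symmetry
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "n_nodes", w.shape[0])

    @property
    def is_integer(self) -> bool:
        return bool(np.all(self.weights == np.round(self.weights)))

    @property
    def n_edges(self) -> int:
        """Number of present (nonzero) unordered connections."""
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    @property
    def total_weight(self) -> float:
        """Sum of weights over unordered connections."""
        return float(np.triu(self.weights, k=1).sum())

    def binarized(self) -> np.ndarray:
        """Boolean adjacency (presence of a connection)."""
        return self.weights > 0

    def __eq__(self, other) -> bool:
        return isinstance(other, ConnectivityMatrix) and np.array_equal(
            self.weights, other.weights
        )

    def __hash__(self):  # frozen dataclass would otherwise hash the array
        return hash((self.n_nodes, self.total_weight))


def _edge_list_to_array(table: pd.DataFrame, n: int) -> np.ndarray:
    w = np.zeros((n, n))
    seen: dict[tuple[int, int], float] = {}
    for row_no, (i, j, weight) in enumerate(
        table.itertuples(index=False), start=2
    ):
        i, j, weight = int(i), int(j), float(weight)
        if not (1 <= i <= n and 1 <= j <= n):
            raise MatrixError(
                f"line {row_no}: index pair ({i}, {j}) outside 1..{n}"
            )
        if i == j:
            raise MatrixError(f"line {row_no}: self-connection at node {i}")
        if weight < 0:
            raise MatrixError(f"line {row_no}: negative weight {weight}")
        key = (min(i, j), max(i, j))
        if key in seen and seen[key] != weight:
            raise MatrixError(
                f"line {row_no}: conflicting weights for pair {key}: "
                f"{seen[key]} vs {weight}"
            )
        seen[key] = weight
        w[i - 1, j - 1] = weight
        w[j - 1, i - 1] = weight
    return w


def read_matrix(path: str | Path, atlas: RoiAtlas | None = None) -> ConnectivityMatrix:
    """Read a connectivity matrix from a tab-separated file.

    Accepts either a full ``n x n`` numeric table (with or without a header
    row of ROI labels) or a three-column edge list ``i <TAB> j <TAB> weight``
    with 1-based atlas indices.  Edge lists are symmetrized by assignment;
    if both orders of a pair are present they must agree exactly.
    """
    atlas = atlas or load_atlas()
    n = len(atlas)
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    has_header = any(c.isalpha() for c in first)
    table = pd.read_csv(path, sep="\t", header=0 if has_header else None)
    if table.shape[1] == 3:
        if table.shape[0] == 0:
            return ConnectivityMatrix(np.zeros((n, n)))
        return ConnectivityMatrix(_edge_list_to_array(table, n))
    if table.shape == (n, n):
        w = table.to_numpy(dtype=float)
        return ConnectivityMatrix(w)  # symmetry enforced by the constructor
    raise MatrixError(
        f"{path}: expected a {n}x{n} table or 3-column edge list, "
        f"got shape {tuple(table.shape)}"
    )


def write_matrix(
    matrix: ConnectivityMatrix,
    path: str | Path,
    dialect: str = "full",
    atlas: RoiAtlas | None = None,
) -> Path:
    """Write a matrix as a full table or an upper-triangle edge list.

    Integer matrices round-trip exactly through :func:`read_matrix` in both
    dialects.  The ``full`` dialect has a header row of hemisphere-qualified
    ROI abbreviations; the ``edgelist`` dialect writes one ``i j weight`` row
    per nonzero upper-triangle entry.
    """
    atlas = atlas or load_atlas()
    path = Path(path)
    w = matrix.weights
    integer = matrix.is_integer
    if dialect == "full":
        out = pd.DataFrame(
            w.astype(int) if integer else w, columns=atlas.labels
        )
        out.to_csv(path, sep="\t", index=False)
    elif dialect == "edgelist":
        rows_i, rows_j = np.nonzero(np.triu(w, k=1))
        with open(path, "w") as fh:
            fh.write("roi_a\troi_b\tweight\n")
            for i, j in zip(rows_i, rows_j):
                val = int(w[i, j]) if integer else w[i, j]
                fh.write(f"{i + 1}\t{j + 1}\t{val}\n")
    else:
        raise ValueError(f"dialect must be 'full' or 'edgelist', got {dialect!r}")
    return path


def binary_difference(
    a: ConnectivityMatrix, b: ConnectivityMatrix
) -> np.ndarray:
    """Signed presence difference map between two thresholded networks.

    Entry (i, j) is +1 where ``a`` has a connection and ``b`` does not, -1
    where ``b`` has one and ``a`` does not, 0 otherwise.  Antisymmetric under
    swapping the arguments.
    """
    if a.weights.shape != b.weights.shape:
        raise MatrixError(
            f"shape mismatch: {a.weights.shape} vs {b.weights.shape}"
        )
    return a.binarized().astype(int) - b.binarized().astype(int)
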