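"""Network construction: fiber records -> thresholded count matrices.

Each record is one reconstructed streamline resolved to an unordered pair of
atlas regions.  The edge weight between two regions is the number of such
records, and a pair counts as anatomically connected only when at least
``min_fibers`` (default 4) streamlines join it — the standard guard against
false-positive connections in tractography-derived networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .atlas import RoiAtlas, load_atlas
from .matrices import ConnectivityMatrix, MatrixError

__all__ = [
    "DEFAULT_MIN_FIBERS",
    "FiberRecord",
    "read_fiber_records",
    "build_count_matrix",
    "apply_threshold",
    "connection_density",
]

#: Minimum streamline count for a pair of regions to count as connected.
DEFAULT_MIN_FIBERS = 4


@dataclass(frozen=True)
class FiberRecord:
    """One streamline, as an unordered pair of distinct atlas indices."""

    roi_a: int
    roi_b: int


def read_fiber_records(path: str | Path) -> list[FiberRecord]:
    """Read a tab-separated streamline file (columns roi_a, roi_b)."""
    table = pd.read_csv(path, sep="\t")
    if not {"roi_a", "roi_b"} <= set(table.columns):
        raise ValueError(f"{path}: expected columns roi_a, roi_b")
    return [
        FiberRecord(int(a), int(b))
        for a, b in zip(table["roi_a"], table["roi_b"])
    ]


def build_count_matrix(
    records: Iterable[FiberRecord], atlas: RoiAtlas | None = None
) -> ConnectivityMatrix:
    """Tally streamlines per unordered region pair into a count matrix."""
    atlas = atlas or load_atlas()
    n = len(atlas)
    w = np.zeros((n, n))
    for rec in records:
        a, b = rec.roi_a, rec.roi_b
        if not (1 <= a <= n and 1 <= b <= n):
            raise MatrixError(f"fiber record ({a}, {b}) outside 1..{n}")
        if a == b:
            raise MatrixError(f"fiber record with identical endpoints: {a}")
        w[a - 1, b - 1] += 1
        w[b - 1, a - 1] += 1
    return ConnectivityMatrix(w)


def apply_threshold(
    matrix: ConnectivityMatrix, min_fibers: int = DEFAULT_MIN_FIBERS
) -> ConnectivityMatrix:
    """Zero out connections with fewer than ``min_fibers`` streamlines.

    Surviving entries keep their raw count (the network stays weighted).
    Idempotent, and never increases any entry.
    """
    if min_fibers < 1:
        raise ValueError(f"min_fibers must be >= 1, got {min_fibers}")
    w = matrix.weights.copy()
    w[w < min_fibers] = 0.0
    return ConnectivityMatrix(w)


def connection_density(matrix: ConnectivityMatrix) -> float:
    """Fraction of possible region pairs with a surviving connection."""
    n = matrix.n_nodes
    return matrix.n_edges / (n * (n - 1) / 2)
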