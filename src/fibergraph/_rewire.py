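"""Degree-preserving double-edge-swap kernel (numba-compiled).

The null model relocates edges while keeping every node's binary degree: a
swap picks two edges (a, b) and (c, d) and replaces them with (a, d) and
(c, b), rejecting self-loops and duplicate edges.  Weights travel with their
edge.  The kernel is compiled because the rewiring budget is a multiple of
the edge count repeated over many sweep iterations and many null networks.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _swap_kernel(u, v, w, adj, n_attempts, seed):  # pragma: no cover - compiled
    np.random.seed(seed)
    m = u.shape[0]
    successes = 0
    for _ in range(n_attempts):
        e1 = np.random.randint(0, m)
        e2 = np.random.randint(0, m)
        if e1 == e2:
            continue
        a, b = u[e1], v[e1]
        c, d = u[e2], v[e2]
        if np.random.randint(0, 2) == 1:
            c, d = d, c
        # proposed replacement: (a, d) and (c, b)
        if a == d or c == b:
            continue
        if a == c or b == d:
            continue  # shared endpoint: swap would duplicate an edge
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        v[e1] = d
        u[e2] = c
        v[e2] = b
        successes += 1
    return successes


def rewire_edges(
    u: np.ndarray,
    v: np.ndarray,
    w: np.ndarray,
    n_nodes: int,
    n_attempts: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Run the swap kernel on copies of an edge list; returns new edges."""
    u = u.astype(np.int64).copy()
    v = v.astype(np.int64).copy()
    w = w.astype(np.float64).copy()
    adj = np.zeros((n_nodes, n_nodes), dtype=np.bool_)
    adj[u, v] = True
    adj[v, u] = True
    successes = _swap_kernel(u, v, w, adj, n_attempts, int(seed) % (2**31))
    return u, v, w, int(successes)
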