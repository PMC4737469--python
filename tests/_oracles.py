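"""Independent brute-force oracles used by the test suite.

Everything here is written from the defining formulas with plain Python
loops — no scipy/networkx graph routines — so the tests cross-check the
package against an implementation that shares no code path with it.
"""

import math

import numpy as np

INF = math.inf


def floyd_warshall(weights, binary=False):
    """All-pairs shortest path lengths with edge length 1/weight."""
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    d = [[0.0 if i == j else INF for j in range(n)] for i in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j and w[i][j] > 0:
                d[i][j] = 1.0 if binary else 1.0 / w[i][j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                via = d[i][k] + d[k][j]
                if via < d[i][j]:
                    d[i][j] = via
    return np.array(d)


def global_efficiency(weights, binary=False):
    d = floyd_warshall(weights, binary)
    n = d.shape[0]
    total = sum(
        1.0 / d[i][j]
        for i in range(n)
        for j in range(n)
        if i != j and math.isfinite(d[i][j])
    )
    return total / (n * (n - 1))


def nodal_efficiency(weights, binary=False):
    d = floyd_warshall(weights, binary)
    n = d.shape[0]
    return np.array(
        [
            sum(
                1.0 / d[i][j]
                for j in range(n)
                if j != i and math.isfinite(d[i][j])
            )
            / (n - 1)
            for i in range(n)
        ]
    )


def average_path_length(weights, binary=False):
    d = floyd_warshall(weights, binary)
    n = d.shape[0]
    finite = [
        d[i][j]
        for i in range(n)
        for j in range(n)
        if i != j and math.isfinite(d[i][j])
    ]
    excluded = n * (n - 1) - len(finite)
    return sum(finite) / len(finite), excluded


def local_efficiency(weights, binary=False):
    """Per-node efficiency of the neighbor subgraph (node itself removed)."""
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if w[i][j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        d = floyd_warshall(sub, binary)
        total = sum(
            1.0 / d[a][b]
            for a in range(k)
            for b in range(k)
            if a != b and math.isfinite(d[a][b])
        )
        out[i] = total / (k * (k - 1))
    return out


def clustering(weights):
    """Binary clustering coefficient per node by direct neighbor-pair count."""
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if w[i][j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        edges = sum(
            1
            for a in range(k)
            for b in range(a + 1, k)
            if w[nbrs[a]][nbrs[b]] > 0
        )
        out[i] = edges / (k * (k - 1) / 2)
    return out


def bh_stepup(p_values, q):
    """Benjamini-Hochberg step-up flags by exhaustive rank scan."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_max = rank
    flags = [False] * m
    for rank, idx in enumerate(order, start=1):
        if rank <= k_max:
            flags[idx] = True
    return np.array(flags)


def tally_pairs(pairs, n):
    """Count matrix from unordered index pairs via a dict tally."""
    counts = {}
    for a, b in pairs:
        key = (min(a, b), max(a, b))
        counts[key] = counts.get(key, 0) + 1
    w = np.zeros((n, n))
    for (a, b), c in counts.items():
        w[a - 1][b - 1] = c
        w[b - 1][a - 1] = c
    return w
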