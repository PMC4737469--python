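"""Graph measures of weighted connectivity networks.

All path-based measures treat the fiber count as a connection *strength*:
the length of an edge is the reciprocal of its weight, so strongly connected
region pairs are close.  Measures:

global
    Global efficiency ``E_glob`` (mean inverse shortest path length over
    ordered node pairs), mean local efficiency ``E_loc`` (efficiency within
    each node's neighbor subgraph), global clustering coefficient ``C``
    (binary triangle density around each node), characteristic path length
    ``L``, and the small-world ratios ``gamma = C/C_rand``,
    ``lambda = L/L_rand`` and ``sigma = gamma/lambda`` against an ensemble
    of degree-preserving rewired null networks.
regional
    Nodal efficiency ``E_i`` (mean inverse distance from node i to the rest
    of the network); a node is a hub when ``E_i`` is at least one sample
    standard deviation above the network mean.

Disconnected pairs contribute 0 to efficiency sums (1/inf = 0) and are
excluded from the characteristic path length, with the excluded-pair count
reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from ._rewire import rewire_edges
from .matrices import ConnectivityMatrix

__all__ = [
    "PathLengthMatrix",
    "GlobalMeasures",
    "NodalMeasures",
    "shortest_paths",
    "global_efficiency",
    "local_efficiency",
    "clustering_coefficient",
    "average_path_length",
    "nodal_efficiency",
    "identify_hubs",
    "rewired_null",
    "small_world",
    "compute_global_measures",
    "compute_nodal_measures",
]


@dataclass(frozen=True)
class PathLengthMatrix:
    """All-pairs shortest path lengths; +inf marks disconnected pairs."""

    lengths: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.lengths.shape[0]


@dataclass(frozen=True)
class GlobalMeasures:
    """Whole-network summary of one connectivity matrix.

    Small-world fields (``gamma``, ``lam``, ``sigma``, ``c_rand``,
    ``l_rand``) are NaN when no null ensemble was requested.
    """

    e_glob: float
    e_loc: float
    e_loc_nodal: np.ndarray
    clustering: float
    clustering_nodal: np.ndarray
    subgraph_edges: np.ndarray  # E_i: edge count among node i's neighbors
    subgraph_nodes: np.ndarray  # K_i: node i's neighbor count
    avg_path: float
    excluded_pairs: int  # ordered disconnected pairs left out of avg_path
    gamma: float = math.nan
    lam: float = math.nan
    sigma: float = math.nan
    c_rand: float = math.nan
    l_rand: float = math.nan


@dataclass(frozen=True)
class NodalMeasures:
    """Per-node efficiency and hub flags for one network."""

    efficiency: np.ndarray
    hub_flags: np.ndarray


def _length_graph(weights: np.ndarray, binary: bool) -> csr_matrix:
    lengths = np.zeros_like(weights, dtype=float)
    present = weights > 0
    lengths[present] = 1.0 if binary else 1.0 / weights[present]
    return csr_matrix(lengths)


def shortest_paths(
    matrix: ConnectivityMatrix, binary: bool = False
) -> PathLengthMatrix:
    """All-pairs shortest path lengths with per-edge length 1/weight.

    ``binary=True`` uses hop counts (every present edge has length 1)
    instead of reciprocal-weight lengths.
    """
    dist = dijkstra(_length_graph(matrix.weights, binary), directed=False)
    return PathLengthMatrix(dist)


def _inverse_lengths(lengths: np.ndarray) -> np.ndarray:
    """1/L with the 1/inf = 0 convention, zero diagonal."""
    inv = np.zeros_like(lengths)
    finite = np.isfinite(lengths) & (lengths > 0)
    inv[finite] = 1.0 / lengths[finite]
    return inv


def global_efficiency(paths: PathLengthMatrix) -> float:
    """Mean of 1/L_ij over ordered pairs i != j (1/inf = 0)."""
    n = paths.n_nodes
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    return float(_inverse_lengths(paths.lengths).sum() / (n * (n - 1)))


def nodal_efficiency(paths: PathLengthMatrix) -> np.ndarray:
    """Per-node mean of 1/L_ij over the other n-1 nodes."""
    n = paths.n_nodes
    if n < 2:
        raise ValueError("nodal efficiency needs at least 2 nodes")
    return _inverse_lengths(paths.lengths).sum(axis=1) / (n - 1)


def average_path_length(paths: PathLengthMatrix) -> tuple[float, int]:
    """Mean shortest path length over connected ordered pairs.

    Returns ``(L, excluded)`` where ``excluded`` counts the ordered
    disconnected pairs left out of the average.  Raises if no pair is
    connected.
    """
    lengths = paths.lengths
    n = paths.n_nodes
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(lengths) & off
    n_finite = int(finite.sum())
    if n_finite == 0:
        raise ValueError("no connected node pairs: path length undefined")
    excluded = int(off.sum()) - n_finite
    return float(lengths[finite].mean()), excluded


def local_efficiency(
    matrix: ConnectivityMatrix, binary: bool = False
) -> tuple[np.ndarray, float]:
    """Efficiency of each node's neighbor subgraph, and the network mean.

    For node i the subgraph holds i's direct neighbors only (i itself
    excluded); paths are recomputed strictly within it.  Nodes with fewer
    than two neighbors score 0.
    """
    w = matrix.weights
    n = matrix.n_nodes
    adj = matrix.binarized()
    eff = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(adj[i])[0]
        k = nbrs.size
        if k < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        dist = dijkstra(_length_graph(sub, binary), directed=False)
        eff[i] = _inverse_lengths(dist).sum() / (k * (k - 1))
    return eff, float(eff.mean())


def clustering_coefficient(
    matrix: ConnectivityMatrix,
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Binary clustering coefficient per node and its network mean.

    Returns ``(C_i, C, E_i, K_i)`` where ``E_i`` is the number of edges
    among node i's neighbors and ``K_i`` the neighbor count; ``C_i`` is
    ``E_i / (K_i (K_i - 1) / 2)`` and 0 where ``K_i < 2``.
    """
    adj = matrix.binarized().astype(float)
    k = adj.sum(axis=1)
    # edges among neighbors of i = number of closed triangles through i / ...
    triangles = np.einsum("ij,jk,ki->i", adj, adj, adj) / 2.0
    c = np.zeros_like(k)
    mask = k >= 2
    possible = k * (k - 1) / 2.0
    c[mask] = triangles[mask] / possible[mask]
    return c, float(c.mean()), triangles, k.astype(int)


def identify_hubs(efficiency: np.ndarray) -> np.ndarray:
    """Flag nodes whose efficiency is >= mean + 1 sample SD (ddof=1).

    A constant efficiency vector (SD = 0) yields no hubs.
    """
    eff = np.asarray(efficiency, dtype=float)
    sd = eff.std(ddof=1)
    if sd <= 1e-12 * max(1.0, float(np.abs(eff).max())):  # numerically constant
        return np.zeros(eff.shape, dtype=bool)
    return eff >= eff.mean() + sd


def rewired_null(
    matrix: ConnectivityMatrix,
    n_nulls: int,
    swap_fraction: float = 0.5,
    n_iter: int = 1000,
    seed: int | None = None,
) -> list[ConnectivityMatrix]:
    """Ensemble of degree-preserving rewired null networks.

    Each null starts from the input network and attempts
    ``ceil(swap_fraction * n_edges)`` random double-edge swaps per sweep,
    for ``n_iter`` sweeps.  Swaps relocate edges together with their
    weights, so every null shares the input's binary degree sequence and
    total weight.  Deterministic for a fixed seed.
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    iu, iv = np.nonzero(np.triu(matrix.weights, k=1))
    m = iu.size
    if m < 2:
        raise ValueError("rewiring needs at least 2 edges")
    ew = matrix.weights[iu, iv]
    n_attempts = int(math.ceil(swap_fraction * m)) * int(n_iter)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_nulls)
    nulls = []
    n = matrix.n_nodes
    for s in child_seeds:
        u, v, w, successes = rewire_edges(iu, iv, ew, n, n_attempts, int(s))
        if successes == 0:
            raise ValueError(
                "graph admits no legal degree-preserving swap (too sparse)"
            )
        out = np.zeros((n, n))
        out[u, v] = w
        out[v, u] = w
        nulls.append(ConnectivityMatrix(out))
    return nulls


def small_world(
    matrix: ConnectivityMatrix,
    n_nulls: int = 100,
    swap_fraction: float = 0.5,
    n_iter: int = 1000,
    seed: int | None = None,
    binary_paths: bool = False,
) -> tuple[float, float, float, float, float]:
    """Small-world ratios against the rewired null ensemble.

    Returns ``(gamma, lam, sigma, c_rand, l_rand)`` with
    ``gamma = C_real / C_rand``, ``lam = L_real / L_rand`` and
    ``sigma = gamma / lam``; ``C_rand`` and ``L_rand`` are ensemble means.
    """
    _, c_real, _, _ = clustering_coefficient(matrix)
    l_real, _ = average_path_length(shortest_paths(matrix, binary=binary_paths))
    nulls = rewired_null(matrix, n_nulls, swap_fraction, n_iter, seed)
    c_rand = float(
        np.mean([clustering_coefficient(nm)[1] for nm in nulls])
    )
    l_rand = float(
        np.mean(
            [
                average_path_length(shortest_paths(nm, binary=binary_paths))[0]
                for nm in nulls
            ]
        )
    )
    if c_rand == 0 or l_rand == 0:
        raise ValueError("degenerate null ensemble: C_rand or L_rand is zero")
    gamma = c_real / c_rand
    lam = l_real / l_rand
    return gamma, lam, gamma / lam, c_rand, l_rand


def compute_global_measures(
    matrix: ConnectivityMatrix,
    n_nulls: int = 0,
    swap_fraction: float = 0.5,
    n_iter: int = 1000,
    seed: int | None = None,
    binary_paths: bool = False,
) -> GlobalMeasures:
    """All global measures of one network; nulls only when ``n_nulls > 0``."""
    paths = shortest_paths(matrix, binary=binary_paths)
    e_glob = global_efficiency(paths)
    e_loc_nodal, e_loc = local_efficiency(matrix, binary=binary_paths)
    c_nodal, c_global, e_i, k_i = clustering_coefficient(matrix)
    avg_path, excluded = average_path_length(paths)
    sw = {}
    if n_nulls > 0:
        gamma, lam, sigma, c_rand, l_rand = small_world(
            matrix, n_nulls, swap_fraction, n_iter, seed, binary_paths
        )
        sw = dict(gamma=gamma, lam=lam, sigma=sigma, c_rand=c_rand, l_rand=l_rand)
    return GlobalMeasures(
        e_glob=e_glob,
        e_loc=e_loc,
        e_loc_nodal=e_loc_nodal,
        clustering=c_global,
        clustering_nodal=c_nodal,
        subgraph_edges=e_i,
        subgraph_nodes=k_i,
        avg_path=avg_path,
        excluded_pairs=excluded,
        **sw,
    )


def compute_nodal_measures(matrix: ConnectivityMatrix) -> NodalMeasures:
    """Nodal efficiency vector and hub flags for one network."""
    eff = nodal_efficiency(shortest_paths(matrix))
    return NodalMeasures(efficiency=eff, hub_flags=identify_hubs(eff))
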