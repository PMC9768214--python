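"""Sparsity-thresholded binary graphs and small-world metrics.

A weighted PLI matrix is binarized by *proportional thresholding*: at
sparsity ``s`` the ``round(s * N(N-1)/2)`` strongest connections become
edges of an undirected graph. On that graph the pipeline computes

* clustering coefficient ``C_i = 2 #_i / (K_i (K_i - 1))`` (fraction of a
  node's neighbor pairs that are themselves linked) and its node mean C;
* characteristic path length L from BFS shortest paths — by default the
  harmonic mean ``N(N-1) / sum(1/L_ij)`` so that disconnected pairs
  (``L_ij = inf``) contribute zero rather than diverging, which makes
  ``L = 1/E_g``; an arithmetic mean over connected pairs is available;
* global efficiency ``E_g = mean(1/L_ij)`` and nodal local efficiency
  ``NE_loc(i)`` = global efficiency of the subgraph induced on i's
  neighbors (0 when the node has fewer than two neighbors);
* small-world indices ``gamma = C/C_random``, ``lambda = L/L_random``,
  ``sigma = gamma/lambda`` against degree-preserving rewired references;
  ``sigma > 1`` marks small-world topology.

Metrics are averaged over a 5-40% sparsity grid (5% steps) because no
single threshold is privileged for a PLI network.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from ._kernels import (
    bfs_all_distances,
    local_efficiency_nodes,
    maslov_sneppen_rewire,
)
from .connectivity import PLIMatrix

__all__ = [
    "BinaryGraph",
    "SmallWorldMetrics",
    "DEFAULT_SPARSITY_GRID",
    "threshold_by_sparsity",
    "clustering",
    "characteristic_path_length",
    "global_efficiency",
    "nodal_local_efficiency",
    "local_efficiency",
    "random_reference",
    "small_world_indices",
    "compute_metrics",
    "sparsity_sweep",
    "average_metrics",
]

logger = logging.getLogger(__name__)

#: 5% to 40% in 5% steps — the averaging range for all reported metrics.
DEFAULT_SPARSITY_GRID: tuple[float, ...] = tuple(
    round(0.05 * k, 2) for k in range(1, 9)
)

DEFAULT_N_REALIZATIONS = 20
_SWAPS_PER_EDGE = 10


@dataclass
class BinaryGraph:
    """Undirected, unweighted graph as a symmetric 0/1 adjacency matrix."""

    adjacency: np.ndarray
    sparsity: float | None = None
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = a.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    def edge_list(self) -> np.ndarray:
        """(E, 2) array of i<j edges in lexicographic order."""
        iu = np.triu_indices(self.n_nodes, k=1)
        mask = self.adjacency[iu] == 1
        return np.column_stack((iu[0][mask], iu[1][mask])).astype(np.int64)


@dataclass
class SmallWorldMetrics:
    """Small-world parameter set of one graph (or a sparsity-range average)."""

    C: float
    L: float
    gamma: float
    lam: float
    sigma: float
    E_g: float
    E_loc: float
    C_i: np.ndarray = field(repr=False)
    NE_loc: np.ndarray = field(repr=False)
    K_i: np.ndarray = field(repr=False)
    sparsity: float | None = None

    def as_dict(self) -> dict[str, float]:
        return {
            "C": self.C,
            "L": self.L,
            "gamma": self.gamma,
            "lambda": self.lam,
            "sigma": self.sigma,
            "E_g": self.E_g,
            "E_loc": self.E_loc,
        }


def threshold_by_sparsity(conn: PLIMatrix, sparsity: float) -> BinaryGraph:
    """Keep the round(sparsity * N(N-1)/2) strongest connections as edges.

    Rounding is half-up; ties at the cutoff are broken by lexicographic
    (i, j) channel-pair order so the graph is deterministic. For tie-free
    weights the edge sets are nested across increasing sparsity.
    """
    if not 0.0 < sparsity <= 1.0:
        raise ValueError(f"sparsity must be in (0, 1], got {sparsity}")
    n = conn.n_channels
    n_possible = n * (n - 1) // 2
    n_edges = int(math.floor(sparsity * n_possible + 0.5))
    iu = np.triu_indices(n, k=1)
    weights = conn.values[iu]
    # stable sort over lexicographically ordered pairs -> deterministic ties
    order = np.argsort(-weights, kind="stable")[:n_edges]
    adjacency = np.zeros((n, n), dtype=np.uint8)
    adjacency[iu[0][order], iu[1][order]] = 1
    adjacency |= adjacency.T
    return BinaryGraph(
        adjacency=adjacency, sparsity=sparsity, channel_names=conn.channel_names
    )


def clustering(graph: BinaryGraph) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients and their mean over all N nodes.

    Nodes of degree < 2 have no neighbor pair and score 0 by convention.
    """
    a = graph.adjacency.astype(np.float64)
    k = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2.0  # edges among each node's neighbors
    denom = k * (k - 1) / 2.0
    c_i = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1.0), 0.0)
    return c_i, float(c_i.mean())


def _distance_matrix(adjacency: np.ndarray) -> np.ndarray:
    return bfs_all_distances(np.ascontiguousarray(adjacency))


def _efficiency_from_distances(dist: np.ndarray) -> float:
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    d = dist[off]
    inv = np.where(np.isinf(d), 0.0, 1.0 / np.where(d > 0, d, 1.0))
    return float(inv.mean())


def _bfs_distances_dense(adjacency: np.ndarray) -> np.ndarray:
    """All-pairs BFS distances by boolean matrix expansion (small graphs)."""
    n = adjacency.shape[0]
    a = adjacency.astype(bool)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    known = np.eye(n, dtype=bool)
    reach = a.copy()
    d = 1
    while True:
        new = reach & ~known
        if not new.any():
            return dist
        dist[new] = d
        known |= new
        d += 1
        reach = (reach.astype(np.uint8) @ a.astype(np.uint8)) > 0


def characteristic_path_length(
    graph: BinaryGraph, method: str = "harmonic"
) -> tuple[float, np.ndarray]:
    """Characteristic path length L and the full BFS distance matrix.

    ``method="harmonic"`` (default): N(N-1)/sum(1/L_ij) with disconnected
    pairs contributing 0 to the sum, i.e. L = 1/E_g — finite for any graph
    with at least one edge. ``method="arithmetic"``: plain mean of L_ij
    over connected pairs only (infinite if there are no connected pairs).
    """
    n = graph.n_nodes
    if n < 2:
        raise ValueError("path length needs at least two nodes")
    dist = _distance_matrix(graph.adjacency)
    off = ~np.eye(n, dtype=bool)
    d = dist[off]
    if method == "harmonic":
        inv = np.where(np.isinf(d), 0.0, 1.0 / np.where(d > 0, d, 1.0))
        total = inv.sum()
        length = float(n * (n - 1) / total) if total > 0 else math.inf
    elif method == "arithmetic":
        finite = d[np.isfinite(d)]
        length = float(finite.mean()) if finite.size else math.inf
    else:
        raise ValueError(f"unknown path-length method {method!r}")
    return length, dist


def global_efficiency(graph: BinaryGraph) -> float:
    """Mean inverse shortest-path length over ordered node pairs."""
    n = graph.n_nodes
    if n < 2:
        raise ValueError("efficiency needs at least two nodes")
    dist = _distance_matrix(graph.adjacency)
    off = ~np.eye(n, dtype=bool)
    d = dist[off]
    inv = np.where(np.isinf(d), 0.0, 1.0 / np.where(d > 0, d, 1.0))
    return float(inv.mean())


def nodal_local_efficiency(graph: BinaryGraph, node: int) -> float:
    """Global efficiency of the subgraph induced on the node's neighbors.

    0 by convention for nodes with fewer than two neighbors.
    """
    if not 0 <= node < graph.n_nodes:
        raise IndexError(f"node {node} out of range for N={graph.n_nodes}")
    neighbors = np.flatnonzero(graph.adjacency[node])
    if neighbors.size < 2:
        return 0.0
    sub = graph.adjacency[np.ix_(neighbors, neighbors)]
    return _efficiency_from_distances(_bfs_distances_dense(sub))


def local_efficiency(graph: BinaryGraph) -> tuple[np.ndarray, float]:
    """Per-node local efficiencies NE_loc and their mean E_loc."""
    ne = local_efficiency_nodes(np.ascontiguousarray(graph.adjacency))
    return ne, float(ne.mean())


def _erdos_renyi_adjacency(n: int, n_edges: int, rng: np.random.Generator) -> np.ndarray:
    iu = np.triu_indices(n, k=1)
    chosen = rng.choice(iu[0].size, size=n_edges, replace=False)
    adjacency = np.zeros((n, n), dtype=np.uint8)
    adjacency[iu[0][chosen], iu[1][chosen]] = 1
    return adjacency | adjacency.T


def random_reference(
    graph: BinaryGraph,
    n_realizations: int = DEFAULT_N_REALIZATIONS,
    seed: int = 0,
    path_method: str = "harmonic",
) -> tuple[float, float]:
    """(C_random, L_random): null clustering and path length for the graph.

    Each realization applies 10 x |E| successful Maslov-Sneppen swaps,
    preserving every node degree. If the graph admits no valid swap the
    realization falls back to an Erdos-Renyi graph with matched N and |E|
    (logged). Returns means over realizations.

    Very sparse graphs can produce a triangle-free batch (C_random = 0,
    which would make gamma undefined); in that case additional batches are
    drawn deterministically, up to 10x the requested count, and as a last
    resort C_random falls back to the configuration-model expectation
    (<k^2> - <k>)^2 / (N <k>^3).
    """
    if graph.n_edges < 2:
        raise ValueError("random reference needs a graph with >= 2 edges")
    if n_realizations < 1:
        raise ValueError("need at least one realization")
    rng = np.random.default_rng(seed)
    base_edges = graph.edge_list()
    n = graph.n_nodes
    target = _SWAPS_PER_EDGE * base_edges.shape[0]
    off = ~np.eye(n, dtype=bool)

    def one_realization() -> tuple[float, float]:
        adjacency = np.ascontiguousarray(graph.adjacency.copy())
        edges = base_edges.copy()
        swap_seed = int(rng.integers(1, 2**31 - 1))
        done = maslov_sneppen_rewire(
            adjacency, edges, target, 100 * target, swap_seed
        )
        if done == 0:
            logger.warning(
                "graph admits no degree-preserving swap; falling back to "
                "Erdos-Renyi with N=%d, E=%d", graph.n_nodes, graph.n_edges
            )
            adjacency = _erdos_renyi_adjacency(graph.n_nodes, graph.n_edges, rng)
        a = adjacency.astype(np.float64)
        k = a.sum(axis=1)
        triangles = np.diag(a @ a @ a) / 2.0
        denom = k * (k - 1) / 2.0
        c_i = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1.0), 0.0)
        d = _distance_matrix(adjacency)[off]
        if path_method == "harmonic":
            inv = np.where(np.isinf(d), 0.0, 1.0 / np.where(d > 0, d, 1.0))
            total = inv.sum()
            length = n * (n - 1) / total if total > 0 else math.inf
        else:
            finite = d[np.isfinite(d)]
            length = finite.mean() if finite.size else math.inf
        return float(c_i.mean()), float(length)

    c_vals: list[float] = []
    l_vals: list[float] = []
    for _ in range(n_realizations):
        c, length = one_realization()
        c_vals.append(c)
        l_vals.append(length)
    extra_batches = 0
    while sum(c_vals) == 0.0 and extra_batches < 9:
        extra_batches += 1
        for _ in range(n_realizations):
            c, length = one_realization()
            c_vals.append(c)
            l_vals.append(length)
    c_random = float(np.mean(c_vals))
    if c_random == 0.0:
        k = graph.degrees.astype(np.float64)
        m1, m2 = k.mean(), (k * k).mean()
        c_random = float((m2 - m1) ** 2 / (n * m1**3)) if m1 > 0 else 0.0
        logger.debug(
            "all rewired references triangle-free; using configuration-"
            "model clustering expectation %.3g", c_random
        )
    return c_random, float(np.mean(l_vals))


def small_world_indices(
    graph_c: float, graph_l: float, reference: tuple[float, float]
) -> tuple[float, float, float]:
    """(gamma, lambda, sigma) from observed C, L and null (C_random, L_random)."""
    c_random, l_random = reference
    if c_random <= 0 or l_random <= 0:
        raise ValueError(
            f"degenerate random reference (C_random={c_random}, "
            f"L_random={l_random}); cannot normalize"
        )
    gamma = graph_c / c_random
    lam = graph_l / l_random
    sigma = gamma / lam
    return gamma, lam, sigma


def compute_metrics(
    graph: BinaryGraph,
    n_realizations: int = DEFAULT_N_REALIZATIONS,
    seed: int = 0,
    path_method: str = "harmonic",
) -> SmallWorldMetrics:
    """Full small-world parameter set of one binary graph."""
    c_i, c = clustering(graph)
    length, dist = characteristic_path_length(graph, method=path_method)
    e_g = _efficiency_from_distances(dist)
    ne_loc, e_loc = local_efficiency(graph)
    reference = random_reference(
        graph, n_realizations=n_realizations, seed=seed, path_method=path_method
    )
    gamma, lam, sigma = small_world_indices(c, length, reference)
    return SmallWorldMetrics(
        C=c, L=length, gamma=gamma, lam=lam, sigma=sigma,
        E_g=e_g, E_loc=e_loc, C_i=c_i, NE_loc=ne_loc,
        K_i=graph.degrees, sparsity=graph.sparsity,
    )


def sparsity_sweep(
    conn: PLIMatrix,
    grid: tuple[float, ...] = DEFAULT_SPARSITY_GRID,
    n_realizations: int = DEFAULT_N_REALIZATIONS,
    seed: int = 0,
    path_method: str = "harmonic",
) -> tuple[list[SmallWorldMetrics], SmallWorldMetrics]:
    """Metrics at every grid sparsity plus their range average.

    Indices (gamma, lambda, sigma) are computed per sparsity and then
    averaged, matching the 5-40% averaging protocol.
    """
    if len(grid) == 0:
        raise ValueError("sparsity grid is empty")
    for s in grid:
        if not 0.0 < s <= 1.0:
            raise ValueError(f"sparsity grid value {s} outside (0, 1]")
    rng = np.random.default_rng(seed)
    per_sparsity = []
    for s in grid:
        graph = threshold_by_sparsity(conn, s)
        per_sparsity.append(
            compute_metrics(
                graph,
                n_realizations=n_realizations,
                seed=int(rng.integers(1, 2**31 - 1)),
                path_method=path_method,
            )
        )
    return per_sparsity, average_metrics(per_sparsity)


def average_metrics(metrics: list[SmallWorldMetrics]) -> SmallWorldMetrics:
    """Arithmetic mean of each metric over a list (e.g. a sparsity range)."""
    if not metrics:
        raise ValueError("no metrics to average")
    return SmallWorldMetrics(
        C=float(np.mean([m.C for m in metrics])),
        L=float(np.mean([m.L for m in metrics])),
        gamma=float(np.mean([m.gamma for m in metrics])),
        lam=float(np.mean([m.lam for m in metrics])),
        sigma=float(np.mean([m.sigma for m in metrics])),
        E_g=float(np.mean([m.E_g for m in metrics])),
        E_loc=float(np.mean([m.E_loc for m in metrics])),
        C_i=np.mean([m.C_i for m in metrics], axis=0),
        NE_loc=np.mean([m.NE_loc for m in metrics], axis=0),
        K_i=np.mean([m.K_i for m in metrics], axis=0),
        sparsity=None,
    )
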