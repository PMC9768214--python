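"""JIT-compiled hot loops: BFS distances, local efficiency, PLI sign
counting, and degree-preserving (Maslov-Sneppen) edge rewiring.

The Monte-Carlo suites (hundreds of full pipeline repetitions, each
rewiring dozens of graphs) make these loops the runtime bottleneck, so
they are numba-compiled. Everything here operates on plain arrays; the
typed containers live in the public modules.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def bfs_all_distances(adjacency):
    """All-pairs shortest-path lengths of an undirected 0/1 adjacency.

    Returns float64 matrix with np.inf for unreachable pairs.
    """
    n = adjacency.shape[0]
    dist = np.full((n, n), np.inf)
    queue = np.empty(n, dtype=np.int64)
    for src in range(n):
        dist[src, src] = 0.0
        head = 0
        tail = 0
        queue[tail] = src
        tail += 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[src, u]
            for v in range(n):
                if adjacency[u, v] == 1 and np.isinf(dist[src, v]):
                    dist[src, v] = du + 1.0
                    queue[tail] = v
                    tail += 1
    return dist


@njit(cache=True)
def local_efficiency_nodes(adjacency):
    """Per-node local efficiency: global efficiency of each neighbor
    subgraph (0 for nodes with fewer than two neighbors)."""
    n = adjacency.shape[0]
    out = np.zeros(n)
    neighbors = np.empty(n, dtype=np.int64)
    for node in range(n):
        m = 0
        for v in range(n):
            if adjacency[node, v] == 1:
                neighbors[m] = v
                m += 1
        if m < 2:
            continue
        sub = np.empty((m, m), dtype=adjacency.dtype)
        for a in range(m):
            for b in range(m):
                sub[a, b] = adjacency[neighbors[a], neighbors[b]]
        dist = bfs_all_distances(sub)
        acc = 0.0
        for a in range(m):
            for b in range(m):
                if a != b and not np.isinf(dist[a, b]):
                    acc += 1.0 / dist[a, b]
        out[node] = acc / (m * (m - 1))
    return out


@njit(cache=True)
def pli_signs(x, y):
    """|mean sign(sin(phi_i - phi_j))| for all channel pairs.

    x, y: cos/sin of the phase block, shape (channels, samples).
    sign(sin(a-b)) equals the sign of the wrapped phase difference
    everywhere except the measure-zero point dphi = pi.
    """
    n_ch, n_s = x.shape
    out = np.zeros((n_ch, n_ch))
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            acc = 0.0
            for t in range(n_s):
                cross = y[i, t] * x[j, t] - x[i, t] * y[j, t]
                if cross > 0.0:
                    acc += 1.0
                elif cross < 0.0:
                    acc -= 1.0
            v = abs(acc) / n_s
            out[i, j] = v
            out[j, i] = v
    return out


@njit(cache=True)
def maslov_sneppen_rewire(adjacency, edges, target_swaps, max_attempts, seed):
    """Rewire ``adjacency``/``edges`` in place; return successful swap count.

    adjacency : (N, N) uint8, symmetric, zero diagonal (mutated)
    edges : (E, 2) int64 edge list (mutated)
    """
    np.random.seed(seed)
    n_edges = edges.shape[0]
    successes = 0
    attempts = 0
    while successes < target_swaps and attempts < max_attempts:
        attempts += 1
        e1 = np.random.randint(n_edges)
        e2 = np.random.randint(n_edges)
        if e1 == e2:
            continue
        a = edges[e1, 0]
        b = edges[e1, 1]
        c = edges[e2, 0]
        d = edges[e2, 1]
        if np.random.randint(2) == 1:
            c, d = d, c
        # proposed replacement: (a-b),(c-d) -> (a-d),(c-b)
        if a == b or c == d or a == c or a == d or b == c or b == d:
            continue
        if adjacency[a, d] == 1 or adjacency[c, b] == 1:
            continue
        adjacency[a, b] = 0
        adjacency[b, a] = 0
        adjacency[c, d] = 0
        adjacency[d, c] = 0
        adjacency[a, d] = 1
        adjacency[d, a] = 1
        adjacency[c, b] = 1
        adjacency[b, c] = 1
        edges[e1, 0] = a
        edges[e1, 1] = d
        edges[e2, 0] = c
        edges[e2, 1] = b
        successes += 1
    return successes
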