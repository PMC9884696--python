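"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library routines they check: centralities are
computed by explicit all-pairs geodesic enumeration over adjacency sets,
clustering by direct triangle counting, and the hypergeometric tail by
exact rational arithmetic.  Intended for graphs of at most a few dozen
nodes.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def _adjacency(edges, nodes=None):
    adj: dict = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    for n in nodes or ():
        adj.setdefault(n, set())
    return adj


def _bfs_distances(adj, source):
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def _all_geodesics(adj, dist_s, s, t):
    """Every shortest path from s to t as a node tuple."""
    if t not in dist_s:
        return []
    if s == t:
        return [(s,)]
    paths = []
    for u in adj[t]:
        if dist_s.get(u) == dist_s[t] - 1:
            paths.extend(p + (t,) for p in _all_geodesics(adj, dist_s, s, u))
    return paths


def brute_betweenness(edges, nodes):
    """Normalized betweenness by explicit geodesic enumeration.

    Fraction of shortest paths through each node over unordered pairs of
    distinct other nodes, normalized by (n-1)(n-2)/2 with n the
    whole-graph node count.
    """
    nodes = sorted(nodes)
    adj = _adjacency(edges, nodes)
    n = len(nodes)
    score = {v: Fraction(0) for v in nodes}
    if n < 3:
        return {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        dist_s = _bfs_distances(adj, s)
        for t in nodes[i + 1 :]:
            paths = _all_geodesics(adj, dist_s, s, t)
            if not paths:
                continue
            for v in nodes:
                if v == s or v == t:
                    continue
                through = sum(1 for p in paths if v in p[1:-1])
                score[v] += Fraction(through, len(paths))
    norm = Fraction((n - 1) * (n - 2), 2)
    return {v: float(score[v] / norm) for v in nodes}


def brute_closeness(edges, nodes):
    """Component-local closeness: (c-1) / sum of distances in component."""
    nodes = sorted(nodes)
    adj = _adjacency(edges, nodes)
    out = {}
    for v in nodes:
        dist = _bfs_distances(adj, v)
        total = sum(dist.values())
        out[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def brute_clustering(edges, nodes):
    """Triangle-count clustering; 0 for degree < 2."""
    nodes = sorted(nodes)
    adj = _adjacency(edges, nodes)
    out = {}
    for v in nodes:
        nbrs = sorted(adj[v])
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(
            1
            for i in range(k)
            for j in range(i + 1, k)
            if nbrs[j] in adj[nbrs[i]]
        )
        out[v] = links / (k * (k - 1) / 2)
    return out


def brute_degree(edges, nodes):
    adj = _adjacency(edges, nodes)
    return {v: len(adj[v]) for v in adj}


def exact_hypergeom_tail(k, K, n, N):
    """P(X >= k) as an exact Fraction, by direct combinatorial summation."""
    numer = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return Fraction(numer, comb(N, n))


def exact_hypergeom_tails(K, n, N):
    """Exact tail for every k in 0..min(K, n), as Fractions (suffix sums)."""
    kmax = min(K, n)
    pmf = [comb(K, i) * comb(N - K, n - i) for i in range(kmax + 1)]
    denom = comb(N, n)
    tails = [Fraction(0)] * (kmax + 1)
    running = 0
    for i in range(kmax, -1, -1):
        running += pmf[i]
        tails[i] = Fraction(running, denom)
    return tails


def stepup_bh(p_values):
    """Literal BH step-up: p_adj(i) = min over j >= i of min(1, p(j) m / j)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adj_sorted = [
        min(
            min(1.0, p_values[order[j]] * m / (j + 1))
            for j in range(i, m)
        )
        for i in range(m)
    ]
    out = [0.0] * m
    for i, idx in enumerate(order):
        out[idx] = adj_sorted[i]
    return out
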