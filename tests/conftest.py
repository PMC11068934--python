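"""Shared fixtures and independent oracles for the test suite.

Oracles here are deliberately written against different primitives than the
implementation (boolean matrix powers instead of BFS, exact rational
hypergeometric tails instead of scipy's Fisher test, explicit triangle
enumeration instead of networkx clustering) so they can referee it.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from keydriver.network import GeneNetwork


@pytest.fixture
def chain_net() -> GeneNetwork:
    """A -> B -> C."""
    return GeneNetwork([("A", "B"), ("B", "C")])


@pytest.fixture
def diamond_net() -> GeneNetwork:
    """A -> {B, C} -> D."""
    return GeneNetwork([("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")])


def random_dag(n_nodes: int, edge_prob: float, rng: np.random.Generator) -> GeneNetwork:
    """Random DAG via upper-triangular edge sampling."""
    names = [f"g{i:02d}" for i in range(n_nodes)]
    edges = [
        (names[i], names[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < edge_prob
    ]
    return GeneNetwork(edges, nodes=names)


def downstream_by_matrix_powers(net: GeneNetwork, gene: str, max_d: int) -> dict[int, set[str]]:
    """Exact-distance downstream sets via boolean adjacency-matrix powers.

    Distance-d set = nodes first reached at power d (shortest-path masking).
    """
    nodes = sorted(net.nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=bool)
    for u, v in net.edges():
        adj[idx[u], idx[v]] = True
    reached = np.zeros(n, dtype=bool)
    reached[idx[gene]] = True
    frontier = reached.copy()
    out: dict[int, set[str]] = {}
    for d in range(1, max_d + 1):
        frontier = (frontier @ adj) & ~reached
        out[d] = {nodes[i] for i in np.nonzero(frontier)[0]}
        reached |= frontier
    return out


def hypergeom_upper_tail(x: int, big_n: int, big_k: int, n_draw: int) -> float:
    """Pr(X >= x) for a hypergeometric draw, by exact rational enumeration."""
    total = comb(big_n, n_draw)
    acc = Fraction(0)
    for k in range(x, min(big_k, n_draw) + 1):
        if n_draw - k <= big_n - big_k:
            acc += Fraction(comb(big_k, k) * comb(big_n - big_k, n_draw - k), total)
    return float(acc)


def brute_force_clustering(net: GeneNetwork) -> float:
    """Mean local clustering of the undirected projection by triangle counting."""
    und: dict[str, set[str]] = {v: set() for v in net.nodes}
    for u, v in net.edges():
        und[u].add(v)
        und[v].add(u)
    total = 0.0
    for v, nbrs in und.items():
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1
            for a in nbrs
            for b in nbrs
            if a < b and b in und[a]
        )
        total += 2.0 * links / (k * (k - 1))
    return total / len(und)


def brute_force_path_length(net: GeneNetwork) -> float:
    """Mean directed shortest-path length over reachable pairs, by per-pair BFS."""
    from collections import deque

    nodes = sorted(net.nodes)
    children = {v: set() for v in nodes}
    for u, v in net.edges():
        children[u].add(v)
    total, pairs = 0, 0
    for s in nodes:
        dist = {s: 0}
        q = deque([s])
        while q:
            u = q.popleft()
            for v in children[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        for t, d in dist.items():
            if t != s:
                total += d
                pairs += 1
    if pairs == 0:
        raise ValueError("no reachable pair")
    return total / pairs
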