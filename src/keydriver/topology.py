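"""Scale-free / small-world topology diagnostics for gene networks.

Biological regulatory networks typically show (i) a power-law out-degree
distribution ``P(k) ~ k^-a`` with exponent a in roughly 2-3 — a few hub
regulators with many downstream genes — and (ii) small-world structure:
clustering well above, and mean path length comparable to, a random graph
of the same size.  This module computes those diagnostics for a
:class:`~keydriver.network.GeneNetwork` and compares them against uniform
random directed graphs with matched node and edge counts.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np

from .network import GeneNetwork

__all__ = [
    "TopologyReport",
    "degree_exponent",
    "clustering_coefficient",
    "average_path_length",
    "compare_to_random",
    "out_degree_distribution",
]


@dataclass(frozen=True)
class TopologyReport:
    """Observed metrics alongside random-graph baselines of the same size."""

    n_nodes: int
    n_edges: int
    degree_exponent: float
    fit_r_squared: float
    clustering_coefficient: float
    average_path_length: float
    random_clustering: float
    random_path_length: float

    def as_dict(self) -> dict:
        return asdict(self)


def out_degree_distribution(net: GeneNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Empirical distribution of out-degree over parents (out-degree >= 1).

    Returns ``(k, P(k))`` where ``P(k)`` is the fraction of parent nodes
    with out-degree ``k``.  Zero-out-degree nodes are excluded (log of a
    zero degree is undefined in the power-law fit).
    """
    degrees = np.array([d for _, d in net.graph.out_degree() if d >= 1])
    if degrees.size == 0:
        raise ValueError("network has no parents (no out-edges)")
    k, counts = np.unique(degrees, return_counts=True)
    return k, counts / degrees.size


def degree_exponent(net: GeneNetwork) -> tuple[float, float]:
    """Power-law exponent of the out-degree distribution via a log-log line fit.

    Fits ``log P(k) = -a log k + b`` by least squares on the unbinned
    empirical distribution, weighting each distinct degree by the number of
    parents that carry it (a fit over nodes rather than over distinct
    degrees; the unweighted fit is biased low by the singleton degrees in
    the tail).  Returns ``(a, r_squared)`` with the weighted coefficient of
    determination; exactly collinear log-log points give ``r_squared = 1``.
    """
    k, p = out_degree_distribution(net)
    if k.size < 2:
        raise ValueError(
            "all parents share one out-degree; power-law fit undefined"
        )
    x = np.log(k.astype(float))
    y = np.log(p)
    degrees = np.array([d for _, d in net.graph.out_degree() if d >= 1])
    _, counts = np.unique(degrees, return_counts=True)
    w = counts.astype(float)
    slope, intercept = np.polyfit(x, y, 1, w=w)
    resid = y - (slope * x + intercept)
    w2 = w * w
    ybar = np.average(y, weights=w2)
    ss_tot = float(np.sum(w2 * (y - ybar) ** 2))
    ss_res = float(np.sum(w2 * resid**2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(-slope), float(r2)


def clustering_coefficient(net: GeneNetwork) -> float:
    """Mean local clustering coefficient of the undirected projection.

    Per node: triangles over connected triples; nodes of degree < 2
    contribute 0.  The small-world clustering metric is defined for
    undirected graphs, so edge directions are dropped.
    """
    if net.n_nodes < 3:
        raise ValueError("need >= 3 nodes for a clustering coefficient")
    und = nx.Graph(net.graph)
    return float(nx.average_clustering(und, count_zeros=True))


def average_path_length(net: GeneNetwork) -> float:
    """Mean directed shortest-path length over reachable ordered pairs.

    Pairs ``(u, v)`` with ``v`` unreachable from ``u`` are excluded; raises
    if no ordered pair is reachable at all.
    """
    total = 0
    n_pairs = 0
    for source in net.graph.nodes:
        lengths = nx.single_source_shortest_path_length(net.graph, source)
        total += sum(lengths.values())  # distance to self is 0
        n_pairs += len(lengths) - 1
    if n_pairs == 0:
        raise ValueError("no reachable ordered pair; path length undefined")
    return total / n_pairs


def compare_to_random(
    net: GeneNetwork, n_random: int = 20, seed: int = 0
) -> TopologyReport:
    """Topology report with uniform random-graph (same |V|, |E|) baselines.

    Random graphs are directed G(n, m) draws without self-edges; the report
    carries the mean clustering and mean path length over ``n_random``
    replicates.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    n, m = net.n_nodes, net.n_edges
    if m > n * (n - 1):
        raise ValueError("edge count exceeds the directed-graph maximum")
    a, r2 = degree_exponent(net)
    clustering = clustering_coefficient(net)
    path_length = average_path_length(net)
    rng = np.random.default_rng(seed)
    rand_c, rand_l = [], []
    for _ in range(n_random):
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)), directed=True)
        rnet = GeneNetwork(((str(u), str(v), 1.0) for u, v in g.edges),
                           nodes=(str(x) for x in g.nodes))
        rand_c.append(clustering_coefficient(rnet))
        try:
            rand_l.append(average_path_length(rnet))
        except ValueError:  # edgeless draw cannot happen for m>=1; guard anyway
            pass
    return TopologyReport(
        n_nodes=n,
        n_edges=m,
        degree_exponent=a,
        fit_r_squared=r2,
        clustering_coefficient=clustering,
        average_path_length=path_length,
        random_clustering=float(np.mean(rand_c)),
        random_path_length=float(np.mean(rand_l)),
    )
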