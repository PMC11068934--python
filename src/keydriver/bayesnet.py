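"""Consensus Bayesian-network structure learning over discretized expression.

The model is a discrete Bayesian network: each gene is a three-level
variable (low/medium/high) and the joint distribution factorizes over
node-given-parents conditional probability tables, ``P(X) = prod_i
P(X_i | D_i)`` with ``D_i`` the parent set of gene ``i``.  Structures are
scored per family by the Bayesian Information Criterion

    BIC = k * ln(n) - 2 * ln(L)

with ``k = 2 * 3^|parents|`` free CPT parameters, ``n`` the number of
samples, and ``ln L`` the maximized multinomial log-likelihood of the
child's levels given each joint parent configuration.  Lower is better; the
total network score is the sum of family BICs minus an additive bonus for
every edge whose parent has cis-eQTL support (eGenes are favored, not
required, as parents).

Search is greedy hill-climbing (add / remove / reverse) restricted to
candidate-parent pairs derived from pairwise Pearson correlations of the
continuous data at significance ``P < alpha`` — a desk-scale stand-in for a
Markov-blanket candidate search — under an acyclicity constraint and an
in-degree cap.  Many seeded runs are merged into a consensus network
keeping edges present in at least a fixed fraction of runs (default 30%),
and remaining directed cycles are broken by deleting minimum-confidence
edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .network import GeneNetwork, GeneSet
from .preprocess import LEVELS, discretize_kmeans, encode_levels

__all__ = [
    "PriorSet",
    "FamilyScore",
    "LearnConfig",
    "correlation_priors",
    "family_bic",
    "learn_single",
    "learn_consensus",
    "consensus_merge",
    "break_cycles",
    "ConsensusNetworkLearner",
]


@dataclass(frozen=True)
class PriorSet:
    """Structure-learning priors: correlation candidates and eGene flags.

    ``candidate_parents[g]`` is the set of genes whose Pearson correlation
    with ``g`` reaches ``P < alpha`` on the continuous data; the relation is
    symmetric before orientation.  ``egenes`` carry an additive score bonus
    when they act as parents.
    """

    candidate_parents: dict[str, frozenset[str]]
    egenes: frozenset[str] = frozenset()
    alpha: float = 0.01


@dataclass(frozen=True)
class FamilyScore:
    """BIC decomposition for one node given a parent set (lower bic = better)."""

    node: str
    parents: frozenset[str]
    log_likelihood: float
    param_count: int
    sample_count: int

    @property
    def bic(self) -> float:
        return self.param_count * np.log(self.sample_count) - 2.0 * self.log_likelihood


@dataclass(frozen=True)
class LearnConfig:
    """Hill-climbing and consensus parameters.

    ``n_seeds`` defaults to a desk-scale 25 independent runs (the published
    pipeline used 1,000); ``consensus_fraction`` keeps edges present in at
    least that fraction of runs.
    """

    n_seeds: int = 25
    consensus_fraction: float = 0.30
    max_parents: int = 3
    egene_bonus: float = 1.0
    alpha: float = 0.01
    max_candidate_parents: int | None = None
    max_passes: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.consensus_fraction <= 1:
            raise ValueError("consensus_fraction must be in (0, 1]")
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")


# -- correlation / eGene priors -------------------------------------------


def correlation_priors(
    mat: pd.DataFrame,
    alpha: float = 0.01,
    egenes: GeneSet | frozenset[str] | None = None,
    max_candidates: int | None = None,
) -> PriorSet:
    """Pairwise-Pearson candidate-parent priors from continuous expression.

    Parameters
    ----------
    mat
        Continuous genes x samples matrix (>= 3 samples).
    alpha
        Two-sided significance level for the correlation test.
    egenes
        Genes with cis-eQTL support, flagged as preferred parents.
    max_candidates
        Optional cap: keep only the ``max_candidates`` strongest
        (largest ``|r|``) partners per gene before symmetrizing.  Constant
        genes are excluded from the candidate relation with a warning.
    """
    n = mat.shape[1]
    if n < 3:
        raise ValueError(f"need >= 3 samples for correlation priors, got {n}")
    values = mat.to_numpy(dtype=float)
    sd = values.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s) excluded from correlation priors",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 1.0)  # a gene is never its own candidate parent
    p[constant, :] = 1.0
    p[:, constant] = 1.0
    genes = list(mat.index)
    significant = p < alpha
    candidates: dict[str, set[str]] = {g: set() for g in genes}
    idx_i, idx_j = np.nonzero(significant)
    if max_candidates is not None:
        keep = np.zeros_like(significant)
        absr = np.where(significant, np.abs(r), -np.inf)
        for i in range(len(genes)):
            hits = np.nonzero(significant[i])[0]
            if hits.size > max_candidates:
                top = hits[np.argsort(absr[i, hits], kind="stable")[::-1][:max_candidates]]
            else:
                top = hits
            keep[i, top] = True
        keep = keep | keep.T  # symmetric before orientation
        idx_i, idx_j = np.nonzero(keep)
    for i, j in zip(idx_i, idx_j):
        candidates[genes[i]].add(genes[j])
        candidates[genes[j]].add(genes[i])
    egene_members = frozenset(egenes.members if isinstance(egenes, GeneSet) else (egenes or ()))
    return PriorSet(
        candidate_parents={g: frozenset(s) for g, s in candidates.items()},
        egenes=egene_members,
        alpha=alpha,
    )


# -- family scoring --------------------------------------------------------


class _FamilyScorer:
    """Cached multinomial family log-likelihood / BIC over coded levels."""

    def __init__(self, codes: np.ndarray):
        self.codes = np.ascontiguousarray(codes, dtype=np.int64)
        self.n_samples = codes.shape[1]
        self._logn = float(np.log(self.n_samples))
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def loglik(self, node: int, parents: tuple[int, ...]) -> float:
        key = (node, parents)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        child = self.codes[node]
        if parents:
            config = self.codes[parents[0]].copy()
            for p in parents[1:]:
                config *= 3
                config += self.codes[p]
            joint = config * 3 + child
            counts = np.bincount(joint, minlength=3 ** (len(parents) + 1))
            counts = counts.reshape(-1, 3)
        else:
            counts = np.bincount(child, minlength=3)[None, :]
        totals = counts.sum(axis=1, keepdims=True)
        mask = counts > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = counts * (np.log(counts, where=mask, out=np.zeros_like(counts, dtype=float))
                                - np.log(totals, where=totals > 0,
                                         out=np.zeros_like(totals, dtype=float)))
        ll = float(contrib[mask].sum())
        self._cache[key] = ll
        return ll

    def bic(self, node: int, parents: tuple[int, ...]) -> float:
        k = 2 * 3 ** len(parents)
        return k * self._logn - 2.0 * self.loglik(node, parents)


def family_bic(
    levels: pd.DataFrame, node: str, parents: frozenset[str] | set[str] = frozenset()
) -> FamilyScore:
    """Score one family (node given parents) on a discretized genes x samples frame.

    ``ln L`` is the maximized multinomial log-likelihood of the node's
    levels within each observed joint parent configuration (unobserved
    configurations contribute zero); ``k = 2 * 3^|parents|``.
    """
    genes = list(levels.index)
    if node not in genes:
        raise KeyError(f"node {node!r} not in data")
    parents = frozenset(parents)
    missing = parents - set(genes)
    if missing:
        raise KeyError(f"parents not in data: {sorted(missing)}")
    codes = encode_levels(levels).to_numpy()
    scorer = _FamilyScorer(codes)
    index = {g: i for i, g in enumerate(genes)}
    ptuple = tuple(sorted(index[p] for p in parents))
    ll = scorer.loglik(index[node], ptuple)
    return FamilyScore(
        node=node,
        parents=parents,
        log_likelihood=ll,
        param_count=2 * 3 ** len(parents),
        sample_count=levels.shape[1],
    )


# -- hill climbing ---------------------------------------------------------


def _reaches(children: list[set[int]], source: int, target: int) -> bool:
    """True if ``target`` is reachable from ``source`` along directed edges."""
    if source == target:
        return True
    stack = [source]
    seen = {source}
    while stack:
        u = stack.pop()
        for v in children[u]:
            if v == target:
                return True
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return False


def _climb(
    scorer: _FamilyScorer,
    genes: list[str],
    priors: PriorSet,
    config: LearnConfig,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """One greedy hill-climbing run; returns the learned edge list (indices)."""
    index = {g: i for i, g in enumerate(genes)}
    egene = np.zeros(len(genes), dtype=bool)
    for g in priors.egenes:
        if g in index:
            egene[index[g]] = True
    pairs = [
        (index[p], index[c])
        for c in genes
        for p in sorted(priors.candidate_parents.get(c, ()))
        if p in index
    ]
    parents: list[set[int]] = [set() for _ in genes]
    children: list[set[int]] = [set() for _ in genes]
    bonus = config.egene_bonus

    def fam(node: int) -> float:
        return scorer.bic(node, tuple(sorted(parents[node])))

    def fam_with(node: int, pset: set[int]) -> float:
        return scorer.bic(node, tuple(sorted(pset)))

    eps = 1e-9
    for _ in range(config.max_passes):
        improved = False
        order = rng.permutation(len(pairs))
        for k in order:
            p, c = pairs[k]
            if c in children[p]:  # edge present: try remove or reverse
                base_c = fam(c)
                reduced = parents[c] - {p}
                d_remove = fam_with(c, reduced) - base_c + (bonus if egene[p] else 0.0)
                best, delta = "remove", d_remove
                children[p].discard(c)
                parents[c].discard(p)
                can_reverse = (
                    len(parents[p]) < config.max_parents
                    and not _reaches(children, p, c)
                )
                if can_reverse:
                    d_rev = (
                        d_remove
                        + fam_with(p, parents[p] | {c})
                        - fam(p)
                        - (bonus if egene[c] else 0.0)
                    )
                    if d_rev < delta:
                        best, delta = "reverse", d_rev
                if delta < -eps:
                    if best == "reverse":
                        children[c].add(p)
                        parents[p].add(c)
                    improved = True
                else:  # restore
                    children[p].add(c)
                    parents[c].add(p)
            else:  # edge absent: try add
                if len(parents[c]) >= config.max_parents:
                    continue
                if _reaches(children, c, p):  # would create a cycle
                    continue
                d_add = (
                    fam_with(c, parents[c] | {p})
                    - fam(c)
                    - (bonus if egene[p] else 0.0)
                )
                if d_add < -eps:
                    children[p].add(c)
                    parents[c].add(p)
                    improved = True
        if not improved:
            break
    return [(p, c) for p in range(len(genes)) for c in children[p]]


def learn_single(
    levels: pd.DataFrame,
    priors: PriorSet,
    config: LearnConfig | None = None,
    seed: int = 0,
) -> GeneNetwork:
    """One seeded hill-climbing run over a discretized genes x samples frame.

    Returns a DAG over all input genes (edges confidence 1.0).  Randomness
    enters only through the move-evaluation order.
    """
    if levels.empty:
        raise ValueError("no genes in discretized data")
    config = config or LearnConfig()
    genes = list(levels.index)
    scorer = _FamilyScorer(encode_levels(levels).to_numpy())
    rng = np.random.default_rng(seed)
    edges = _climb(scorer, genes, priors, config, rng)
    return GeneNetwork(
        [(genes[p], genes[c], 1.0) for p, c in edges], nodes=genes
    )


def consensus_merge(
    networks: list[GeneNetwork], fraction: float = 0.30
) -> GeneNetwork:
    """Merge seeded runs, retaining edges present in >= ``fraction`` of them.

    The retained edge's confidence is its occurrence frequency.  The result
    may contain directed cycles (individual runs are DAGs but their union
    need not be); follow with :func:`break_cycles`.
    """
    if not networks:
        raise ValueError("no networks to merge")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    counts: dict[tuple[str, str], int] = {}
    nodes: set[str] = set()
    for net in networks:
        nodes |= net.nodes
        for e in net.edges():
            counts[e] = counts.get(e, 0) + 1
    m = len(networks)
    edges = [
        (p, c, k / m) for (p, c), k in counts.items() if k / m >= fraction - 1e-12
    ]
    return GeneNetwork(edges, nodes=nodes)


def break_cycles(net: GeneNetwork) -> GeneNetwork:
    """Delete minimum-confidence cycle edges until the network is acyclic.

    While a directed cycle exists, the lowest-confidence edge lying on any
    cycle (ties broken by lexicographically smallest ``(parent, child)``) is
    removed.  The returned network's ``removed_edges`` attribute logs the
    deletions.
    """
    g = net.graph.copy()
    removed: list[tuple[str, str, float]] = []
    while True:
        cyclic_edges = []
        for comp in nx.strongly_connected_components(g):
            if len(comp) > 1:
                cyclic_edges.extend(
                    (d["confidence"], u, v)
                    for u, v, d in g.edges(comp, data=True)
                    if u in comp and v in comp
                )
        if not cyclic_edges:
            break
        conf, u, v = min(cyclic_edges)
        g.remove_edge(u, v)
        removed.append((u, v, conf))
    out = GeneNetwork(
        ((u, v, d["confidence"]) for u, v, d in g.edges(data=True)), nodes=net.nodes
    )
    out.removed_edges = removed
    return out


def learn_consensus(
    levels: pd.DataFrame,
    priors: PriorSet,
    config: LearnConfig | None = None,
    keep_runs: bool = False,
):
    """Full consensus construction: seeded runs -> merge -> cycle removal.

    Returns ``(dag, consensus, runs)`` where ``dag`` is the final acyclic
    network (with ``removed_edges`` log), ``consensus`` the pre-cycle-removal
    merge, and ``runs`` the per-seed DAGs (empty list unless ``keep_runs``).
    A single family-score cache is shared across seeds.
    """
    config = config or LearnConfig()
    genes = list(levels.index)
    scorer = _FamilyScorer(encode_levels(levels).to_numpy())
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_seeds) % (2**31)
    runs: list[GeneNetwork] = []
    counts: dict[tuple[int, int], int] = {}
    for s in seeds:
        rng = np.random.default_rng(int(s))
        edges = _climb(scorer, genes, priors, config, rng)
        for e in edges:
            counts[e] = counts.get(e, 0) + 1
        if keep_runs:
            runs.append(
                GeneNetwork([(genes[p], genes[c], 1.0) for p, c in edges], nodes=genes)
            )
    m = config.n_seeds
    consensus = GeneNetwork(
        [
            (genes[p], genes[c], k / m)
            for (p, c), k in counts.items()
            if k / m >= config.consensus_fraction - 1e-12
        ],
        nodes=genes,
    )
    dag = break_cycles(consensus)
    return dag, consensus, runs


# -- sklearn estimator -----------------------------------------------------


class ConsensusNetworkLearner(BaseEstimator):
    """Sklearn-style estimator: fit a consensus Bayesian network to expression.

    ``fit`` accepts a samples x genes DataFrame.  Continuous input is
    discretized internally (per-gene 3-level k-means) and also drives the
    correlation priors; already-discretized input (values in
    low/medium/high) requires ``X_continuous`` or an explicit ``priors``.

    Parameters mirror :class:`LearnConfig`.

    Fitted attributes
    -----------------
    network_ : GeneNetwork
        Final directed acyclic consensus network.
    consensus_ : GeneNetwork
        Pre-cycle-removal consensus (may contain cycles).
    priors_ : PriorSet
        Candidate-parent priors used during search.
    removed_edges_ : list of (parent, child, confidence)
        Cycle-breaking deletions.
    """

    def __init__(
        self,
        n_seeds: int = 25,
        consensus_fraction: float = 0.30,
        max_parents: int = 3,
        egene_bonus: float = 1.0,
        alpha: float = 0.01,
        max_candidate_parents: int | None = None,
        max_passes: int = 30,
        random_state: int = 0,
    ):
        self.n_seeds = n_seeds
        self.consensus_fraction = consensus_fraction
        self.max_parents = max_parents
        self.egene_bonus = egene_bonus
        self.alpha = alpha
        self.max_candidate_parents = max_candidate_parents
        self.max_passes = max_passes
        self.random_state = random_state

    def _config(self) -> LearnConfig:
        return LearnConfig(
            n_seeds=self.n_seeds,
            consensus_fraction=self.consensus_fraction,
            max_parents=self.max_parents,
            egene_bonus=self.egene_bonus,
            alpha=self.alpha,
            max_candidate_parents=self.max_candidate_parents,
            max_passes=self.max_passes,
            seed=self.random_state,
        )

    def fit(
        self,
        X: pd.DataFrame,
        y=None,
        *,
        X_continuous: pd.DataFrame | None = None,
        egenes=None,
        priors: PriorSet | None = None,
    ):
        X = pd.DataFrame(X)
        is_discrete = X.dtypes.map(lambda d: d == object).all()
        if is_discrete:
            levels = X.T
            if priors is None and X_continuous is None:
                raise ValueError(
                    "discrete input needs X_continuous or explicit priors"
                )
        else:
            levels = discretize_kmeans(X.T, seed=self.random_state)
            if X_continuous is None:
                X_continuous = X
        if priors is None:
            priors = correlation_priors(
                X_continuous.T,
                alpha=self.alpha,
                egenes=egenes,
                max_candidates=self.max_candidate_parents,
            )
        dag, consensus, _ = learn_consensus(levels, priors, self._config())
        self.priors_ = priors
        self.consensus_ = consensus
        self.network_ = dag
        self.removed_edges_ = dag.removed_edges
        self.n_features_in_ = X.shape[1]
        return self
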