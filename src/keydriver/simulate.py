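"""Synthetic regulatory truths and replicate expression cohorts.

The generator emulates the statistical structure the pipeline assumes about
adipose-tissue cohorts so every stage is testable without restricted-access
data: a sparse ground-truth DAG with a few high-out-degree hub regulators
(scale-free-like), continuous TPM-scale expression produced by a
linear-Gaussian structural-equation model along the topological order, a
disease ("GWAS") gene label set planted to be enriched among the
descendants of chosen hubs, an eGene label set, and independent replicate
cohorts sharing the same truth with cohort-specific noise and sample
sizes (mirroring a two-cohort male/female replication design).

It deliberately does not model RNA-seq count noise, batch structure or
sex-chromosome biology; see the methods note for what that implies.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import GeneNetwork, GeneSet

__all__ = [
    "SyntheticTruth",
    "simulate_dag",
    "simulate_expression",
    "make_replicates",
    "preferential_attachment_network",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """A ground-truth DAG with hub, GWAS and eGene labels."""

    dag: GeneNetwork
    hub_genes: frozenset[str]
    gwas_labels: GeneSet
    egene_labels: GeneSet
    generation_params: dict

    @property
    def genes(self) -> list[str]:
        return sorted(self.dag.nodes)


def _gene_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


def simulate_dag(
    n_genes: int = 200,
    n_hubs: int = 5,
    edge_density: float = 0.03,
    seed: int = 0,
    hub_attachment: float = 0.6,
    gwas_fraction: float = 0.15,
    gwas_enrichment: float = 5.0,
    egene_fraction: float = 0.2,
) -> SyntheticTruth:
    """Sample a hub-structured ground-truth DAG with planted label sets.

    Genes are laid out along a topological order; each non-root gene draws
    parents from earlier genes, attaching to a designated hub with
    probability ``hub_attachment`` (preferential, scale-free-like
    out-degrees).  Hubs are root regulators — they receive no parents, so
    their downstream dominance is not inherited by upstream genes and the
    hubs are well separated in downstream-count profiles.  GWAS labels are
    planted so that genes descending from half of the hubs are
    ``gwas_enrichment`` times more likely to carry the label than
    background; eGenes are the hubs plus a random subset.

    ``edge_density`` is relative to the ``n*(n-1)/2`` orderable pairs.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if not 0 < edge_density < 0.2:
        raise ValueError("edge_density must be in (0, 0.2)")
    if not 1 <= n_hubs < n_genes // 2:
        raise ValueError("n_hubs must be >= 1 and well below n_genes")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    # hubs sit early in the topological order so they can acquire many children
    early = max(n_hubs, n_genes // 5)
    hub_idx = np.sort(rng.choice(early, size=n_hubs, replace=False))
    hubs = {genes[i] for i in hub_idx}
    target_edges = edge_density * n_genes * (n_genes - 1) / 2.0
    lam = target_edges / (n_genes - 1)
    edges: set[tuple[int, int]] = set()
    hub_set = set(int(i) for i in hub_idx)
    for child in range(1, n_genes):
        if child in hub_set:  # hubs are roots
            continue
        k = min(child, 1 + rng.poisson(max(lam - 1.0, 0.0)))
        eligible_hubs = hub_idx[hub_idx < child]
        for _ in range(k):
            if eligible_hubs.size and rng.random() < hub_attachment:
                parent = int(rng.choice(eligible_hubs))
            else:
                parent = int(rng.integers(child))
            edges.add((parent, child))
    dag = GeneNetwork(
        [(genes[p], genes[c], 1.0) for p, c in sorted(edges)], nodes=genes
    )
    # GWAS labels enriched among descendants of half the hubs
    chosen = [genes[i] for i in hub_idx[: max(1, n_hubs // 2 + n_hubs % 2)]]
    descendants: set[str] = set()
    for hub in chosen:
        descendants |= {
            g for g, d in dag.distances_from(hub).items() if d >= 1
        }
    n_desc = len(descendants)
    n_bg = n_genes - n_desc
    target_total = gwas_fraction * n_genes
    base_rate = target_total / (n_bg + gwas_enrichment * n_desc)
    desc_rate = min(1.0, gwas_enrichment * base_rate)
    gwas_members = {
        g
        for g in genes
        if rng.random() < (desc_rate if g in descendants else base_rate)
    }
    if not gwas_members:
        gwas_members = set(rng.choice(sorted(descendants) or genes, size=1))
    egene_members = set(hubs) | {
        g for g in genes if rng.random() < egene_fraction
    }
    return SyntheticTruth(
        dag=dag,
        hub_genes=frozenset(hubs),
        gwas_labels=GeneSet("gwas", frozenset(gwas_members)),
        egene_labels=GeneSet("egenes", frozenset(egene_members)),
        generation_params={
            "n_genes": n_genes,
            "n_hubs": n_hubs,
            "edge_density": edge_density,
            "seed": seed,
            "hub_attachment": hub_attachment,
            "gwas_fraction": gwas_fraction,
            "gwas_enrichment": gwas_enrichment,
            "egene_fraction": egene_fraction,
        },
    )


def simulate_expression(
    truth: SyntheticTruth,
    n_samples: int = 500,
    effect: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    sample_prefix: str = "S",
    base_log_tpm: float = 2.0,
) -> pd.DataFrame:
    """Linear-Gaussian structural-equation sampling on the truth DAG.

    On the latent (log) scale each gene is ``effect * mean(parents) +
    N(0, noise_sd)``, evaluated along the topological order; the observed
    matrix is ``exp(latent + base_log_tpm)``, a monotone map onto a
    non-negative TPM-like scale.  Returns a genes x samples DataFrame.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    genes = truth.genes
    index = {g: i for i, g in enumerate(genes)}
    parents = [
        [index[p] for p in truth.dag.graph.predecessors(g)] for g in genes
    ]
    order = [index[g] for g in nx.topological_sort(truth.dag.graph)]
    latent = np.zeros((len(genes), n_samples))
    for i in order:
        noise = rng.normal(0.0, noise_sd, size=n_samples)
        if parents[i]:
            latent[i] = effect * latent[parents[i]].mean(axis=0) + noise
        else:
            latent[i] = noise
    tpm = np.exp(latent + base_log_tpm)
    samples = [f"{sample_prefix}{j:04d}" for j in range(n_samples)]
    return pd.DataFrame(tpm, index=genes, columns=samples)


def make_replicates(
    truth: SyntheticTruth,
    n_samples_a: int = 400,
    n_samples_b: int = 200,
    seed: int = 0,
    effect: float = 1.0,
    noise_sd: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two independent cohorts from one truth (shared structure, fresh noise).

    Unequal sample sizes emulate cohort imbalance (e.g. twice as many male
    as female donors) and support sub-sampling experiments.
    """
    seq = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    cohort_a = simulate_expression(
        truth, n_samples_a, effect, noise_sd, seed=int(seq[0]), sample_prefix="A"
    )
    cohort_b = simulate_expression(
        truth, n_samples_b, effect, noise_sd, seed=int(seq[1]), sample_prefix="B"
    )
    return cohort_a, cohort_b


def preferential_attachment_network(
    n_genes: int = 1000, m: int = 2, seed: int = 0
) -> GeneNetwork:
    """Directed preferential-attachment graph with power-law out-degrees.

    Barabasi-Albert growth (each new gene attaches to ``m`` existing genes
    chosen proportionally to current degree), with every adjacency oriented
    in both directions so each gene's out-degree equals its full
    attachment degree and follows the heavy-tailed ``~ k^-3`` law.  Used as
    the scale-free positive control for the topology diagnostics (it is
    not acyclic).
    """
    g = nx.barabasi_albert_graph(n_genes, m, seed=seed)
    genes = _gene_ids(n_genes)
    edges = []
    for u, v in g.edges:
        edges.append((genes[u], genes[v], 1.0))
        edges.append((genes[v], genes[u], 1.0))
    return GeneNetwork(edges, nodes=genes)
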