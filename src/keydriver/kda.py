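"""Two-type key-driver identification on directed gene networks.

A key driver is a gene whose prominent network position implies it
regulates many downstream genes (type 1) or many disease-annotated
downstream genes (type 2):

* **Type 1** — every gene is profiled for its number of downstream genes
  ``G_d`` at exact shortest-path distances d = 1..10; each count is turned
  into a network-level z-score ``Score_d = (G_d - NM_d) / NS_d`` against the
  network mean ``NM_d`` and population SD ``NS_d``, and a distance-weighted
  sum ``GeneScore = sum_d w_d * Score_d`` with weights
  (1, 1, 1, 0.75, 0.5, 0.25, 0.125, 0.0625, 0.03125) for d = 1..9 ranks
  genes.  The top decile (ceil, boundary ties included) are type-1 drivers.

* **Type 2** — every gene's downstream "neighborhood" (genes within four
  edges) is tested for enrichment of a disease gene set (e.g. fat-
  distribution GWAS candidates) by a one-sided Fisher exact test against
  the rest of the network; nominally significant genes are type-2 drivers.

The per-network key-driver set is the union of the two types; drivers
replicated across two cohorts' networks are their intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network import GeneNetwork, GeneSet

__all__ = [
    "DEFAULT_WEIGHTS",
    "KDAProfile",
    "KeyDriverResult",
    "downstream_profile",
    "type1_scores",
    "type2_enrichment",
    "key_drivers",
    "shared_key_drivers",
]

#: distance weights for d = 1..9 (d = 10 is profiled but unweighted)
DEFAULT_WEIGHTS = (1.0, 1.0, 1.0, 0.75, 0.5, 0.25, 0.125, 0.0625, 0.03125)


@dataclass(frozen=True)
class KDAProfile:
    """Per-gene downstream counts by exact distance, with network mean/SD.

    ``counts`` is a genes x distances DataFrame (columns 1..max_distance);
    ``network_mean``/``network_sd`` are the per-distance mean and population
    SD over *all* network genes.
    """

    counts: pd.DataFrame
    network_mean: np.ndarray = field(default=None)
    network_sd: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("downstream counts must be non-negative")
        if self.network_mean is None:
            object.__setattr__(self, "network_mean", values.mean(axis=0))
        if self.network_sd is None:
            object.__setattr__(self, "network_sd", values.std(axis=0))

    @property
    def max_distance(self) -> int:
        return self.counts.shape[1]

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "KDAProfile":
        return cls(counts=counts)


@dataclass(frozen=True)
class KeyDriverResult:
    """Scores, per-type driver sets, and their union for one network."""

    gene_scores: pd.Series
    type1: frozenset[str]
    type2_pvalues: pd.Series
    type2: frozenset[str]
    key_drivers: frozenset[str]
    score_table: pd.DataFrame
    enrichment_table: pd.DataFrame
    parameters: dict


def downstream_profile(net: GeneNetwork, max_distance: int = 10) -> KDAProfile:
    """Count downstream genes at exact BFS distances 1..``max_distance`` per gene."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    genes = sorted(net.nodes)
    counts = np.zeros((len(genes), max_distance), dtype=np.int64)
    for i, gene in enumerate(genes):
        for node, d in net.distances_from(gene, max_distance=max_distance).items():
            if 1 <= d <= max_distance:
                counts[i, d - 1] += 1
    frame = pd.DataFrame(counts, index=genes, columns=range(1, max_distance + 1))
    return KDAProfile(counts=frame)


def type1_scores(
    profile: KDAProfile,
    weights: tuple[float, ...] = DEFAULT_WEIGHTS,
    decile: float = 0.10,
) -> tuple[pd.Series, frozenset[str]]:
    """Distance-weighted z-score ranking and the top-decile type-1 set.

    ``Score_d`` is 0 wherever the network SD is 0 (degenerate distance).
    The type-1 cutoff is the ``ceil(decile * N)``-th highest GeneScore;
    boundary ties are all included.
    """
    weights = np.asarray(weights, dtype=float)
    if profile.max_distance < weights.size:
        raise ValueError(
            f"profile spans {profile.max_distance} distances but "
            f"{weights.size} weights were given"
        )
    counts = profile.counts.to_numpy()[:, : weights.size]
    mean = profile.network_mean[: weights.size]
    sd = profile.network_sd[: weights.size]
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (counts - mean) / sd
    z[:, sd == 0] = 0.0
    scores = pd.Series(z @ weights, index=profile.counts.index, name="GeneScore")
    n = len(scores)
    m = int(np.ceil(decile * n))
    boundary = scores.sort_values(ascending=False).iloc[m - 1]
    type1 = frozenset(scores.index[scores >= boundary])
    return scores, type1


def _score_table(profile: KDAProfile, scores: pd.Series, type1: frozenset[str],
                 weights: tuple[float, ...]) -> pd.DataFrame:
    table = profile.counts.copy()
    table.columns = [f"G_{d}" for d in table.columns]
    w = np.asarray(weights, dtype=float)
    counts = profile.counts.to_numpy()[:, : w.size]
    sd = profile.network_sd[: w.size]
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (counts - profile.network_mean[: w.size]) / sd
    z[:, sd == 0] = 0.0
    for j in range(w.size):
        table[f"Score_{j + 1}"] = z[:, j]
    table["GeneScore"] = scores
    table["type1"] = [g in type1 for g in table.index]
    return table.sort_values("GeneScore", ascending=False)


def type2_enrichment(
    net: GeneNetwork,
    gwas: GeneSet,
    radius: int = 4,
    alpha: float = 0.05,
    correction: str | None = None,
) -> pd.DataFrame:
    """Fisher-exact enrichment of a disease gene set in each downstream neighborhood.

    For each gene g the 2x2 table {in/out neighborhood} x {GWAS/non-GWAS}
    over all network genes except g is tested one-sided (greater).  Returns
    a DataFrame with neighborhood size, overlap, p-value and significance
    at nominal ``alpha`` (or Benjamini-Hochberg when
    ``correction='fdr_bh'``).
    """
    universe = net.nodes
    gwas_in_net = gwas.members & universe
    if not gwas_in_net:
        raise ValueError(
            f"gene set {gwas.name!r} has no members in the network universe"
        )
    genes = sorted(universe)
    rows = []
    for gene in genes:
        neighborhood = net.downstream_within(gene, radius)
        others = len(universe) - 1
        k_gwas = len(gwas_in_net - {gene})
        n_neigh = len(neighborhood)
        overlap = len(neighborhood & gwas_in_net)
        table = [
            [overlap, n_neigh - overlap],
            [k_gwas - overlap, (others - n_neigh) - (k_gwas - overlap)],
        ]
        _, p = stats.fisher_exact(table, alternative="greater")
        rows.append((gene, n_neigh, overlap, float(p)))
    frame = pd.DataFrame(
        rows, columns=["gene", "neighborhood_size", "gwas_overlap", "p_value"]
    ).set_index("gene")
    if correction == "fdr_bh":
        order = np.argsort(frame["p_value"].to_numpy(), kind="stable")
        n = len(frame)
        ranked = frame["p_value"].to_numpy()[order]
        adj = np.minimum.accumulate((ranked * n / np.arange(1, n + 1))[::-1])[::-1]
        adjusted = np.empty(n)
        adjusted[order] = np.minimum(adj, 1.0)
        frame["p_adjusted"] = adjusted
        frame["significant"] = frame["p_adjusted"] < alpha
    elif correction is None:
        frame["significant"] = frame["p_value"] < alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return frame


def key_drivers(
    net: GeneNetwork,
    gwas: GeneSet,
    weights: tuple[float, ...] = DEFAULT_WEIGHTS,
    max_distance: int = 10,
    radius: int = 4,
    decile: float = 0.10,
    alpha: float = 0.05,
    correction: str | None = None,
) -> KeyDriverResult:
    """Run the full two-type analysis; drivers are the union of the types."""
    profile = downstream_profile(net, max_distance=max_distance)
    scores, type1 = type1_scores(profile, weights=weights, decile=decile)
    enrichment = type2_enrichment(
        net, gwas, radius=radius, alpha=alpha, correction=correction
    )
    type2 = frozenset(enrichment.index[enrichment["significant"]])
    return KeyDriverResult(
        gene_scores=scores,
        type1=type1,
        type2_pvalues=enrichment["p_value"],
        type2=type2,
        key_drivers=type1 | type2,
        score_table=_score_table(profile, scores, type1, weights),
        enrichment_table=enrichment,
        parameters={
            "weights": tuple(weights),
            "max_distance": max_distance,
            "radius": radius,
            "decile": decile,
            "alpha": alpha,
            "correction": correction,
        },
    )


def shared_key_drivers(
    result_a: KeyDriverResult | frozenset[str], result_b: KeyDriverResult | frozenset[str]
) -> frozenset[str]:
    """Drivers identified (either type) in both networks: the replicated set."""
    a = result_a.key_drivers if isinstance(result_a, KeyDriverResult) else frozenset(result_a)
    b = result_b.key_drivers if isinstance(result_b, KeyDriverResult) else frozenset(result_b)
    return a & b
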