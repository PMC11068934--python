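"""Two-type key-driver scoring and replication intersections."""

import numpy as np
import pandas as pd
import pytest

from keydriver.kda import (
    DEFAULT_WEIGHTS,
    KDAProfile,
    downstream_profile,
    key_drivers,
    shared_key_drivers,
    type1_scores,
    type2_enrichment,
)
from keydriver.network import GeneNetwork, GeneSet
from keydriver.simulate import simulate_dag

from conftest import hypergeom_upper_tail, random_dag


class TestDownstreamProfile:
    def test_chain_counts(self, chain_net):
        profile = downstream_profile(chain_net)
        assert profile.counts.loc["A"].tolist() == [1, 1] + [0] * 8
        assert profile.counts.loc["B"].tolist() == [1] + [0] * 9
        assert profile.counts.loc["C"].tolist() == [0] * 10
        assert profile.network_mean[0] == pytest.approx(2 / 3)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_distance_one_counts_sum_to_edges(self, seed):
        rng = np.random.default_rng(seed)
        net = random_dag(25, 0.15, rng)
        profile = downstream_profile(net)
        assert profile.counts[1].sum() == net.n_edges

    def test_population_sd(self):
        net = GeneNetwork([("A", "B"), ("A", "C"), ("B", "C")])
        profile = downstream_profile(net)
        g1 = profile.counts[1].to_numpy()
        assert profile.network_sd[0] == pytest.approx(np.std(g1))  # ddof=0


class TestType1Scores:
    def test_unit_z_scores_sum_to_printed_weights(self):
        """A gene one SD above the mean at every distance scores 4.71875."""
        # counts per distance: two genes at 0, two at 3 -> mean 1.5, sd 1.5;
        # the focal gene's count of 3 is exactly mean + sd at every distance
        counts = pd.DataFrame(
            np.array([[0] * 10, [0] * 10, [3] * 10, [3] * 10]),
            index=["a", "b", "c", "focal"],
            columns=range(1, 11),
        )
        profile = KDAProfile.from_counts(counts)
        scores, _ = type1_scores(profile)
        assert scores["focal"] == pytest.approx(4.71875)
        assert sum(DEFAULT_WEIGHTS) == pytest.approx(4.71875)

    def test_linearity_in_weights(self):
        truth = simulate_dag(n_genes=60, n_hubs=3, edge_density=0.06, seed=0)
        profile = downstream_profile(truth.dag)
        scores, type1 = type1_scores(profile)
        doubled, type1_doubled = type1_scores(
            profile, weights=tuple(2 * w for w in DEFAULT_WEIGHTS)
        )
        assert np.allclose(doubled.to_numpy(), 2 * scores.to_numpy())
        assert type1 == type1_doubled

    def test_degenerate_sd_gives_zero_scores_and_full_tie(self):
        """Identical profiles: all z-scores zero, boundary tie includes everyone."""
        net = GeneNetwork([("A", "B"), ("B", "C"), ("C", "A")])
        profile = downstream_profile(net)
        scores, type1 = type1_scores(profile)
        assert (scores == 0).all()
        assert type1 == frozenset(net.nodes)

    def test_star_hub_score_matches_hand_computation(self):
        """Hub with 99 leaves: z-score from an independent mean/SD calculation."""
        leaves = [f"L{i:02d}" for i in range(99)]
        net = GeneNetwork([("HUB", leaf) for leaf in leaves])
        profile = downstream_profile(net)
        scores, type1 = type1_scores(profile)
        g1 = np.array([99] + [0] * 99)
        z = (99 - g1.mean()) / g1.std()
        assert scores["HUB"] == pytest.approx(z * DEFAULT_WEIGHTS[0])
        assert "HUB" in type1

    def test_top_decile_size(self):
        truth = simulate_dag(n_genes=100, n_hubs=5, edge_density=0.05, seed=1)
        _, type1 = type1_scores(downstream_profile(truth.dag))
        assert len(type1) >= int(np.ceil(0.10 * truth.dag.n_nodes))

    def test_weight_length_mismatch_rejected(self):
        profile = downstream_profile(GeneNetwork([("A", "B")]), max_distance=3)
        with pytest.raises(ValueError):
            type1_scores(profile, weights=DEFAULT_WEIGHTS)


class TestType2Enrichment:
    def test_against_exact_hypergeometric_tail(self):
        """Fisher one-sided p equals the rational hypergeometric enumeration."""
        rng = np.random.default_rng(0)
        for seed in range(6):
            net = random_dag(int(rng.integers(20, 61)), 0.12, rng)
            genes = sorted(net.nodes)
            gwas = GeneSet("gwas", frozenset(rng.choice(genes, size=8, replace=False)))
            table = type2_enrichment(net, gwas)
            for gene in genes:
                neigh = net.downstream_within(gene, 4)
                big_n = len(genes) - 1
                big_k = len((gwas.members & set(genes)) - {gene})
                x = len(neigh & gwas.members)
                expected = hypergeom_upper_tail(x, big_n, big_k, len(neigh))
                assert table.loc[gene, "p_value"] == pytest.approx(
                    expected, abs=1e-12
                )

    def test_worked_hypergeometric_example(self):
        """Neighborhood of 10 with 5 hits among 10 annotated in 99: exact tail."""
        # star-like construction: focal -> 10 downstream, universe padded to 100
        edges = [("F", f"N{i}") for i in range(10)]
        nodes = [f"Z{i}" for i in range(89)]
        net = GeneNetwork(edges, nodes=nodes)
        gwas = GeneSet(
            "gwas", frozenset([f"N{i}" for i in range(5)] + [f"Z{i}" for i in range(5)])
        )
        table = type2_enrichment(net, gwas)
        assert table.loc["F", "p_value"] == pytest.approx(
            hypergeom_upper_tail(5, 99, 10, 10), abs=1e-12
        )

    def test_zero_overlap_is_p_one(self):
        net = GeneNetwork([("A", "B")], nodes=["G1", "G2"])
        gwas = GeneSet("gwas", frozenset({"G1"}))
        table = type2_enrichment(net, gwas)
        assert table.loc["A", "p_value"] == pytest.approx(1.0)

    def test_no_overlap_with_universe_rejected(self):
        net = GeneNetwork([("A", "B")])
        with pytest.raises(ValueError):
            type2_enrichment(net, GeneSet("gwas", frozenset({"X"})))

    def test_bh_correction_is_monotone(self):
        truth = simulate_dag(n_genes=50, n_hubs=3, edge_density=0.08, seed=2)
        table = type2_enrichment(
            truth.dag, truth.gwas_labels, correction="fdr_bh"
        )
        assert (table["p_adjusted"] >= table["p_value"] - 1e-12).all()
        assert (table["p_adjusted"] <= 1.0).all()


class TestKeyDrivers:
    def test_union_and_intermediates(self):
        truth = simulate_dag(n_genes=80, n_hubs=4, edge_density=0.06, seed=3)
        result = key_drivers(truth.dag, truth.gwas_labels)
        assert result.key_drivers == result.type1 | result.type2
        assert result.type1 <= frozenset(result.gene_scores.index)
        assert set(result.score_table.index) == truth.dag.nodes

    def test_empty_type2_reduces_to_type1(self):
        # GWAS gene exists in universe but in no neighborhood at alpha
        net = GeneNetwork([("A", "B"), ("C", "D")], nodes=["W"])
        result = key_drivers(net, GeneSet("gwas", frozenset({"W"})))
        assert result.type2 == frozenset()
        assert result.key_drivers == result.type1

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_hubs_recovered_as_type1(self, seed):
        """Five hubs among 200 genes are always top-decile type-1 drivers."""
        truth = simulate_dag(n_genes=200, n_hubs=5, edge_density=0.03, seed=seed)
        core = truth.dag.subgraph(truth.dag.connected_nodes())
        result = key_drivers(core, truth.gwas_labels)
        assert truth.hub_genes <= result.type1


class TestSharedKeyDrivers:
    def test_intersection(self):
        assert shared_key_drivers(frozenset("ABC"), frozenset("BCD")) == frozenset("BC")

    def test_disjoint_and_subset_property(self):
        a, b = frozenset({"X"}), frozenset({"Y"})
        assert shared_key_drivers(a, b) == frozenset()
        truth = simulate_dag(n_genes=40, n_hubs=2, edge_density=0.08, seed=4)
        r = key_drivers(truth.dag, truth.gwas_labels)
        shared = shared_key_drivers(r, r)
        assert shared == r.key_drivers
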