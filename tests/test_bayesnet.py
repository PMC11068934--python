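"""Priors, family BIC scoring, hill climbing, consensus merge and cycle removal."""

import numpy as np
import pandas as pd
import pytest

from keydriver.bayesnet import (
    ConsensusNetworkLearner,
    LearnConfig,
    break_cycles,
    consensus_merge,
    correlation_priors,
    family_bic,
    learn_consensus,
    learn_single,
)
from keydriver.network import GeneNetwork, GeneSet
from keydriver.preprocess import LEVELS, discretize_kmeans, log_transform
from keydriver.simulate import simulate_dag, simulate_expression


def levels_frame(rows: dict) -> pd.DataFrame:
    mat = pd.DataFrame.from_dict(rows, orient="index")
    mat.columns = [f"s{j}" for j in range(mat.shape[1])]
    return mat


class TestCorrelationPriors:
    def test_strongly_coupled_pair_become_mutual_candidates(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        mat = pd.DataFrame(
            {"a": x, "b": x + rng.normal(0, 0.1, 100), "c": rng.normal(size=100)}
        ).T
        priors = correlation_priors(mat, alpha=0.01)
        assert "b" in priors.candidate_parents["a"]
        assert "a" in priors.candidate_parents["b"]

    def test_independent_pair_candidate_rate_near_alpha(self):
        """False-candidate rate for independent normals is ~ alpha."""
        rng = np.random.default_rng(1)
        hits = 0
        reps = 400
        for _ in range(reps):
            mat = pd.DataFrame(rng.normal(size=(2, 100)), index=["a", "b"])
            priors = correlation_priors(mat, alpha=0.01)
            hits += "b" in priors.candidate_parents["a"]
        # binomial(400, 0.01): mean 4, sd ~2; allow 4 sd
        assert hits <= 12

    def test_never_own_candidate_and_symmetry(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.normal(size=(6, 50)), index=list("abcdef"))
        priors = correlation_priors(mat, alpha=0.5)
        for g, cands in priors.candidate_parents.items():
            assert g not in cands
            for other in cands:
                assert g in priors.candidate_parents[other]

    def test_constant_gene_excluded_with_warning(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(
            {"a": rng.normal(size=30), "flat": np.ones(30)}
        ).T
        with pytest.warns(UserWarning, match="constant"):
            priors = correlation_priors(mat, alpha=0.5)
        assert priors.candidate_parents["flat"] == frozenset()

    def test_max_candidates_caps_then_symmetrizes(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=80)
        rows = {f"g{i}": base + rng.normal(0, 0.5, 80) for i in range(12)}
        mat = pd.DataFrame(rows)
        priors = correlation_priors(mat.T, alpha=0.01, max_candidates=3)
        sizes = [len(v) for v in priors.candidate_parents.values()]
        assert max(sizes) <= 12  # symmetrized union can exceed 3, never the universe
        for g, cands in priors.candidate_parents.items():
            for other in cands:
                assert g in priors.candidate_parents[other]


class TestFamilyBic:
    def test_uniform_three_level_closed_form(self):
        """90 samples spread uniformly over 3 levels, no parents."""
        row = (["low"] * 30 + ["medium"] * 30 + ["high"] * 30)
        data = levels_frame({"g": row})
        score = family_bic(data, "g")
        assert score.log_likelihood == pytest.approx(90 * np.log(1 / 3))
        assert score.param_count == 2
        assert score.bic == pytest.approx(2 * np.log(90) - 2 * 90 * np.log(1 / 3))

    def test_constant_node_loglik_zero(self):
        data = levels_frame({"g": ["medium"] * 50})
        score = family_bic(data, "g")
        assert score.log_likelihood == 0.0
        assert score.bic == pytest.approx(2 * np.log(50))

    def test_param_count_scales_with_parents(self):
        rng = np.random.default_rng(0)
        labels = np.array(LEVELS)
        data = levels_frame(
            {g: labels[rng.integers(0, 3, 60)].tolist() for g in "abc"}
        )
        assert family_bic(data, "a", {"b"}).param_count == 6
        assert family_bic(data, "a", {"b", "c"}).param_count == 18

    def test_independent_parent_worsens_bic_at_large_n(self):
        """An unrelated parent buys little likelihood but pays k*ln(n)."""
        rng = np.random.default_rng(1)
        labels = np.array(LEVELS)
        n = 500
        data = levels_frame(
            {
                "child": labels[rng.integers(0, 3, n)].tolist(),
                "noise": labels[rng.integers(0, 3, n)].tolist(),
            }
        )
        alone = family_bic(data, "child")
        with_parent = family_bic(data, "child", {"noise"})
        assert with_parent.log_likelihood >= alone.log_likelihood
        assert with_parent.bic > alone.bic

    def test_unknown_node_or_parent_raises(self):
        data = levels_frame({"g": ["low", "high"]})
        with pytest.raises(KeyError):
            family_bic(data, "missing")
        with pytest.raises(KeyError):
            family_bic(data, "g", {"missing"})


class TestLearnSingle:
    @staticmethod
    def coupled_pair(n=500, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=n)
        b = a + rng.normal(0, 0.5, n)
        mat = pd.DataFrame({"a": a, "b": b, "c": rng.normal(size=n)}).T
        levels = discretize_kmeans(mat, seed=seed)
        priors = correlation_priors(mat, alpha=0.01)
        return levels, priors

    def test_recovers_dependent_edge(self):
        levels, priors = self.coupled_pair()
        net = learn_single(levels, priors, LearnConfig(), seed=0)
        assert ("a", "b") in net.edges() or ("b", "a") in net.edges()

    def test_independent_genes_stay_unconnected(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(
            rng.normal(size=(8, 500)), index=[f"g{i}" for i in range(8)]
        )
        levels = discretize_kmeans(mat, seed=0)
        priors = correlation_priors(mat, alpha=0.01)
        net = learn_single(levels, priors, LearnConfig(), seed=0)
        assert net.n_edges <= max(1, int(0.05 * 8 * 7))

    def test_output_is_dag_and_respects_indegree_cap(self):
        truth = simulate_dag(n_genes=30, n_hubs=3, edge_density=0.1, seed=0)
        mat = log_transform(simulate_expression(truth, n_samples=200, seed=0))
        levels = discretize_kmeans(mat, seed=0)
        priors = correlation_priors(mat)
        config = LearnConfig(max_parents=2)
        net = learn_single(levels, priors, config, seed=1)
        assert net.is_dag
        assert max((d for _, d in net.graph.in_degree()), default=0) <= 2

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            learn_single(pd.DataFrame(), None, LearnConfig(), seed=0)

    def test_score_decomposes_over_families(self):
        """Deleting an edge changes only the child's family score."""
        levels, priors = self.coupled_pair()
        net = learn_single(levels, priors, LearnConfig(), seed=0)
        edges = sorted(net.edges())
        assert edges, "learner found no edges to test decomposition on"
        parent, child = edges[0]
        parents_of = {
            g: {u for u, v in net.edges() if v == g} for g in net.nodes
        }
        before = {
            g: family_bic(levels, g, parents_of[g]).bic for g in net.nodes
        }
        parents_of[child].discard(parent)
        after = {
            g: family_bic(levels, g, parents_of[g]).bic for g in net.nodes
        }
        changed = {g for g in net.nodes if before[g] != after[g]}
        assert changed == {child}


class TestConsensusMerge:
    def nets(self):
        n1 = GeneNetwork([("A", "B"), ("B", "C")])
        n2 = GeneNetwork([("A", "B")], nodes=["C"])
        n3 = GeneNetwork([("A", "B"), ("A", "C")])
        return [n1, n2, n3]

    def test_threshold_rule(self):
        merged = consensus_merge(self.nets(), fraction=0.30)
        assert merged.edges() == {("A", "B"), ("B", "C"), ("A", "C")}
        assert merged.confidence("A", "B") == pytest.approx(1.0)
        assert merged.confidence("B", "C") == pytest.approx(1 / 3)

    def test_fraction_one_is_intersection(self):
        merged = consensus_merge(self.nets(), fraction=1.0)
        assert merged.edges() == {("A", "B")}

    def test_tiny_fraction_is_union(self):
        merged = consensus_merge(self.nets(), fraction=1e-9)
        assert merged.edges() == {("A", "B"), ("B", "C"), ("A", "C")}

    def test_permutation_invariance(self):
        nets = self.nets()
        a = consensus_merge(nets, 0.30)
        b = consensus_merge(nets[::-1], 0.30)
        assert a == b

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            consensus_merge([], 0.3)


class TestBreakCycles:
    def test_two_cycle_drops_weaker_edge(self):
        net = GeneNetwork([("A", "B", 0.9), ("B", "A", 0.4)])
        dag = break_cycles(net)
        assert dag.edges() == {("A", "B")}
        assert dag.removed_edges == [("B", "A", 0.4)]

    def test_acyclic_input_unchanged(self):
        net = GeneNetwork([("A", "B", 0.5), ("B", "C", 0.7)])
        dag = break_cycles(net)
        assert dag == net and dag.removed_edges == []

    def test_three_cycle_single_minimal_removal(self):
        net = GeneNetwork(
            [("A", "B", 0.9), ("B", "C", 0.8), ("C", "A", 0.35), ("A", "D", 0.5)]
        )
        dag = break_cycles(net)
        assert dag.is_dag
        assert dag.removed_edges == [("C", "A", 0.35)]
        assert ("A", "D") in dag.edges()

    def test_tie_breaks_lexicographically(self):
        net = GeneNetwork([("A", "B", 0.5), ("B", "A", 0.5)])
        dag = break_cycles(net)
        assert dag.removed_edges == [("A", "B", 0.5)]

    @pytest.mark.parametrize("seed", [0, 1])
    def test_always_yields_dag_on_noisy_unions(self, seed):
        rng = np.random.default_rng(seed)
        names = [f"g{i}" for i in range(12)]
        edges = []
        for _ in range(40):
            u, v = rng.choice(12, size=2, replace=False)
            edges.append((names[u], names[v], float(rng.random())))
        dag = break_cycles(GeneNetwork(edges))
        assert dag.is_dag


class TestConsensusRecovery:
    def test_skeleton_recovery_on_synthetic_truth(self):
        """20-node truth, n=500, 25 seeds: recall >= 0.6 at FDR <= 0.4."""
        truth = simulate_dag(n_genes=20, n_hubs=2, edge_density=0.08, seed=7)
        expr = simulate_expression(truth, n_samples=500, seed=7)
        logged = log_transform(expr)
        levels = discretize_kmeans(logged, seed=7)
        priors = correlation_priors(logged, egenes=truth.egene_labels)
        dag, consensus, runs = learn_consensus(
            levels, priors, LearnConfig(n_seeds=25, seed=7), keep_runs=True
        )
        assert len(runs) == 25 and all(r.is_dag for r in runs)
        true_skel = {frozenset(e) for e in truth.dag.edges()}
        learned_skel = {frozenset(e) for e in dag.edges()}
        tp = len(true_skel & learned_skel)
        assert tp / len(true_skel) >= 0.6
        assert 1 - tp / max(len(learned_skel), 1) <= 0.4

    def test_consensus_confidences_are_frequencies(self):
        truth = simulate_dag(n_genes=15, n_hubs=2, edge_density=0.1, seed=3)
        expr = log_transform(simulate_expression(truth, n_samples=150, seed=3))
        levels = discretize_kmeans(expr, seed=3)
        priors = correlation_priors(expr)
        dag, consensus, runs = learn_consensus(
            levels, priors, LearnConfig(n_seeds=8, seed=3), keep_runs=True
        )
        for u, v, c in consensus.edges_with_confidence():
            freq = sum((u, v) in r.edges() for r in runs) / len(runs)
            assert c == pytest.approx(freq)
            assert freq >= 0.30 - 1e-12


class TestEstimator:
    def test_fit_continuous_input(self):
        truth = simulate_dag(n_genes=15, n_hubs=2, edge_density=0.1, seed=11)
        expr = simulate_expression(truth, n_samples=150, seed=11)
        est = ConsensusNetworkLearner(n_seeds=5, random_state=11)
        est.fit(np.log1p(expr).T)
        assert est.network_.is_dag
        assert est.network_.nodes == set(expr.index)

    def test_discrete_input_requires_priors(self):
        levels = levels_frame({"a": ["low", "high"] * 10, "b": ["low", "high"] * 10})
        est = ConsensusNetworkLearner(n_seeds=2)
        with pytest.raises(ValueError, match="priors"):
            est.fit(levels.T)

    def test_sklearn_param_interface(self):
        est = ConsensusNetworkLearner(n_seeds=7)
        assert est.get_params()["n_seeds"] == 7
        est.set_params(consensus_fraction=0.5)
        assert est.consensus_fraction == 0.5
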