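"""End-to-end workflow orchestration, reporting, and prioritization filters.

One "group" is a sex/depot/cohort expression matrix; :func:`run_group`
takes it from raw TPM values to a consensus network with key drivers
(filter -> log -> discretize -> priors -> seeded learning -> consensus ->
cycle removal -> topology -> key-driver analysis), writing plain-text
artifacts and a parameter/seed log along the way.  :func:`compare_cohorts`
replicates drivers across two groups and attaches the permutation overlap
test; :func:`prioritize` applies the evidence set-filters (cell type,
novelty, genetic support) that narrow replicated drivers to testable
candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bayesnet import LearnConfig, correlation_priors, learn_consensus
from .kda import (
    DEFAULT_WEIGHTS,
    KeyDriverResult,
    downstream_profile,
    key_drivers,
    shared_key_drivers,
    type1_scores,
)
from .network import GeneNetwork, GeneSet, read_gene_set, write_edge_list, write_gene_set
from .preprocess import (
    discretize_kmeans,
    filter_low_expression,
    log_transform,
    read_expression,
)
from .replication import OverlapTest, overlap_null
from .topology import TopologyReport, compare_to_random

__all__ = [
    "RunConfig",
    "GroupResult",
    "load_config",
    "run_group",
    "run_all",
    "compare_cohorts",
    "overlap_matrix",
    "prioritize",
]

ANNOTATION_FLAGS = (
    "adipocyte_expressed",
    "known_function",
    "gwas_candidate",
    "mouse_phenotype",
)


@dataclass
class RunConfig:
    """File paths and parameters for a multi-group run (YAML-loadable)."""

    expression: dict[str, str]
    gwas: str
    egenes: str | None = None
    annotations: str | None = None
    output_dir: str | None = None
    seed: int = 0
    subsample: int | None = None
    filter_threshold: float = 0.1
    filter_fraction: float = 0.8
    learner: dict = field(default_factory=dict)
    kda: dict = field(default_factory=dict)
    replicates: int = 10_000

    def learn_config(self) -> LearnConfig:
        return LearnConfig(seed=self.seed, **self.learner)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(**raw)


@dataclass
class GroupResult:
    """Artifacts of one group run."""

    group: str
    network: GeneNetwork
    kda: KeyDriverResult | None
    topology: TopologyReport | None
    summary: dict
    n_samples: int


def _log(outdir: Path | None, group: str, payload: dict) -> None:
    if outdir is None:
        return
    with (outdir / f"{group}.log.yaml").open("w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def run_group(
    expression: pd.DataFrame,
    gwas: GeneSet,
    egenes: GeneSet | None = None,
    *,
    group: str = "group",
    learn: LearnConfig | None = None,
    kda_params: dict | None = None,
    filter_threshold: float = 0.1,
    filter_fraction: float = 0.8,
    subsample: int | None = None,
    seed: int = 0,
    output_dir: str | Path | None = None,
    n_random: int = 10,
) -> GroupResult:
    """Run preprocessing, consensus learning and key-driver analysis for one group.

    ``expression`` is a genes x samples TPM matrix.  ``subsample``
    restricts all stages to a random subset of that many samples (the
    sample-size-matched sub-sampling experiment).  All randomness descends
    from ``seed``; identical inputs and seed give identical artifacts.
    """
    learn = learn or LearnConfig(seed=seed)
    kda_params = dict(kda_params or {})
    outdir = Path(output_dir) if output_dir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    seq = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    mat = filter_low_expression(expression, filter_threshold, filter_fraction)
    if subsample is not None:
        if subsample > mat.shape[1]:
            raise ValueError(
                f"subsample {subsample} exceeds {mat.shape[1]} available samples"
            )
        rng = np.random.default_rng(int(seq[0]))
        keep = np.sort(rng.choice(mat.shape[1], size=subsample, replace=False))
        mat = mat.iloc[:, keep]
    logged = log_transform(mat)
    levels = discretize_kmeans(logged, seed=int(seq[1]))
    priors = correlation_priors(
        logged,
        alpha=learn.alpha,
        egenes=egenes,
        max_candidates=learn.max_candidate_parents,
    )
    dag, _consensus, _ = learn_consensus(levels, priors, learn)

    connected = dag.connected_nodes()
    result = None
    if connected:
        core = dag.subgraph(connected)
        if gwas.members & connected:
            result = key_drivers(core, gwas, **kda_params)
        else:
            warnings.warn(
                f"group {group}: no disease genes among connected genes; "
                "type-2 analysis skipped",
                stacklevel=2,
            )
            kp = kda_params
            profile = downstream_profile(core, max_distance=kp.get("max_distance", 10))
            scores, type1 = type1_scores(
                profile,
                weights=kp.get("weights", DEFAULT_WEIGHTS),
                decile=kp.get("decile", 0.10),
            )
            result = KeyDriverResult(
                gene_scores=scores,
                type1=type1,
                type2_pvalues=pd.Series(dtype=float),
                type2=frozenset(),
                key_drivers=type1,
                score_table=pd.DataFrame(),
                enrichment_table=pd.DataFrame(),
                parameters=kda_params,
            )
    topology = None
    try:
        topology = compare_to_random(dag, n_random=n_random, seed=int(seq[1]))
    except ValueError as exc:
        warnings.warn(f"group {group}: topology report skipped ({exc})", stacklevel=2)

    summary = {
        "group": group,
        "n_samples": mat.shape[1],
        "genes_input": expression.shape[0],
        "genes_connected": len(connected),
        "edges": dag.n_edges,
        "key_drivers": len(result.key_drivers) if result else 0,
    }

    if outdir is not None:
        write_edge_list(dag, outdir / f"{group}.edges.tsv")
        with (outdir / f"{group}.removed_edges.tsv").open("w") as fh:
            fh.write("parent\tchild\tconfidence\n")
            for u, v, c in dag.removed_edges:
                fh.write(f"{u}\t{v}\t{c:.6g}\n")
        if result is not None:
            result.score_table.to_csv(outdir / f"{group}.gene_scores.tsv", sep="\t")
            result.enrichment_table.to_csv(outdir / f"{group}.enrichment.tsv", sep="\t")
            write_gene_set(result.key_drivers, outdir / f"{group}.key_drivers.txt")
        if topology is not None:
            pd.Series(topology.as_dict()).to_csv(
                outdir / f"{group}.topology.tsv", sep="\t", header=False
            )
        pd.DataFrame([summary]).to_csv(
            outdir / f"{group}.summary.tsv", sep="\t", index=False
        )
        _log(
            outdir,
            group,
            {
                "group": group,
                "seed": int(seed),
                "stage_seeds": [int(s) for s in seq],
                "subsample": subsample,
                "filter_threshold": filter_threshold,
                "filter_fraction": filter_fraction,
                "learner": {
                    "n_seeds": learn.n_seeds,
                    "consensus_fraction": learn.consensus_fraction,
                    "max_parents": learn.max_parents,
                    "egene_bonus": learn.egene_bonus,
                    "alpha": learn.alpha,
                    "max_candidate_parents": learn.max_candidate_parents,
                    "max_passes": learn.max_passes,
                    "seed": learn.seed,
                },
                "kda": {k: (list(v) if isinstance(v, tuple) else v) for k, v in kda_params.items()},
                "summary": summary,
            },
        )
    return GroupResult(
        group=group,
        network=dag,
        kda=result,
        topology=topology,
        summary=summary,
        n_samples=mat.shape[1],
    )


def run_all(config: RunConfig) -> dict[str, GroupResult]:
    """Run every group in a config; returns results keyed by group label."""
    gwas = read_gene_set(config.gwas, "gwas")
    egenes = read_gene_set(config.egenes, "egenes") if config.egenes else None
    results = {}
    for group, path in config.expression.items():
        mat = read_expression(path)
        results[group] = run_group(
            mat,
            gwas,
            egenes,
            group=group,
            learn=config.learn_config(),
            kda_params=config.kda,
            filter_threshold=config.filter_threshold,
            filter_fraction=config.filter_fraction,
            subsample=config.subsample,
            seed=config.seed,
            output_dir=config.output_dir,
        )
    return results


def compare_cohorts(
    result_a: GroupResult,
    result_b: GroupResult,
    replicates: int = 10_000,
    seed: int = 0,
) -> dict:
    """Shared key drivers between two group runs plus the permutation null.

    The sampling universes are each network's connected genes (the genes
    eligible to be key drivers).  Emits a warning when the two gene
    universes differ (identifier mismatch or different inputs).
    """
    universe_a = result_a.network.connected_nodes()
    universe_b = result_b.network.connected_nodes()
    if universe_a != universe_b:
        warnings.warn(
            f"gene universes differ between {result_a.group} and {result_b.group} "
            f"({len(universe_a)} vs {len(universe_b)} connected genes)",
            stacklevel=2,
        )
    drivers_a = result_a.kda.key_drivers if result_a.kda else frozenset()
    drivers_b = result_b.kda.key_drivers if result_b.kda else frozenset()
    shared = shared_key_drivers(drivers_a, drivers_b)
    test = overlap_null(
        frozenset(universe_a),
        frozenset(universe_b),
        n_a=len(drivers_a),
        n_b=len(drivers_b),
        observed=len(shared),
        replicates=replicates,
        seed=seed,
    )
    return {
        "pair": (result_a.group, result_b.group),
        "shared": shared,
        "n_shared": len(shared),
        "overlap_test": test,
        "empirical_p": test.empirical_p,
    }


def overlap_matrix(
    results: dict[str, GroupResult], replicates: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Pairwise shared-driver counts and permutation p-values for all groups."""
    rows = []
    names = list(results)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            cmp = compare_cohorts(results[a], results[b], replicates, seed)
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "n_shared": cmp["n_shared"],
                    "empirical_p": cmp["empirical_p"],
                }
            )
    return pd.DataFrame(rows)


def prioritize(
    shared: frozenset[str] | set[str], annotations: pd.DataFrame
) -> tuple[frozenset[str], dict[str, int]]:
    """Narrow replicated key drivers to testable candidates via set filters.

    ``annotations`` is a per-gene table with boolean flags
    ``adipocyte_expressed`` (expressed in the target cell type),
    ``known_function`` (already characterized there), ``gwas_candidate``
    and ``mouse_phenotype`` (genetic evidence).  Filters, in order: keep
    target-cell-expressed; drop known-function; keep genes with either
    line of genetic evidence.  Genes absent from the table count as
    all-flags-false (warned).  Returns the final set and the count after
    each step.
    """
    missing_flags = set(ANNOTATION_FLAGS) - set(annotations.columns)
    if missing_flags:
        raise ValueError(f"annotation table missing columns: {sorted(missing_flags)}")
    shared = frozenset(shared)
    absent = shared - set(annotations.index)
    if absent:
        warnings.warn(
            f"{len(absent)} gene(s) missing from annotations treated as "
            "flag-false",
            stacklevel=2,
        )
    flags = (
        annotations.reindex(sorted(shared))
        .astype("boolean")
        .fillna(False)
        .astype(bool)
    )
    step1 = frozenset(flags.index[flags["adipocyte_expressed"]])
    flags1 = flags.loc[sorted(step1)]
    step2 = frozenset(flags1.index[~flags1["known_function"]])
    flags2 = flags.loc[sorted(step2)]
    step3 = frozenset(
        flags2.index[flags2["gwas_candidate"] | flags2["mouse_phenotype"]]
    )
    counts = {
        "input": len(shared),
        "cell_type": len(step1),
        "novel": len(step2),
        "genetic_evidence": len(step3),
    }
    return step3, counts
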