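# keydriver

Consensus Bayesian gene networks and key-driver analysis for adipose-tissue
fat-distribution genetics.

## The problem

Body-fat distribution (waist-to-hip ratio adjusted for BMI, WHR_adjBMI) is a
highly heritable cardio-metabolic risk factor, yet few of the ~500 genes near
its GWAS loci have established mechanisms in adipocytes. One productive
in-silico strategy is to model directed gene–gene regulation in adipose
tissue as a Bayesian network per sex/depot/cohort group and nominate "key
driver" genes — nodes that regulate far more downstream genes, or far more
disease-annotated downstream genes, than expected by chance — then replicate
the drivers across independent cohorts before committing to bench work.

`keydriver` is a desk-scale, fully tested implementation of that pipeline for
computational biologists: preprocessing and discretization of TPM expression
matrices, BIC-scored structure learning with correlation/eQTL priors merged
across many seeded runs, scale-free/small-world diagnostics, two-type
key-driver scoring, permutation nulls for cross-cohort agreement, the
evidence set-filters that narrow replicated drivers to testable candidates,
and the closed-form assay metrics (doubling time, Seahorse mitochondrial
phenotypes) used in functional follow-up. A synthetic-data generator with
planted hub regulators and disease labels makes every stage testable without
restricted-access cohort data.

## The model

Expression is discretized per gene into three levels (low/medium/high) by
one-dimensional k-means. A network structure is a DAG whose joint
distribution factorizes as P(X) = ∏ᵢ P(Xᵢ | Dᵢ) over parent sets Dᵢ; each
family is scored by

    BIC = k·ln(n) − 2·ln(L),  k = 2·3^|parents|,

with ln L the maximized multinomial log-likelihood of the child's levels per
joint parent configuration (lower BIC is better). Greedy hill-climbing
(add/remove/reverse) is restricted to candidate-parent pairs with Pearson
correlation P < 0.01 on the continuous data, favors eQTL-supported genes
(eGenes) as parents via an additive score bonus, and respects acyclicity and
an in-degree cap. Many seeded runs are merged by keeping edges present in
≥ 30% of runs (edge confidence = frequency), and residual cycles are broken
by deleting minimum-confidence cycle edges.

Key drivers come in two types. Type 1: each gene's downstream counts G_d at
exact shortest-path distances d = 1..10 are converted to network z-scores
Score_d = (G_d − NM_d)/NS_d and combined as

    GeneScore = Σ_d w_d·Score_d,
    w = (1, 1, 1, 0.75, 0.5, 0.25, 0.125, 0.0625, 0.03125) for d = 1..9,

with the top decile declared type-1 drivers. Type 2: each gene's downstream
neighborhood (within four edges) is tested for enrichment of a disease gene
set by a one-sided Fisher exact test against the rest of the network. The
per-network driver set is the union; drivers replicated in two cohorts are
the intersection, and their count is tested against a permutation null
(10,000 random same-sized gene sets drawn from each network).

## Worked example

Simulate a ground truth with 4 planted hub regulators and two replicate
cohorts, learn a consensus network per cohort, and compare their drivers:

```sh
keydriver simulate --n-genes 100 --n-hubs 4 --edge-density 0.05 \
    --n-samples-a 300 --n-samples-b 200 --seed 21 --out demo
keydriver learn demo/cohort_a.tsv --egenes demo/egenes.txt \
    --n-seeds 10 --max-candidate-parents 8 --seed 21 --out demo/netA.tsv
# consensus network: 99 connected genes, 120 edges (26 cycle edges removed)
keydriver kda demo/netA.tsv demo/gwas.txt --out-prefix demo/A
# type1=10 type2=1 union=11
```

The 11 recovered drivers for cohort A include all four planted hubs
(G05, G07, G12, G14). Repeating for cohort B (seed 22: 96 connected genes,
115 edges, 10 drivers) and comparing:

```sh
keydriver compare demo/run.yaml cohortA cohortB
# {"n_shared": 4, "empirical_p": 0.0110988901109889, "null_mean": 1.0848}
```

The four drivers shared between cohorts are exactly the planted hubs; four
shared genes against a null averaging ~1.1 is significant at p ≈ 0.011.
Topology diagnostics (`keydriver topology demo/netA.tsv`) report the
degree-exponent fit, clustering coefficient and average path length next to
size-matched random-graph baselines — the learned network clusters ~4× above
random (0.126 vs 0.029) at a shorter path length (2.0 vs 5.0), the expected
small-world signature.

The same steps are available as library calls (`simulate_dag`,
`make_replicates`, `run_group`, `compare_cohorts`, `prioritize`), and a YAML
config can drive multi-group runs end to end (`keydriver run config.yaml`).

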