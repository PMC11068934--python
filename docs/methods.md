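# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `keydriver`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Preprocessing

Expression matrices are genes × samples tables of non-negative TPM-scale
values. Genes with values below 0.1 TPM in strictly more than 80% of
samples are removed (the boundary case — low in exactly 80% — is retained);
the filter is idempotent. The log transform is the natural log with a +1
offset: it is defined at zero, monotone, and standard for TPM. Sample sexes
can be confirmed by splitting on a marker transcript (e.g. XIST); when no
threshold is supplied, the split point defaults to the midpoint of a
2-means clustering of the marker's values, since the marker is a
confirmation device rather than a calibrated assay.

Discretization maps each gene independently onto the ordered alphabet
low < medium < high by one-dimensional k-means with k = 3 (other k are
rejected — the downstream multinomial model is hard-coded to three levels).
The k-means is fit on the sorted values (10 restarts, fixed seed), which
makes the assignment invariant to sample ordering; clusters are relabelled
by ascending centroid, so levels are monotone in the underlying value, and
the induced interval boundaries are applied by thresholding. Degenerate
genes: a constant gene maps to all-medium, a two-valued gene to low/high
(both warned). Level boundaries are strictly per-gene: pooling genes never
changes another gene's levels.

## Bayesian-network structure learning

The model is a discrete Bayesian network over three-level variables: the
joint distribution factorizes into per-node conditional probability tables
given the parent set. Each family (node + parents) is scored by
BIC = k·ln(n) − 2·ln(L) with k = 2·3^|parents| free CPT parameters and n
the number of **samples**. Two textual conventions in the source
formulation are resolved deliberately: (i) n is taken as sample count (the
standard BIC penalty, and the only reading under which the score responds
to the data per family), and (ii) the score is **minimized** — the
quantity as written grows with model complexity, so maximizing it would
always prefer the densest graph. ln L is the maximized multinomial
log-likelihood of the child's levels within each observed joint parent
configuration; unobserved configurations contribute zero. The factorization
P(A|B,C) = P(A|B)·P(A|C) holds only under special independence
assumptions, so full joint-parent tables are used instead.

Search is greedy hill-climbing from the empty graph with add, remove and
reverse moves, restricted to candidate-parent pairs: gene pairs whose
Pearson correlation on the continuous (log) data reaches two-sided
P < 0.01 (constant genes excluded, with a warning). This correlation
screen, optionally capped at the `max_candidate_parents` strongest
partners per gene (|r|-ranked, then symmetrized), stands in for a
Markov-blanket candidate search and keeps a 200-gene consensus run at desk
scale. eGenes (cis-eQTL-supported genes) are favored as parents through an
additive score bonus per out-edge (default 1.0 on the BIC scale) — a soft
preference, not a constraint, because eQTL support makes a gene *more
likely* to be causal upstream, not certainly so. Moves are accepted only
if they lower the total score while keeping the graph acyclic and the
in-degree at or below `max_parents` (default 3). A pass with no accepted
move, or the `max_passes` budget (default 30), ends the climb. Randomness
enters only through the move-evaluation order, so each seed explores a
different local optimum.

`n_seeds` independent climbs (desk default 25; the published pipeline ran
1,000 — consensus behavior is testable at reduced seeds and the default is
configurable) are merged by keeping edges present in at least
`consensus_fraction` (default 0.30, inclusive) of runs; a retained edge's
confidence is its frequency. The merged graph may contain cycles; they are
removed by repeatedly deleting the minimum-confidence edge lying on any
cycle (ties broken by lexicographically smallest (parent, child) pair —
deterministic), logging every deletion. A shared family-score cache across
seeds makes the per-seed cost essentially the cost of the moves it
evaluates.

## Topology diagnostics

The out-degree distribution over parents (out-degree ≥ 1; zero-out-degree
nodes are excluded, since log 0 is undefined) is fit on the log-log scale
as log P(k) = −a·log k + b. The fit is least squares with each distinct
degree weighted by the number of parents carrying it — i.e., a fit over
nodes rather than over distinct degrees. The unweighted variant is biased
low on heavy-tailed data because the many singleton degrees in the tail
form a near-horizontal stripe; the node-weighted fit recovers planted
exponents on sampled discrete power laws (checked in the tests to ±0.3)
and leaves exactly collinear constructions exact. The reported r² is the
weighted coefficient of determination.

Clustering is the mean local clustering coefficient of the undirected
projection (nodes of degree < 2 contribute 0); the small-world clustering
metric is defined for undirected graphs. Average path length is the mean
directed shortest-path length over reachable ordered pairs, excluding
unreachable pairs. Both are compared against uniform random directed
graphs with identical node and edge counts (G(n, m) without self-edges),
averaging over seeded replicates.

The scale-free positive control, `preferential_attachment_network`, is a
Barabási–Albert graph with both orientations of every adjacency, so each
gene's out-degree equals its full attachment degree, the quantity whose
distribution follows the ~k⁻³ law. Orienting each adjacency only
old → new yields attachment counts whose distribution is not power-law at
small k and falls outside the 2–3 diagnostic band.

## Key-driver analysis

Every gene is profiled for its number of downstream genes at exact BFS
distances 1..10 ("exact" distance, not cumulative: the per-distance score
functions require disjoint shells). The network mean NM_d and **population**
SD NS_d at each distance are taken over all network genes, including genes
with zero downstream genes at that distance (they are part of the network
being described; excluding them would inflate NM). Score_d =
(G_d − NM_d)/NS_d, with Score_d = 0 whenever NS_d = 0, which preserves
ranking without undefined values. GeneScore is the weighted sum with the
weight vector (1, 1, 1, 0.75, 0.5, 0.25, 0.125, 0.0625, 0.03125) over
d = 1..9; the distance-10 count is profiled but unweighted, matching the
printed scoring formula. Type-1 drivers are the ⌈0.10·N⌉ highest scorers,
with all genes tied at the boundary included (deterministic and
conservative toward inclusion).

Type-2 drivers: for each gene, the downstream neighborhood within four
edges is crossed with the disease gene set in a 2×2 table over all network
genes except the focal gene (it cannot be its own downstream gene), tested
one-sided (greater) by Fisher's exact test. Empty neighborhoods give p = 1
automatically. Significance is nominal p < 0.05 by default — the
replication-across-cohorts step, not multiplicity correction, is the
false-positive control in this design — with Benjamini–Hochberg available
via `correction="fdr_bh"`. Per-network drivers are the union of the types;
replicated drivers the intersection across cohorts.

## Replication permutation null

The observed number of shared drivers between two networks is compared to
the null obtained by drawing, 10,000 times, a random gene set of the same
size as each network's driver list from that network's **connected** genes
(the genes eligible to be drivers; the full input geneset is available by
passing a different universe) and recording the intersection size. The
empirical p uses the add-one rule (1 + #{null ≥ observed})/(1 + R), never
exactly zero. The null mean converges to n_a·n_b·|A∩B|/(|A|·|B|), which
the tests verify within three Monte-Carlo standard errors.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes. A
ground-truth DAG over n genes lays genes along a topological order;
designated hubs sit early in the order and each non-hub gene draws ~1–3
parents from earlier genes, choosing a hub with probability 0.6 —
producing the scale-free-like out-degree skew the pipeline expects. Hubs
are root regulators (no parents): a gene upstream of a hub would inherit
the hub's entire subtree at distance 2 and outrank it, so parentless hubs
are what makes "well-separated hubs" well separated in downstream-count
profiles. Disease ("GWAS") labels are planted so that descendants of half
the hubs carry the label 5× more often than background (~15% of genes
labelled overall); eGene labels are the hubs plus a random 20% subset.

Expression follows a linear-Gaussian structural-equation model on the
latent scale: each gene is effect·mean(parents) + N(0, noise_sd), defaults
effect = 1.0 and noise_sd = 1.0, giving parent–child correlations of
~0.7 — strong but realistic co-expression for true regulatory pairs — and
mapped monotonically to a TPM-like scale as exp(latent + 2) (median ~7
TPM). Replicate cohorts share the truth with independent noise and may
have unequal sizes, emulating cohort imbalance and supporting sub-sampling
experiments. The generator deliberately omits RNA-seq count noise
(negative binomial), batch effects, and sex-chromosome biology: passing
tests demonstrate that the algorithms recover planted structure under the
model's own assumptions, not that real cohorts satisfy those assumptions.

## Problem sizes in the tests and acceptance script

Structure recovery is exercised on 20-node truths with 500 samples and 25
consensus seeds; driver recovery on 200-gene truths with 5 hubs, run both
on the true DAG (isolating the scoring from learning noise) and end-to-end
through discretization, priors and 25-seed consensus learning (500
samples, candidate parents capped at 10), averaged over 20 simulated
truths. Oracle checks run on random DAGs of up to 50–60 nodes against
boolean matrix-power reachability and exact rational hypergeometric tails.
These sizes were chosen as the smallest at which each property is
statistically meaningful; all are configurable upward.

## Numerical conventions and edge cases

- Duplicate edges in input collapse to the maximum confidence
  (conservative under consensus semantics); self-edges are rejected.
- Consensus thresholding is inclusive (frequency ≥ fraction) with a 1e-12
  float guard.
- Hill-climbing accepts a move only if it improves the score by more than
  1e-9, avoiding cycling on float ties.
- "Downstream genes at distance d" is the exact shortest-path shell;
  shells partition the reachable set.
- Degree-exponent fits require at least two distinct positive out-degrees;
  average path length requires at least one reachable ordered pair.
- Doubling time is undefined at zero growth (raises) and negative for a
  shrinking population (warned, returned).
- Seahorse phenotypes assume per-well normalization (e.g. Hoechst cell
  counts) has already been applied to the OCR values.

## Limitations

- The learner is a greedy local search over correlation-screened
  candidates, not an exhaustive or MCMC structure search; consensus over
  seeds is the hedge against local optima.
- Edge orientation within a correlated pair is only weakly identified from
  observational data; recovery is therefore evaluated on the skeleton, and
  the eGene bonus is the only orientation prior.
- Networks here are desk-scale (tens to hundreds of genes). The
  algorithms are polynomial and cache-friendly but have not been profiled
  at the ~8,500-gene published scale, which is cluster work.
- The prioritization filters encode literature/cell-type/mouse evidence as
  user-supplied boolean flags; the curation itself is not computable.
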