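# Methods

## Model and procedure

`crcsubtype` stratifies a probe-set × sample matrix of nonnegative
log2-scale expression values (RMA-style, *not* mean-centered) into a
two-level subtype hierarchy.  The engine is consensus non-negative matrix
factorization: X ≈ WH with W, H ≥ 0, fitted by Brunet-style multiplicative
updates that minimize the generalized Kullback–Leibler divergence

    D(X ‖ WH) = Σᵢⱼ [ Xᵢⱼ log(Xᵢⱼ/(WH)ᵢⱼ) − Xᵢⱼ + (WH)ᵢⱼ ].

Each restart clusters samples by the argmax row of H.  Stability over
restarts is summarized by the consensus matrix (fraction of restarts in
which two samples co-cluster) and its cophenetic correlation coefficient ρ:
the Pearson correlation between the consensus dissimilarities 1 − C and the
ultrametric distances of their average-linkage dendrogram.  ρ ≈ 1 means the
clustering is reproducible and tree-like; the rank with maximal ρ wins
(ties go to the smaller rank).

The iterative scheme runs this machinery on 100 random probe-set groups:
each group votes for a rank, the modal rank K sets the cluster number, each
group is clustered into K by cutting its consensus dendrogram, and pairwise
co-cluster counts over groups are accumulated.  Complete-linkage clustering
of (n_groups − counts) cut into K gives candidate clusters, trimmed to
*core clusters* by iteratively removing the member with the lowest mean
co-cluster count against the other retained members until every member's
mean count is ≥ the threshold (80/100 by default; when groups are skipped
as inseparable, the threshold is rescaled proportionally to the groups
actually used).  Cores with fewer than two samples cannot support a t-test
and are moved to the excluded list.

Signatures: among the 5000 highest-variance probes (variance computed over
the core samples of the current level, unbiased n−1 estimator, ties broken
lexicographically), a probe joins subtype S's up-regulated signature iff
for *every* sibling core the two-sample t-test reaches BH-adjusted
FDR < 0.01 (adjustment per pairwise comparison) with the higher mean in S.
Sibling signatures are disjoint by construction.  The recorded per-probe
statistics are those of the binding (least significant) comparison.

Assignment: samples are row mean-centered (per batch when batch labels are
present), hierarchically clustered with 1 − Pearson distance and complete
linkage on the union of signature probes, cut into the number of
signatures, and each cluster is labeled by the signature with maximal mean
centered expression over the cluster (greedy one-to-one matching; the
degenerate all-equal case falls back to label order and is logged).  The
second step repeats this inside each type on that type's subtype
signatures, re-centering within the type so the comparison is among its own
samples.  Discovery uses exactly this code path for its own training-set
assignment, so applying the saved model to the training matrix reproduces
the discovery labels.

Drug response: potencies are compared as per-compound centered −log
potency, v = −log₁₀(EC50) (or −ln(IC50)) minus the mean of v over cell
lines with data, so positive = more sensitive than the panel average.
Replicate measurements of a (line, compound) pair are collapsed by the
geometric mean before the log transform (potencies are conventionally
log-normal).  Compounds sharing a target are pooled; a cell line's value
for a target is the mean of its pooled centered values.  Subtype summaries
report mean, standard error and n over lines; group comparisons default to
the two-sided Wilcoxon rank-sum test on per-line means (exact for small
tie-free samples), with Welch's t available by flag.  The test choice is
this package's design decision: rank-sum is robust at the panel sizes
involved (≈ 5–30 lines per subtype).

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `n_groups` | 100 | random probe-set groups per level; co-cluster counts live on [0, n_groups] |
| `group_size` | 300 | probes per group — the order of magnitude of a mid-sized KEGG signaling pathway on an expression array |
| `core_threshold` | 80 | minimum mean co-cluster count (of 100) for core membership |
| `ranks` | 2–5 | candidate cluster numbers searched per group |
| `n_runs` | 30 | NMF restarts per (group, rank); consensus resolution is 1/n_runs |
| `max_iter`, `tol` | 200, 1e-4 (consensus stage) | short fits: cluster memberships stabilize long before the divergence tail, and restart diversity is what consensus measures.  Single factorizations via `nmf_factorize` default to 2000 / 1e-5 |
| `min_cluster_size` | 10 | below this a cluster is not split further (consensus on fewer samples is not meaningful) |
| `n_top_variance` | 5000 | variance filter before differential expression |
| `fdr_cutoff` | 0.01 | BH threshold per pairwise core comparison |
| `min_coverage` | 0.5 | fraction of a signature's probes that must be present when assigning another platform's matrix |
| effect Δ / noise σ / baseline µ (generator) | 2 / 1 / 7 log2 units | a 4-fold planted change against unit microarray noise on a realistic log2 baseline; µ − 4σ ≥ 0 keeps values nonnegative |

## Numerical choices

- A ridge of 1e−9 is added inside denominators and logarithms of the
  multiplicative updates.  The reported divergence keeps the ridge only
  inside the logarithm, so an exact factorization reports ≈ 0 (the ridge in
  the raw objective would add n·m·1e−9).
- Consensus-stage NMF runs in float32 (about half the runtime); single
  factorizations default to float64.  Rank k ≤ min(dims) is accepted.
- Convergence: relative divergence change over a 10-iteration window below
  `tol`.  The divergence is non-increasing under the updates; the test
  suite asserts this per iteration on random instances.
- Degenerate cophenetic input (all dissimilarities equal, e.g. an all-ones
  consensus) is defined as ρ = 1: the hierarchy is trivially exact.
- Tie handling is deterministic throughout: argmax ties take the lowest
  index, rank ties the smallest rank, modal-rank ties the smallest value,
  variance ties lexicographic probe order, label-matching ties label order.
  When tied merges leave fewer than K groups in a dendrogram cut, the
  largest groups are split deterministically so exactly K come back.
- Multiplicative KL updates can hit local minima even on exactly separable
  matrices (roughly 1 restart in 6 on rank-3 block-diagonal instances), so
  exact-recovery checks take the best of several restarts.
- Cophenetic rank selection has a known failure mode on *strongly*
  separated data: at too-small k the optimal merge of two true clusters can
  be deterministic, giving ρ = 1 and a tie that the smallest-rank rule
  resolves wrongly; at too-large k the consensus can remain tree-like.
  Many short restarts mitigate both (the reference check uses 40 restarts of
  100-iteration fits and recovers the planted k in 97/100 instances at
  effect 3σ).  In the full procedure the modal vote over 100 groups
  suppresses residual per-group errors.

## What the synthetic generator emulates — and what it does not

`generate_hierarchical_expression` plants a two-level hierarchy (2 types →
3 + 2 subtypes by default, 30 samples per subtype, 5000 probes) as disjoint
300-probe blocks shifted +Δ on a truncated-Gaussian log2 baseline;
`generate_drug_response` plants a subtype-specific shift on log10 EC50 with
Gaussian measurement noise, several compounds per target.  This reproduces
the *statistical shape* that the method assumes: nonnegative log-scale
intensities, block-structured differential expression, log-normal
potencies.

It does **not** emulate probe-level hybridization artifacts, correlated
probe sets of one gene, batch/scanner effects beyond per-set mean shifts,
tumor purity/stromal admixture gradients, heavy-tailed noise, or partially
overlapping signatures.  Passing the planted-recovery studies therefore
demonstrates that the implementation is correct and that the procedure
recovers clean hierarchical structure of the stated effect size; it does
not certify performance on real tumor cohorts, where effect sizes are
smaller and structure is blurrier.

## Reference study sizes

The acceptance studies (see `scripts/acceptance.py`) use: the default
generator (150 samples × 5000 probes) with 100 groups of 300, candidate
ranks 2–4 and 10 restarts per rank for discovery; 20 null replicates of
1000 probes / 30 samples for FDR calibration; a 33-sample, 1000-probe
outlier study (3 mixed-membership profiles injected); 100 small instances
each for divergence monotonicity and rank recovery; and 100 seeds of a
10-vs-10-line potency panel (shift equal to the per-measurement noise SD,
three compounds pooled per target) for detection power.  These sizes keep
the whole battery around ten minutes on one CPU while leaving every check
comfortably away from small-sample artifacts.

## Known limitations

- Depth is fixed at two levels (the discovery recursion stops at
  `max_depth`); deeper hierarchies would need externally validated stopping
  rules.
- Assignment is cohort-level (a dataset is clustered as a whole); there is
  deliberately no single-sample nearest-centroid classifier.
- Signatures are probe-set-level; gene-level collapsing is left to the
  caller except in directional-signature scoring, where probes of a gene
  are averaged.
- P-values for subtype–drug associations are reported raw, without
  multiple-testing control across targets.
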