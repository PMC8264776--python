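# Methods

This note documents the models, estimators and numerical choices behind
the package, the synthetic benchmark's assumptions, and the places
where the design was genuinely open.

## Candidate edge space

All engines share one edge universe: ordered TF → gene pairs over every
gene in the matrix (a TF never regulates itself). Symmetric scores
(correlation, MI-based) are emitted once per TF–gene pair with the TF
as regulator; a TF–TF pair is emitted in both orientations with the
same score, so that directed (GENIE3) and undirected engines rank the
same universe and the consensus can align them. Without a shared
universe, average-rank aggregation would conflate "ranked low" with
"not comparable".

## Mutual information

MI is estimated by equal-width discretization and the plug-in
(maximum-likelihood) entropy estimator in log base 2. Bins span
[min, max] with interior edges right-closed (a value on an edge falls
into the lower bin; the last bin includes the max; a constant profile
occupies a single bin). The default bin count is ⌈√n_samples⌉ — the
usual bias/variance compromise for plug-in estimators at these sample
sizes. Only ranks survive aggregation, so the estimator's (known,
positive) bias is immaterial downstream; the implementation is verified
to 1e-12 against an explicit triple-loop oracle.

CLR computes, for edge (i, j), z_i = max(0, (MI_ij − μ_i)/σ_i) against
gene i's background MI distribution (its MI with every other gene),
likewise z_j, and scores √(z_i² + z_j²). A degenerate background
(σ = 0, e.g. a constant gene) sets that z to 0 rather than erroring:
real compendia contain flat probes.

ARACNe applies the data processing inequality simultaneously on the
unpruned MI matrix: edge (i, j) is removed if some k adjacent to both
satisfies MI_ij < min(MI_ik, MI_jk)·(1 − ε). The inequality implies the
removed edge is a strict triplet minimum, so at most one edge per
triangle is ever removed. The default tolerance is ε = 0 (strict);
ε ≈ 0.15, the tolerance the method's original description recommends
for MI-estimation noise, is advisable on data with strongly
co-regulated blocks, where target–target MI rivals TF–target MI by
construction and a strict DPI also prunes genuine edges.

GENIE3-style importance: each gene in turn is a regression target
(standardized to unit variance) for a random forest over all candidate
TF profiles; the importance of TF t for target g is the mean total
variance reduction attributed to t across trees (unnormalized, so
importances are comparable across targets). Candidate-feature subset
size per split is ⌈√#candidates⌉; trees are fully grown. The
per-engine default is 1,000 trees; the benchmark configuration uses 100
(with 20 candidate regulators the ranking is already stable there — see
"Benchmark scale" below).

Ties are broken everywhere by descending score, then lexicographic
(regulator, target); ranks are therefore reproducible byte for byte.

## Consensus

The edge × method rank matrix is filled with each method's dense ranks;
an edge absent from a method is charged that method's worst present
rank + 1. The phrase "lowest rank plus one" is directionally ambiguous
in isolation; the worst-position reading is implemented because the
alternative (best rank + 1) would reward absence. Mean ranks are
re-ranked ascending and truncated to K; the stored consensus score is
the negated mean rank so score-descending order coincides with
rank-ascending order. Aggregation is permutation-invariant in method
order and monotone in any single method's rank — both property-tested.

## Modules

Target genes are linked when the Jaccard index of their predicted
regulator sets reaches the q-quantile of all nonzero Jaccard values
("high overlap" is relative to the consensus at hand, not a hard-coded
cutoff). Default q = 0.95, appropriate for sparse genome-scale
consensus networks. The benchmark configuration uses q = 0.80: with 4
blocks of 50 targets, ~25% of candidate pairs are genuinely
co-regulated, so a 0.95 cut necessarily discards most true pairs at
this scale and fragments the blocks, regardless of inference quality.

Markov clustering is implemented in full: self-loops at each node's
maximum incident weight, column-stochastic normalization, then repeated
expansion (matrix squaring) and inflation (entrywise power 2.0 by
default, then renormalization), pruning entries below 1e-5, until the
maximum entrywise change drops below 1e-8 (cap: 200 iterations, error
with the residual beyond that). Clusters are read from attractor rows
(positive diagonal); attractor rows with shared support are merged into
systems, and a gene claimed by several systems goes to the one holding
more of its column mass (ties: the system containing the
lexicographically smallest gene). Singletons are reported as
unassigned, and module ids M0001… are assigned by decreasing size.

The TF × module matrix G holds plain Jaccard indices between predicted
target sets and module gene sets; it is exact set arithmetic and tested
against an independent oracle at 1e-15.

Enrichment uses the hypergeometric upper tail P(X ≥ k) with
Benjamini–Hochberg correction applied jointly across all
(module, annotation set) tests; sets annotating fewer than 3 or more
than 500 genes are dropped before testing, and significance means
q < 0.05 (strict). Ontology annotations propagate child → ancestor
(the true-path rule: a gene annotated to a child term is implicitly
annotated to every ancestor); edges must be acyclic.

## Classifier

A linear-kernel SVM is trained on G with raw features (Jaccard indices
are already in [0, 1]; no standardization, so hyperplane coefficients
read directly as module importances). The penalty C is tuned on a grid
(0.001 to 10 in steps of 0.1 — exactly 100 points) by cross-validated
AUC-PR, sharing one seeded fold split across grid points; ties go to
the smallest C. Cross-validation is stratified (required to avoid
single-class folds at small n; folds differ in size by at most one),
re-drawn up to 100 times if a fold ends up single-class.

AUC-PR is computed by precision–recall step integration over distinct
score thresholds and matches a threshold-enumeration oracle exactly.

Final scores come from one stratified 5-fold round: every fold model
scores every TF; a labeled TF averages the four models that trained on
it, and an unlabeled TF (no fold of its own) averages all five — the
only symmetric choice. TFs are ranked by descending mean margin D and
DS = 1 − (rank−1)/(N−1). Rank scaling (rather than min-max scaling of
raw D) is the canonical DS because it is comparable across retrainings;
raw D is preserved in the table. Class weighting for imbalanced labels
is available but off by default.

Two negative controls re-run the same cross-validation with
pseudo-positives drawn uniformly from all TFs, or drawn to match the
positive class's family composition (with replacement only when a
family is too small, logged). Feature importance is the absolute
hyperplane coefficient averaged over the five fold models.

The bin diagnostic sorts TFs by DS, splits them into equal bins
(remainder spread over leading bins), and asks how well each bin's TF
expression profiles classify samples into the two condition groups
(stratified 3-fold CV, AUC-ROC). Bins with no TF present in the
expression matrix are recorded as missing rather than erroring.

## Synthetic benchmark

The generator plants P programs of T TFs each; program p's TFs
regulate every gene of a disjoint block of G targets with weights
~ Normal(w, 0.1w) and random sign; cross-program TF → target edges
appear independently with probability p_bg. TF profiles are i.i.d.
standard normal per sample; the TFs of the first stress-designated
program(s) gain a mean shift δ in stress samples; each target is the
weighted sum of its regulators plus Normal(0, σ) noise. Defaults: 4
programs × 5 TFs × 50 targets, 75 control + 75 stress samples,
p_bg = 0.01, w = 1, δ = 2, σ = 0.5, one stress program. All randomness
flows from a single integer seed through named generators.

Stress-program TFs are the labeled positive class. Family tags cut
across programs (the i-th TF of every program shares a family): real
TF families are not aligned with regulatory programs, and a
family-matched control is only a genuine null when matching the family
histogram does not reproduce the positive set itself.

The linear additive Gaussian model is deliberately the common ground
every engine in scope must detect. It omits probe/batch effects,
nonlinear kinetics, feedback (an option plants TF → TF edges for
direction stress-tests) and combinatorial regulation — so passing
tests demonstrate correct mechanics and sensible relative behavior of
the stages, not performance claims on real compendia.

## Benchmark scale

Tests and the acceptance script run the benchmark at desk scale:
220 genes × 150 samples, edge retention K = 1000 (planted regulators
per target × number of targets — the analogue of retaining top edges
on the order of the expected true edge count, as one does at genome
scale with K = 500,000), 100 trees per forest, co-regulation quantile
0.80 as above. The genome-scale defaults (K = 500,000, q = 0.95,
1,000 trees) remain the package defaults.

## Known limitations

* MI binning is equal-width only; adaptive or kernel estimators are out
  of scope (ranks, not MI values, drive the consensus).
* ARACNe at strict tolerance over-prunes dense co-regulated blocks;
  use ε > 0 there (see above).
* The co-regulation quantile is the single most sensitivity-relevant
  parameter; it should be rescaled with the expected co-regulated pair
  fraction of the data at hand.
* The classifier is linear by design — coefficients are the product
  (module importances); nonlinear kernels are out of scope.
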