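# Methods

This note documents the model implemented by `ihnet`, the choices made
where the design was genuinely open, the study conditions emulated by the
synthetic-data generator, and the known limitations. Nothing here states a
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Input preprocessing

Feature matrices (entities × samples, one per omics layer) are restricted
to the samples shared by all layers (sorted order, idempotent) and each
entity row is z-scored across samples with the population convention
(ddof = 0), so that the Pearson correlation of two rows is exactly their
dot product divided by the sample count. Zero-variance rows map to all-zero
rows. Missing values are imputed to the row mean before scaling (hence to
exactly 0 after centering); entities missing in more than 20% of samples
(configurable) are dropped. Pearson correlation is invariant to affine
row transforms, so the choice of z-scoring affects only the scale of the
regression coefficients, not the correlational edges; the choice is
recorded in the matrix's `normalized` flag.

CNV segment tables are collapsed to per-gene values as the
overlap-length-weighted mean of all segments intersecting the gene's
transcript span. Coordinates are treated as 0-based half-open; strand is
ignored; for genes with several transcript rows the longest span is kept;
genes without any overlapping segment in a sample get 0 (logged). STRING
combined scores (0–1000) are divided by 1000; duplicate interaction pairs
collapse to their maximum weight; PPI self-edges are dropped; PPI edges
with an endpoint absent from the expression matrix are removed.

## Network construction

**Correlational edges** are seed-anchored: only pairs with at least one
seed endpoint are tested, with the two-sided correlation t-test
t = r·√((n−2)/(1−r²)) and a default p < 0.05 cutoff (configurable; whether
to threshold on p, on |r|, or not at all was an open choice — a p cutoff
keeps edge density calibrated under the null, which the tests verify).
Kept entries are |r|, symmetrized. Each seed is correlated against the full
entity matrix one seed at a time (BLAS matrix–vector product), so a pair's
value never depends on which other seeds are present; this is what makes
the cached leave-one-out re-wiring exactly equal to a full rebuild.

**Normalization** of every symmetric nonnegative matrix M is
M̄(i,j) = M(i,j)/√(E(i,i)·E(j,j)) with E(i,i) the row sum; zero-sum rows
stay zero. This is the symmetric diagonal scaling whose spectral radius is
at most 1 (verified on random instances by dense eigendecomposition), which
guarantees convergence of the damped iteration for any λ < 1.

**Fusion** on the expression layer is the noisy-OR
w = 1 − (1 − m^pcc)(1 − m^ppi): monotone in both arguments, bounded in
[0, 1], never below either input. The other three layers carry their
normalized correlation matrices unchanged.

**Regulatory regression** is per-gene OLS with an intercept (on z-scored
inputs the intercept is ≈ 0; it is reported but never used as an edge
weight). Rank deficiency — e.g. collinear miRNA regulators — is resolved by
the minimum-norm least-squares solution. Genes missing a CNV or methylation
row, or with fewer samples than parameters, are marked unfit and get no
inter-layer edges. Edge weights use |β| because propagation weights must be
nonnegative; signs are retained in the fit objects for reporting.

**Assembly** keys nodes by (entity, omics), so the same gene id in three
layers is three distinct nodes, never a collision. The global transition
matrix W̄ applies the same sqrt-row-sum normalization to the full block
matrix. Resistance defaults є = |V|/|E|² and β = 1/|E| are derived from the
assembled network (undirected edge count) and re-derived per cross-validation
fold.

## Propagation

Priors follow the three-branch rule (seed → 1; non-seed with N_v ≥ α →
n_v/N_v; non-seed below α → e^(N_v−α)·n_v/N_v; isolated non-seed → 0),
with neighbors counted on the binary adjacency of the raw weighted network,
not weighted degree. α defaults to 50.

The iteration is S^t = λ·f(S^{t−1}) + (1−λ)·D with S^1 = D and λ = 0.2.
Without resistance f(S)_v = Σ_u S_u·W̄(u,v), whose fixed point is the
linear solve (1−λ)(I − λW̄)^(−1)D — the test suite checks the iterate
against that dense oracle to 1e−6 on networks up to 200 nodes. With
resistance, each transition becomes SR(u,v) = max(S_u·W̄(u,v) − є, 0),
zeroed entirely when the target scores below θ = 0.005 *and* its strongest
incoming flow is below β. Both branch conditions are evaluated against the
previous iterate, so each update is a function of S^{t−1} alone and reruns
are bit-identical. Resistance can only lower scores (SR ≤ S_u·W̄ pointwise
and the map is monotone), and every score keeps the floor (1−λ)·D_v; both
properties are asserted in the tests.

The stopping rule is the mean (not sum) of squared per-node changes
falling to 1e−5; "mean" was chosen as the literal reading of mean square
error, and the tolerance is configurable where a tighter fixed point is
needed (the linear-solve comparisons run at 1e−18). Hitting the iteration
cap (default 1000) flags the result as non-converged rather than raising.

A gene's final score is the maximum over its expression/CNV/methylation
nodes; miRNA nodes are scored but never ranked.

## Cross-validation and metrics

One fold per seed gene entry (miRNA seeds always stay in the training
set). The held-out seed's anchored correlation edges are dropped unless the
other endpoint is still a seed — exactly what recomputing with the reduced
seed set yields — its prior is recomputed as a non-seed, and є/β are
re-derived from the fold's network. Regression coefficients do not depend
on seed status and are reused. The cached masking path and the naive
per-fold rebuild are enforced to be bit-identical by a test.

Ranks use the pessimistic tie convention (tied candidates count as better).
The ROC sweeps the rank threshold as a fraction of each fold's ranking-list
size; because every fold shares one candidate set, the trapezoid AUC equals
the Mann–Whitney pairwise count exactly (asserted to 1e−12). Sensitivity at
a specificity floor is the highest Sn among sweep points with Sp at or
above the floor. Top-k% fractions count held-out seeds whose rank among
*all* genes (training seeds included) falls in the top ⌊k·G/100⌋, with an
upper-tail hypergeometric p-value over (G genes, s seed genes, top-K
slice); the hypergeometric tail is cross-checked against exhaustive
enumeration for populations ≤ 30. Fold enrichment is (candidates/2)/rank
per fold, averaged. Precision/recall pool TP = [rank ≤ k] and FP = k − TP
per fold over thresholds 100..2000 (capped at the list size); k = 0 reports
precision 0 by convention.

At desk scale the top-5% slice is structurally hard: 5% of 500 genes is 25
ranks, and the ~29 training seeds — which properly keep their high scores —
can fill it entirely, so the top-5% fraction can be 0 even when ranking is
excellent. The effect vanishes as the gene universe grows relative to the
seed list.

## Synthetic study conditions

The generator's defaults define the conditions under which the pipeline is
exercised: 500 genes × 300 samples, 60 miRNAs, 30 seed genes split 20/4/6
across expression/CNV/methylation and 5 seed miRNAs (preserving the layer
proportions of curated disease-gene lists at desk scale), modules of 10
entities with within-module correlation ρ = 0.8, regression noise sd 0.5,
PPI density 0.01 with seed/module pair probabilities enriched ×25 and
weights U(0.4, 0.99), and coefficient ranges β_cnv ∈ (0.8, 1.5),
β_methy ∈ (−1.2, −0.4), β_mir ∈ (−0.8, −0.3) (methylation and miRNAs
repressive, as is typical).

Modules group a layer's seeds four per module plus non-seed recruits, all
sharing one latent factor x = √ρ·f + √(1−ρ)·noise — the simplest structure
with tunable pairwise correlation. CNV- and methylation-module genes also
receive a planted coefficient for their layer, so module structure
propagates into expression; expression-module genes instead carry their
factor in the regression noise term with all coefficients zero, which keeps
the regulatory model exact *and* puts their pairwise expression correlation
at ρ. A disjoint set of 60 regulated genes carries all three coefficient
types for regression-recovery checks. The null configuration (ρ = 0, all
coefficient ranges collapsed to 0, no PPI enrichment) leaves seeds with
label-only status; under it the LOOCV AUC sits at 50% and the
correlation-edge acceptance rate at the p cutoff, which is how the t-test
calibration is validated end to end.

What the generator does not emulate: platform artifacts (RSEM/RPM
distributions, 450K beta bimodality, segment noise), gene-length or GC
biases, population substructure, and realistic PPI topology (edges are
Erdős–Rényi with enrichment, not scale-free). Passing tests therefore show
that the algorithmic chain is correct and calibrated, not that the method's
real-data performance numbers transfer.

Replicated calibration runs (null calibration, AUC-vs-ρ monotonicity) use a
200-gene/20-seed-gene scaling of the same shape with 10–20 replicates —
sizes chosen so the whole suite stays interactive while binomial/Monte-Carlo
error stays well inside the asserted bands.

## Known limitations

* Correlation edges are seed-anchored only; candidate–candidate
  correlation, however strong, never forms an edge.
* The regression is per-gene OLS: no shrinkage, no interaction terms, and
  coefficient magnitudes (hence inter-layer edge weights) depend on the
  normalization convention.
* Scores are comparable within one network but not across folds or
  datasets; all pooled metrics therefore work on ranks, not raw scores.
* Diseases with no known seeds, or cohorts missing one of the four omics,
  are outside the model's assumptions.
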