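# Methods

## Model

The package scores pathways per sample by diffusing gene-level
differential-significance over a directed, two-layer gene-gene graph and
then combining the converged node weights with per-gene direction scores
and standardized measurements.

**Graph.** Expression nodes carry the pathway-derived directed edges,
restricted to genes actually measured. Every gene measured on both the
expression and the copy-number layer gets one CNA node and exactly one
cross-layer edge (g, CNA) → (g, EXPR). CNA nodes never receive edges and
are never connected to each other, encoding the asymmetric assumption that
copy-number state can drive expression but not vice versa. Nodes are
ordered by (layer, gene) so all matrices and weight vectors are
reproducible across runs. The transition matrix is the row-normalized
adjacency; rows of dangling nodes stay all-zero rather than being
redistributed — the restart term keeps the iteration well-posed, and this
matches the update equation literally. Mass lost at dangling nodes is not
re-injected.

**Seed weights.** W₀ = −log(w_g + ε) with ε = 2.2e−16, where w_g is the
gene's test p-value (genes absent from the data get w_g = 1). The raw
values are min–max rescaled to [0, 1] *within each layer* and the
concatenated vector is L1-normalized. Per-layer scaling prevents one
layer's p-value distribution (e.g. many tiny expression p-values) from
drowning the other layer's seed mass; a layer whose raw values are
constant is filled with a uniform 0.5 before normalization, which reduces
to the uniform distribution in the single-layer case.

**Walk.** W_{t+1} = (1 − r) Mᵀ W_t + r W₀ with restart probability
r = 0.7 (the method is known to be insensitive to r in this family of
diffusion scores). Convergence is declared when the L1 norm of the update
falls below 1e−10; with r > 0 and substochastic M the map is a
contraction, so the `max_iter = 10000` guard is a safety net for CLI use
only. `solve_direct` solves (I − (1 − r)Mᵀ)W = rW₀ by sparse LU and
serves as an independent oracle for the iteration in the tests.

**Activity.** For pathway P_j, only *differential* layered members
(w_g < 0.05, raw, no multiple-testing correction) contribute:

    a(P_j) = Σᵢ W_∞(gᵢ)·score(gᵢ)·z(gᵢ) / sqrt(Σᵢ W_∞(gᵢ)²).

The score is sign(t) for continuous expression, the Wald log₂ fold change
for counts, and the poor-minus-good mean call difference for CNA — all
oriented so positive means higher in the poor-survival group. z(g) is the
per-gene standardization across samples (ddof = 1; constant genes map to
zero); for CNA genes it is computed on the raw calls. A gene significant
on both layers contributes two terms. The ratio is invariant to positive
rescaling of W_∞ and, for a single member, reduces to score·z. Pathways
with no contributing member are flagged excluded and never reach feature
selection — a zero activity row has an undefined t-statistic, so carrying
it forward would poison the ranking.

## Gene-level tests

* **Continuous expression:** two-tailed two-sample t-test, Welch by
  default (`variant="student"` for the pooled-variance form). The Welch
  default is the robust choice when group variances are unknown.
* **Copy-number calls:** Pearson χ² test of independence on the
  (call category × class) table, no continuity correction. Categories
  absent from the data are dropped. Sparse categories are pooled into the
  nearest neighbouring call state when any expected cell count falls below
  Cochran's threshold of 5: without pooling the test is noticeably
  conservative at realistic call sparsity (the extreme states ±2 occur in
  only a few percent of samples), and pooling restores the nominal type-I
  rate while leaving well-filled tables untouched. A constant call vector
  returns p = 1 by convention.
* **RNA-seq counts:** negative-binomial GLM (log link, class covariate,
  log size-factor offset) with per-gene method-of-moments dispersion
  (floor 1e−8), Wald test on the class coefficient; log₂FC is the
  coefficient divided by ln 2. Size factors use median-of-ratios over
  genes positive in all samples. This is a deliberately simple NB test —
  no shrinkage across genes — and a plug-in path accepts precomputed
  (p, log₂FC) tables from any external differential-expression tool;
  plugged-in values are only range-validated. All-zero genes return
  (p = 1, log₂FC = 0); a group with zero total count gets a 0.5
  pseudocount so the coefficient stays finite.

## Evaluation protocol

Pathways are ranked by two-sample t-tests of their activities (ascending
p, ties broken by descending |t| then pathway id), the top-k activities
feed an unpenalized maximum-likelihood logistic regression (features
standardized on training statistics; ridge fallback when a perfectly
separable fold prevents convergence), with POOR as the positive class for
precision/recall and the zero-division convention precision = recall = 0.

Two protocols:

* **default (leakage-free):** gene statistics, walk, activities and the
  ranking are re-estimated on each training split; held-out samples are
  transformed with training parameters only (stored gene means/sds; for
  PLAGE, projection onto the training singular vector u₁ᵀz/σ₁).
* **paper_mode:** statistics and ranking computed once on all samples,
  folds only refit the classifier. This is the protocol commonly used in
  the literature for this family of methods; it is optimistically biased
  and provided for comparability, not as the default.

Folds are stratified by class; the repeated scheme yields
repeats × n_folds evaluations (50 × 5 = 250 by default), LOOCV yields one
per sample. The subsample-sensitivity analysis draws floor(fraction·n)
samples, allocated to classes by largest remainder (70% of a 1648-sample
cohort draws exactly 1153).

A note on interpreting null cross-validation accuracy: for a single finite
cohort the repeated folds reuse the same samples, so the per-cohort mean
accuracy under the null is unbiased at 0.5 but has substantial spread
across cohorts (sd ≈ 0.08 at 100 samples); averages over independent
cohorts stabilize it.

## Synthetic cohorts

The generator emulates the structure of a two-class, two-layer survival
cohort: background expression ~ N(0, 1) (or NB counts with lognormal base
means, dispersion 0.1, via a gamma–Poisson mixture), CNA calls from a
categorical over {−2…2} with baseline probabilities
(0.02, 0.08, 0.80, 0.08, 0.02) resembling GISTIC-style call sparsity,
disjoint pathways of equal size, within-pathway directed edges at a fixed
density (default 0.15), and a configurable fraction of genes measured on
both layers (default 0.8). Planted signal shifts the planted pathway's
member genes by `delta_expr` standard deviations (default 2.0) in the
poor group — or multiplies count means by `fold_change` (default 4.0) —
and moves `delta_cna_gain` (default 0.15) of the neutral-call probability
to the +1 call. Defaults correspond to the reference study condition used
throughout the tests: 50+50 samples, 30 pathways × 20 genes, one planted
pathway. Everything is driven by one integer seed and is byte-reproducible.

What the generator does **not** emulate: gene-gene correlation beyond the
planted mean shifts, overlapping pathway membership, realistic edge
topology (hubs, scale-free degree), copy-number segmentation (calls are
drawn independently per gene rather than in chromosomal blocks), batch
effects, or censoring in the survival labels. Passing tests therefore
demonstrate correctness of the computations and recoverability of planted
signal under idealized noise — not expected performance on real cohorts,
where effect sizes are far smaller and correlation structure matters.

## Numerical choices and conventions

* Duplicate gene rows in input matrices are collapsed by median; missing
  cells are imputed with the per-sample median (rounded to the nearest
  integer for calls); genes missing in more than half the samples are
  dropped for count/call layers.
* PLAGE uses the standardized member submatrix and fixes the arbitrary
  SVD sign so the activity correlates nonnegatively with the mean member
  z-profile.
* Walk convergence uses the L1 norm, consistent with the unit-vector
  framing of W₀.
* Problem sizes in the automated checks (graph sizes 10–500, 2000-gene
  null panels, 10 recovery seeds, 5 CV repeats) were chosen to exercise
  the method at its reference study condition while keeping a full run in
  the minutes range on one CPU.

## Known limitations

* The NB Wald test is anti-conservative for very small groups and makes
  no attempt at dispersion shrinkage; use the plug-in path for serious
  RNA-seq work.
* One CNA node connects to exactly one expression node (same gene symbol);
  many-to-many probe/locus relations must be supplied as extra edges.
* Edge semantics (activation/inhibition, KGML relation subtypes) are
  flattened to plain directed edges.
* No survival regression on continuous time; the grouping is binary.
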