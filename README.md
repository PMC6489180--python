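# idrw

Pathway activity inference for survival-group classification by an
**integrative directed random walk** over a two-layer gene-gene graph that
combines gene expression with copy-number alteration (CNA) calls.

## Who this is for

Cancer genomics groups that have, for one cohort, (a) a continuous
expression matrix (microarray log-intensities or RNA-seq counts), (b) a
discrete gene-level copy-number call matrix (GISTIC-style values in
{−2,−1,0,1,2}), (c) a binary survival grouping of the samples (good/poor),
and (d) pathway definitions with directed gene-gene interactions (KEGG
KGML files or a plain edge list). The package turns gene-level measurements
into per-sample, per-pathway activity scores that can be ranked and fed to
a classifier, so that results are interpretable at the pathway level rather
than as anonymous gene signatures.

## The method

1. **Integrated graph.** Directed pathway-derived edges connect expression
   nodes. Each gene measured on both layers additionally gets a CNA node
   with a single directed edge (g, CNA) → (g, EXPR): copy-number state may
   influence expression, never the reverse, and CNA nodes receive no edges.

2. **Gene statistics.** Each layered gene g gets a p-value w_g from a
   layer-appropriate two-group test (two-tailed t-test for continuous
   expression; χ² test of independence for discrete calls; a
   negative-binomial Wald test for counts), a signed direction score
   (sign t, log₂ fold change, or poor-minus-good mean call difference) and
   a standardized sample vector z(g).

3. **Random walk with restart.** Seed weights
   W₀ = −log(w_g + ε), ε = 2.2e−16, min–max scaled per layer and
   L1-normalized, are diffused along the graph:

       W_{t+1} = (1 − r) Mᵀ W_t + r W₀,     r = 0.7,

   with M the row-normalized adjacency matrix, iterated until the L1
   change is below 1e−10. The fixed point W_∞ up-weights genes that are
   both differential and topologically central.

4. **Pathway activity.** For pathway P_j with differential members
   (w_g < 0.05) g₁…g_nj, the per-sample activity is

       a(P_j) = Σᵢ W_∞(gᵢ) · score(gᵢ) · z(gᵢ) / √(Σᵢ W_∞(gᵢ)²).

   A gene present on both layers contributes one expression term and one
   CNA term. PLAGE (first singular vector of the standardized member
   submatrix) and the combined z-score are included as expression-only
   baselines.

5. **Evaluation.** Pathways are ranked by t-tests of their activities,
   the top-k (k = 5…50 by 5) feed an unpenalized logistic regression, and
   performance is assessed by repeated stratified 5-fold CV (50×5 = 250
   evaluations) or leave-one-out CV, reporting accuracy, precision, recall
   and F1. Cross-validation is leakage-free by default (statistics, walk,
   ranking re-estimated per training split); `paper_mode=True` ranks once
   on the full cohort, the optimistic protocol common in the literature.

A synthetic cohort generator with planted pathway signal makes the whole
pipeline testable without any external data.

## Worked example

```python
from idrw import *
from idrw.evaluate import CVPlan, cross_validate, rank_pathways
from idrw.simulate import SimulationConfig, simulate_cohort

cfg = SimulationConfig(seed=11)   # 50+50 samples, 30 pathways x 20 genes,
                                  # one planted pathway (2 sd shift)
expr, cna, labels, pathways, edges, truth = simulate_cohort(cfg)

graph = add_cna_layer(build_expression_layer(edges, expr.genes), cna.genes)
stats = build_stat_table([expr, cna], labels)
winf = walk(row_normalize(graph), initialize_weights(stats, graph))
act = idrw_activity(pathways, stats, winf)
print(rank_pathways(act, labels).head(3))
```

prints (the planted pathway is `PW000`):

```
            p_value          t
PW000  4.096146e-67  44.836764
PW013  3.665423e-05   4.325514
PW021  3.255931e-04   3.725805
```

i.e. the planted pathway separates the survival groups at p ≈ 4e−67 while
the best unplanted pathway sits ~60 orders of magnitude behind. The
membership audit `act.membership.loc["PW000"]` reports
`n_total 37, n_exp_sig 20, n_cna_sig 7`: all 20 expression members and 7
of the 17 CNA members of the planted pathway are individually significant.
Cross-validating the classifier:

```python
report = cross_validate(expr, labels, pathways, edges=edges, cna=cna,
                        plan=CVPlan(repeats=5, seed=11), k_grid=(5, 10))
print(report.summary().round(3))   # mean accuracy 0.998 at k = 5
```

The same pipeline is available from a shell:

```bash
idrw simulate --out cohort --seed 11
idrw evaluate --method idrw --expr cohort/expression.tsv \
    --cna cohort/cna_calls.tsv --labels cohort/labels.tsv \
    --gmt cohort/pathways.gmt --edges cohort/edges.tsv \
    --repeats 5 --seed 11 --out report.tsv
```

## Layout

| module          | contents                                                   |
|-----------------|------------------------------------------------------------|
| `idrw.types`    | `OmicsMatrix`, `SampleLabels`, `PathwayCollection`, layers  |
| `idrw.io`       | TSV/GMT/edge-list/KGML readers, GraphML subnetwork export   |
| `idrw.graph`    | two-layer `IntegratedGraph`, transition matrix              |
| `idrw.stats`    | per-gene tests, scores, standardization, plug-in path       |
| `idrw.walk`     | seed weights, restart walk, direct linear solve             |
| `idrw.activity` | walk-based activity, PLAGE, z-score                         |
| `idrw.evaluate` | ranking, top-k, logistic CV, subsample sensitivity          |
| `idrw.simulate` | synthetic cohorts with planted signal, worked example       |
| `idrw.cli`      | `idrw` command-line entry point                             |

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
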