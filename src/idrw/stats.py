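"""Per-gene differential statistics for each omics layer.

Each layered gene gets three quantities that feed the walk and the
activity formula:

* ``w_g`` — the p-value of a layer-appropriate two-group test (t-test for
  continuous expression, chi-square test of independence for discrete
  copy-number calls, negative-binomial Wald test for RNA-seq counts);
* ``score(g)`` — a signed direction-of-change summary (sign of the
  t-statistic, log2 fold change, or poor-minus-good mean call difference),
  oriented so positive means higher in the poor-survival group;
* ``z(g)`` — the per-sample standardized value vector.

The table stores the standardization mean/sd so held-out samples can be
transformed with training-set parameters only.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .types import Layer, LayerKind, OmicsMatrix, SampleLabels

log = logging.getLogger(__name__)

__all__ = [
    "GeneStatTable",
    "ttest_gene",
    "chisq_gene",
    "nb_wald_gene",
    "size_factors",
    "cna_score",
    "standardize_gene",
    "build_stat_table",
]

ALPHA = 0.05  # raw p-value cut for "differential" genes


def ttest_gene(
    values: np.ndarray, poor_mask: np.ndarray, variant: str = "welch"
) -> tuple[float, float]:
    """Two-sided two-sample t-test, POOR vs GOOD contrast.

    Returns (p_value, t_statistic) with t > 0 when the POOR group mean is
    higher. ``variant`` is ``"welch"`` (unequal variances, default) or
    ``"student"`` (pooled variance).
    """
    values = np.asarray(values, dtype=float)
    poor, good = values[poor_mask], values[~poor_mask]
    if len(poor) < 2 or len(good) < 2:
        raise ValueError("need at least 2 samples per class for a t-test")
    if np.array_equal(np.sort(poor), np.sort(good)):
        return 1.0, 0.0
    t, p = scipy.stats.ttest_ind(poor, good, equal_var=(variant == "student"))
    if not np.isfinite(t):  # both groups constant and equal handled above
        return 1.0, 0.0
    return float(p), float(t)


def _pool_sparse_categories(
    table: np.ndarray, cats: np.ndarray, min_expected: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Pool categories with an expected count below Cochran's threshold into
    the nearest (by call value) neighbouring category. Without pooling the
    test is noticeably conservative at realistic call sparsity, where the
    extreme call states are rare."""
    while table.shape[0] > 2:
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        bad = np.where((expected < min_expected).any(axis=1))[0]
        if len(bad) == 0:
            break
        i = bad[0]
        j = i + 1 if i == 0 else i - 1
        table[j] += table[i]
        table = np.delete(table, i, axis=0)
        cats = np.delete(cats, i)
    return table, cats


def chisq_gene(calls: np.ndarray, poor_mask: np.ndarray) -> float:
    """Pearson chi-square test of independence of (call category x class).

    No continuity correction. Categories absent from the data are dropped;
    sparse categories (expected count < 5) are pooled into the nearest
    category so the large-sample approximation holds. A constant call
    vector is not testable and returns p = 1.
    """
    calls = np.asarray(calls)
    cats = np.unique(calls)
    if len(cats) < 2:
        return 1.0
    table = np.stack(
        [
            np.array([(calls[~poor_mask] == c).sum() for c in cats]),
            np.array([(calls[poor_mask] == c).sum() for c in cats]),
        ],
        axis=1,
    ).astype(float)
    table, cats = _pool_sparse_categories(table, cats)
    if table.shape[0] < 2:
        return 1.0
    stat, p, _, _ = scipy.stats.chi2_contingency(table, correction=False)
    return float(p)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors.

    For genes with all-positive counts, s_j = median_g(count_gj / geometric
    mean of gene g). Raises when no gene is positive in every sample.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene with all-positive counts; supply size factors computed "
            "with a pseudo-reference instead"
        )
    logs = np.log(mat[positive])
    log_geo = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - log_geo, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _nb_dispersion_mom(q: np.ndarray, poor_mask: np.ndarray, floor: float = 1e-8) -> float:
    """Method-of-moments NB dispersion from size-factor-normalized counts,
    using within-group residuals (small-sample bias corrected)."""
    groups = [q[poor_mask], q[~poor_mask]]
    n = len(q)
    resid_sq = sum(((g - g.mean()) ** 2).sum() for g in groups)
    var = resid_sq / max(n - 2, 1)
    mean = q.mean()
    if mean <= 0:
        return floor
    return max((var - mean) / mean**2, floor)


def nb_wald_gene(
    counts: np.ndarray,
    poor_mask: np.ndarray,
    size_factors: np.ndarray | None = None,
) -> tuple[float, float]:
    """Negative-binomial GLM Wald test on the class coefficient.

    Fits log mu = b0 + b1 * [POOR] + log(size factor) with per-gene
    method-of-moments dispersion (floor 1e-8) and returns
    (p_value, log2 fold change POOR vs GOOD). An all-zero gene returns
    (1.0, 0.0). Groups with zero total count get a 0.5 pseudocount so the
    coefficient stays finite.
    """
    counts = np.asarray(counts, dtype=float)
    if poor_mask.sum() < 2 or (~poor_mask).sum() < 2:
        raise ValueError("need at least 2 samples per class")
    if size_factors is None:
        size_factors = np.ones_like(counts)
    size_factors = np.asarray(size_factors, dtype=float)
    if counts.sum() == 0:
        return 1.0, 0.0
    if counts[poor_mask].sum() == 0 or counts[~poor_mask].sum() == 0:
        counts = counts + 0.5
    q = counts / size_factors
    alpha = _nb_dispersion_mom(q, poor_mask)
    X = sm.add_constant(poor_mask.astype(float))
    try:
        fit = sm.GLM(
            counts,
            X,
            family=sm.families.NegativeBinomial(alpha=alpha),
            offset=np.log(size_factors),
        ).fit()
        beta = float(fit.params[1])
        p = float(fit.pvalues[1])
    except Exception as exc:  # IRLS failure on degenerate genes
        log.warning("NB GLM failed (%s); falling back to moment contrast", exc)
        m_poor = q[poor_mask].mean()
        m_good = q[~poor_mask].mean()
        beta = np.log((m_poor + 0.5) / (m_good + 0.5))
        p = 1.0
    if not np.isfinite(p):
        p = 1.0
    return p, beta / np.log(2.0)


def cna_score(calls: np.ndarray, poor_mask: np.ndarray) -> float:
    """mean(calls in POOR) - mean(calls in GOOD)."""
    calls = np.asarray(calls, dtype=float)
    return float(calls[poor_mask].mean() - calls[~poor_mask].mean())


def standardize_gene(values: np.ndarray, ddof: int = 1) -> np.ndarray:
    """(x - mean) / sd; a constant vector standardizes to all zeros."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=ddof)
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


@dataclass
class GeneStatTable:
    """Per-layered-gene statistics plus the standardization parameters.

    ``table`` is indexed by (layer, gene) with columns p_value, score,
    mean, sd, is_differential. ``z`` holds the standardized values of the
    samples the table was built on.
    """

    table: pd.DataFrame
    z: pd.DataFrame = field(repr=False)
    samples: tuple[str, ...] = ()

    def lookup(self, gene: str, layer: Layer) -> pd.Series | None:
        key = (layer.value, gene)
        if key in self.table.index:
            return self.table.loc[key]
        return None

    def p_value(self, gene: str, layer: Layer, default: float = 1.0) -> float:
        row = self.lookup(gene, layer)
        return float(row["p_value"]) if row is not None else default

    def transform(self, layers: list[OmicsMatrix]) -> pd.DataFrame:
        """Standardize new samples with the stored (training) mean/sd."""
        blocks = []
        for layer_mat in layers:
            layer = layer_mat.graph_layer
            sub = self.table.loc[layer.value]
            genes = [g for g in sub.index if g in layer_mat.values.index]
            vals = layer_mat.values.loc[genes].to_numpy(dtype=float)
            mean = sub.loc[genes, "mean"].to_numpy()[:, None]
            sd = sub.loc[genes, "sd"].to_numpy()[:, None]
            with np.errstate(invalid="ignore", divide="ignore"):
                z = np.where(sd > 0, (vals - mean) / sd, 0.0)
            blocks.append(
                pd.DataFrame(
                    z,
                    index=pd.MultiIndex.from_product([[layer.value], genes]),
                    columns=layer_mat.samples,
                )
            )
        return pd.concat(blocks)


def _ttest_layer(values: np.ndarray, poor_mask: np.ndarray, variant: str):
    poor, good = values[:, poor_mask], values[:, ~poor_mask]
    t, p = scipy.stats.ttest_ind(
        poor, good, axis=1, equal_var=(variant == "student")
    )
    t = np.nan_to_num(t, nan=0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    return p, t


def build_stat_table(
    layers: list[OmicsMatrix],
    labels: SampleLabels,
    variant: str = "welch",
    plug_in: pd.DataFrame | None = None,
) -> GeneStatTable:
    """Run the layer-appropriate test on every gene of every layer.

    Dispatch: MICROARRAY -> t-test, score = sign(t); RNASEQ_COUNTS ->
    NB Wald, score = log2FC; CNA_CALLS -> chi-square, score = poor-good
    mean call difference. z-vectors are computed for all layers, including
    the discrete calls.

    ``plug_in`` (columns gene, layer, p_value, score) bypasses the internal
    tests for the layered genes it covers — the path for users who ran an
    external differential-expression tool; values are range-validated only.
    """
    samples = layers[0].samples
    for m in layers[1:]:
        if m.samples != samples:
            raise ValueError("all layers must share the same sample order")
    poor_mask = labels.poor_mask(samples)
    labels.subset(samples).require_both_classes(min_per_class=2)

    plug: dict[tuple[str, str], tuple[float, float]] = {}
    if plug_in is not None:
        bad = plug_in[(plug_in["p_value"] < 0) | (plug_in["p_value"] > 1)]
        if len(bad):
            raise ValueError("plug-in p-values outside [0, 1]")
        if not np.isfinite(plug_in["score"]).all():
            raise ValueError("plug-in scores must be finite")
        plug = {
            (r.layer, r.gene): (float(r.p_value), float(r.score))
            for r in plug_in.itertuples()
        }

    rows, z_blocks = [], []
    for mat in layers:
        layer = mat.graph_layer
        vals = mat.values.to_numpy(dtype=float)
        kind = mat.layer_kind
        if kind is LayerKind.MICROARRAY:
            p_vec, t_vec = _ttest_layer(vals, poor_mask, variant)
            scores = np.sign(t_vec)
        elif kind is LayerKind.CNA_CALLS:
            p_vec = np.array([chisq_gene(v, poor_mask) for v in vals])
            scores = vals[:, poor_mask].mean(axis=1) - vals[:, ~poor_mask].mean(axis=1)
        elif kind is LayerKind.RNASEQ_COUNTS:
            sf = size_factors(mat.values).to_numpy()
            out = [nb_wald_gene(v, poor_mask, sf) for v in vals]
            p_vec = np.array([p for p, _ in out])
            scores = np.array([lfc for _, lfc in out])
        else:
            raise ValueError(f"unknown layer kind {kind!r}")

        mean = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd[:, None] > 0, (vals - mean[:, None]) / sd[:, None], 0.0)
        for i, gene in enumerate(mat.genes):
            p_i, s_i = plug.get((layer.value, gene), (p_vec[i], scores[i]))
            rows.append((layer.value, gene, float(p_i), float(s_i), mean[i], sd[i]))
        z_blocks.append(
            pd.DataFrame(
                z,
                index=pd.MultiIndex.from_product([[layer.value], mat.genes]),
                columns=samples,
            )
        )

    table = pd.DataFrame(
        rows, columns=["layer", "gene", "p_value", "score", "mean", "sd"]
    ).set_index(["layer", "gene"])
    table["is_differential"] = table["p_value"] < ALPHA
    return GeneStatTable(table=table, z=pd.concat(z_blocks), samples=tuple(samples))
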