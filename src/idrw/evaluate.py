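"""Feature selection, survival-group classification, and cross-validation.

Pathways are ranked by two-sample t-tests of their activity profiles, the
top-k activities feed an (unpenalized) logistic regression, and
performance is measured with accuracy / precision / recall / F1 under
repeated stratified 5-fold CV or leave-one-out CV.

Two protocols are provided. The default is leakage-free: gene statistics,
walk weights, activities and the pathway ranking are all re-estimated on
each training split, and held-out samples are transformed with
training-set parameters only. ``paper_mode=True`` instead computes
statistics and the ranking once on the full cohort and cross-validates
only the classifier — the protocol that matches published practice for
this family of methods, and optimistically biased.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .activity import PathwayActivityMatrix, idrw_activity
from .graph import IntegratedGraph, add_cna_layer, build_expression_layer, row_normalize
from .stats import build_stat_table, standardize_gene
from .types import POOR, LayerKind, OmicsMatrix, PathwayCollection, SampleLabels
from .walk import RESTART_PROB, WALK_TOL, initialize_weights, walk

log = logging.getLogger(__name__)

__all__ = [
    "CVPlan",
    "EvaluationReport",
    "rank_pathways",
    "select_top_k",
    "fit_predict_logistic",
    "metrics",
    "cross_validate",
    "subsample_sensitivity",
    "DEFAULT_K_GRID",
]

DEFAULT_K_GRID = tuple(range(5, 55, 5))


def rank_pathways(
    activity: PathwayActivityMatrix,
    labels: SampleLabels,
    train_samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Rank pathways by the p-value of a two-sample t-test of their
    activities (POOR vs GOOD), computed on training samples only.

    Returns a DataFrame ordered by ascending p-value, ties broken by
    descending |t| and then pathway id, with columns p_value and t.
    Excluded pathways are skipped.
    """
    usable = activity.usable
    samples = list(train_samples) if train_samples is not None else list(usable.columns)
    poor = labels.poor_mask(samples)
    if poor.sum() < 2 or (~poor).sum() < 2:
        raise ValueError("need at least 2 training samples per class to rank")
    vals = usable.loc[:, samples].to_numpy(dtype=float)
    t, p = scipy.stats.ttest_ind(vals[:, poor], vals[:, ~poor], axis=1)
    t = np.nan_to_num(t, nan=0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    out = pd.DataFrame({"p_value": p, "t": t}, index=usable.index)
    out["_neg_abs_t"] = -np.abs(out["t"])
    # pre-sort by pathway id, then stable-sort by (p, -|t|): remaining ties
    # fall back to id order
    out = (
        out.sort_index(kind="mergesort")
        .sort_values(["p_value", "_neg_abs_t"], kind="mergesort")
        .drop(columns="_neg_abs_t")
    )
    return out


def select_top_k(ranked: pd.DataFrame, k: int) -> list[str]:
    """First k pathway ids of a ranking; k is clamped (with a warning) when
    it exceeds the number of available pathways."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(ranked):
        log.warning("k=%d exceeds %d available pathways; clamping", k, len(ranked))
        k = len(ranked)
    return list(ranked.index[:k])


def fit_predict_logistic(
    train_X: np.ndarray,
    train_poor: np.ndarray,
    test_X: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, LogisticRegression]:
    """Maximum-likelihood logistic regression on activity features.

    Features are standardized with training statistics only; prediction
    threshold is probability 0.5 for the POOR class. Falls back to a ridge
    penalty when the unpenalized fit does not converge (perfectly
    separable folds push coefficients to infinity).
    """
    mu = train_X.mean(axis=0)
    sd = train_X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xtr = (train_X - mu) / sd
    Xte = (test_X - mu) / sd

    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("error", ConvergenceWarning)
        try:
            model = LogisticRegression(C=np.inf, max_iter=500)  # unpenalized MLE
            model.fit(Xtr, train_poor)
        except ConvergenceWarning:
            log.debug("unpenalized logistic fit did not converge; ridge fallback")
            model = LogisticRegression(C=1.0, max_iter=1000)
            model.fit(Xtr, train_poor)
    prob = model.predict_proba(Xte)[:, list(model.classes_).index(True)]
    return prob >= 0.5, prob, model


def metrics(
    pred_poor: np.ndarray, true_poor: np.ndarray
) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, F1) with POOR as the positive class.

    Zero-division convention: precision/recall are 0 when their denominator
    is 0, and F1 is 0 when precision + recall is 0.
    """
    pred = np.asarray(pred_poor, dtype=bool)
    true = np.asarray(true_poor, dtype=bool)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth lengths differ")
    if pred.size == 0:
        raise ValueError("empty prediction vector")
    tp = int((pred & true).sum())
    fp = int((pred & ~true).sum())
    fn = int((~pred & true).sum())
    tn = int((~pred & ~true).sum())
    accuracy = (tp + tn) / pred.size
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return accuracy, precision, recall, f1


@dataclass
class CVPlan:
    """Cross-validation layout: repeated stratified k-fold or leave-one-out."""

    scheme: str = "repeated_kfold"  # repeated_kfold | loocv
    n_folds: int = 5
    repeats: int = 50
    seed: int = 0

    def splits(
        self, labels: SampleLabels, samples: Sequence[str]
    ) -> Iterator[tuple[int, int, list[str], list[str]]]:
        """Yield (repeat, fold, train sample ids, test sample ids)."""
        samples = list(samples)
        y = labels.poor_mask(samples)
        if self.scheme == "loocv":
            for i, s in enumerate(samples):
                yield 0, i, [x for x in samples if x != s], [s]
            return
        if self.scheme != "repeated_kfold":
            raise ValueError(f"unknown CV scheme {self.scheme!r}")
        from sklearn.model_selection import StratifiedKFold

        for rep in range(self.repeats):
            skf = StratifiedKFold(
                n_splits=self.n_folds, shuffle=True, random_state=self.seed + rep
            )
            for fold, (tr, te) in enumerate(skf.split(np.zeros(len(samples)), y)):
                yield rep, fold, [samples[i] for i in tr], [samples[i] for i in te]

    @property
    def n_evaluations_per_n(self) -> int | None:
        if self.scheme == "repeated_kfold":
            return self.repeats * self.n_folds
        return None


@dataclass
class EvaluationReport:
    """Per-(method, k, repeat, fold) classification metrics plus aggregates."""

    records: pd.DataFrame
    method: str

    def summary(self) -> pd.DataFrame:
        agg = self.records.groupby("k")[["accuracy", "precision", "recall", "f1"]]
        out = agg.mean()
        out.columns = [f"mean_{c}" for c in out.columns]
        sds = agg.std(ddof=1)
        for c in sds.columns:
            out[f"sd_{c}"] = sds[c]
        return out

    @property
    def optimal_k(self) -> int:
        means = self.records.groupby("k")["accuracy"].mean()
        return int(means.idxmax())

    @property
    def n_evaluations(self) -> int:
        return len(self.records[["repeat", "fold"]].drop_duplicates())


class _ActivityModel:
    """Fit activity inference on training samples; transform held-out ones."""

    def __init__(
        self,
        method: str,
        pathways: PathwayCollection,
        graph: IntegratedGraph | None,
        r: float,
        tol: float,
        variant: str,
    ) -> None:
        self.method = method
        self.pathways = pathways
        self.graph = graph
        self.r = r
        self.tol = tol
        self.variant = variant

    def fit(self, layers: list[OmicsMatrix], labels: SampleLabels) -> PathwayActivityMatrix:
        if self.method == "idrw":
            self.stats_ = build_stat_table(layers, labels, variant=self.variant)
            w0 = initialize_weights(self.stats_, self.graph)
            M = row_normalize(self.graph)
            self.winf_ = walk(M, w0, r=self.r, tol=self.tol)
            act = idrw_activity(self.pathways, self.stats_, self.winf_)
            self.excluded_ = act.excluded
            return act
        expr = layers[0]
        vals = expr.values.to_numpy(dtype=float)
        self.mu_ = vals.mean(axis=1)
        self.sd_ = vals.std(axis=1, ddof=1)
        z = self._z(expr)
        return self._score_z(z, expr.samples, fit=True)

    def transform(self, layers: list[OmicsMatrix]) -> PathwayActivityMatrix:
        if self.method == "idrw":
            z = self.stats_.transform(layers)
            return idrw_activity(self.pathways, self.stats_, self.winf_, z=z)
        expr = layers[0]
        return self._score_z(self._z(expr), expr.samples, fit=False)

    def _z(self, expr: OmicsMatrix) -> pd.DataFrame:
        vals = expr.values.to_numpy(dtype=float)
        sd = np.where(self.sd_ > 0, self.sd_, 1.0)[:, None]
        z = np.where(self.sd_[:, None] > 0, (vals - self.mu_[:, None]) / sd, 0.0)
        return pd.DataFrame(z, index=expr.values.index, columns=expr.samples)

    def _score_z(self, z: pd.DataFrame, samples, fit: bool) -> PathwayActivityMatrix:
        rows, member_rows, excluded = [], [], []
        if fit:
            self.plage_ = {}
        for pid, pw in self.pathways.items():
            genes = [g for g in pw.members if g in z.index]
            if not genes:
                excluded.append(pid)
                rows.append(np.zeros(len(samples)))
                member_rows.append((pid, 0, 0, 0))
                continue
            sub = z.loc[genes].to_numpy(dtype=float)
            if self.method == "zscore":
                rows.append(sub.sum(axis=0) / np.sqrt(len(genes)))
            elif self.method == "plage":
                if fit:
                    u, s, vt = np.linalg.svd(sub, full_matrices=False)
                    v = vt[0]
                    if np.dot(v, sub.mean(axis=0)) < 0:
                        u, s = -u, s
                        v = -v
                    s0 = s[0] if s[0] > 0 else 1.0
                    self.plage_[pid] = (u[:, 0], s0)
                    rows.append(v)
                else:
                    u0, s0 = self.plage_[pid]
                    rows.append(u0 @ sub / s0)
            else:
                raise ValueError(f"unknown activity method {self.method!r}")
            member_rows.append((pid, len(genes), len(genes), 0))
        if fit:
            self.excluded_ = frozenset(excluded)
        values = pd.DataFrame(rows, index=list(self.pathways), columns=list(samples))
        membership = pd.DataFrame(
            member_rows, columns=["pathway", "n_total", "n_exp_sig", "n_cna_sig"]
        ).set_index("pathway")
        return PathwayActivityMatrix(values, membership, self.excluded_)


def _build_graph(
    edges: set[tuple[str, str]], expr: OmicsMatrix, cna: OmicsMatrix | None
) -> IntegratedGraph:
    g = build_expression_layer(edges, expr.genes)
    if cna is not None:
        g = add_cna_layer(g, cna.genes)
    return g


def cross_validate(
    expr: OmicsMatrix,
    labels: SampleLabels,
    pathways: PathwayCollection,
    edges: set[tuple[str, str]] | None = None,
    cna: OmicsMatrix | None = None,
    method: str = "idrw",
    plan: CVPlan | None = None,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    r: float = RESTART_PROB,
    tol: float = WALK_TOL,
    variant: str = "welch",
    paper_mode: bool = False,
) -> EvaluationReport:
    """Run the full pipeline under cross-validation.

    ``method`` is ``idrw`` (needs ``edges``; ``cna`` optional but intended),
    ``plage`` or ``zscore`` (expression only). See the module docstring for
    the default vs ``paper_mode`` protocols.
    """
    plan = plan or CVPlan()
    samples = expr.samples
    layers: list[OmicsMatrix] = [expr] + ([cna] if cna is not None and method == "idrw" else [])
    for m in layers:
        if m.samples != samples:
            raise ValueError("layers must share the same sample order")
    graph = None
    if method == "idrw":
        if edges is None:
            raise ValueError("the walk-based method needs a gene-gene edge set")
        graph = _build_graph(edges, expr, cna)
    model = _ActivityModel(method, pathways, graph, r, tol, variant)

    full_act = full_rank = None
    if paper_mode:
        full_act = model.fit(layers, labels)
        full_rank = rank_pathways(full_act, labels)

    records = []
    for rep, fold, train_s, test_s in plan.splits(labels, samples):
        test_labels = labels.poor_mask(test_s)
        if paper_mode:
            act_train = full_act.usable.loc[:, train_s]
            act_test = full_act.usable.loc[:, test_s]
            ranked = full_rank
        else:
            train_layers = [m.subset_samples(train_s) for m in layers]
            test_layers = [m.subset_samples(test_s) for m in layers]
            train_labels = labels.subset(train_s)
            act = model.fit(train_layers, train_labels)
            act_test_m = model.transform(test_layers)
            ranked = rank_pathways(act, train_labels)
            act_train = act.usable
            act_test = act_test_m.usable
        train_poor = labels.poor_mask(train_s)
        for k in k_grid:
            feats = select_top_k(ranked, k)
            Xtr = act_train.loc[feats, train_s].to_numpy(dtype=float).T
            Xte = act_test.loc[feats, test_s].to_numpy(dtype=float).T
            pred, _, _ = fit_predict_logistic(Xtr, train_poor, Xte)
            acc, prec, rec, f1 = metrics(pred, test_labels)
            records.append((method, k, rep, fold, acc, prec, rec, f1))

    df = pd.DataFrame(
        records,
        columns=["method", "k", "repeat", "fold", "accuracy", "precision", "recall", "f1"],
    )
    return EvaluationReport(df, method)


def _stratified_subsample(
    labels: SampleLabels, samples: Sequence[str], fraction: float, rng: np.random.Generator
) -> list[str]:
    """Draw floor(fraction * n) samples, allocated to classes by largest
    remainder so the total count is exact."""
    samples = list(samples)
    n_total = int(np.floor(fraction * len(samples)))
    poor = labels.poor_mask(samples)
    groups = [
        [s for s, m in zip(samples, poor) if m],
        [s for s, m in zip(samples, poor) if not m],
    ]
    quotas = [fraction * len(g) for g in groups]
    base = [int(np.floor(q)) for q in quotas]
    shortfall = n_total - sum(base)
    order = np.argsort([b - q for b, q in zip(base, quotas)])  # largest remainder first
    for i in order[:shortfall]:
        base[i] += 1
    chosen: list[str] = []
    for g, b in zip(groups, base):
        chosen.extend(rng.choice(g, size=b, replace=False))
    return sorted(chosen)


def subsample_sensitivity(
    expr: OmicsMatrix,
    labels: SampleLabels,
    pathways: PathwayCollection,
    cna: OmicsMatrix | None = None,
    fractions: Sequence[float] = (0.7, 0.8, 0.9, 1.0),
    seed: int = 0,
    min_per_class: int = 10,
    **cv_kwargs,
) -> dict[float, EvaluationReport]:
    """Data-size sensitivity: stratified subsample at each fraction, then
    cross-validate on the reduced cohort."""
    rng = np.random.default_rng(seed)
    out = {}
    for frac in fractions:
        if frac >= 1.0:
            sub_samples = expr.samples
        else:
            sub_samples = _stratified_subsample(labels, expr.samples, frac, rng)
        poor = labels.poor_mask(sub_samples)
        if poor.sum() < min_per_class or (~poor).sum() < min_per_class:
            raise ValueError(
                f"fraction {frac} leaves fewer than {min_per_class} samples in a class"
            )
        out[frac] = cross_validate(
            expr.subset_samples(sub_samples),
            labels.subset(sub_samples),
            pathways,
            cna=cna.subset_samples(sub_samples) if cna is not None else None,
            **cv_kwargs,
        )
    return out
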