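"""Per-sample pathway activity inference.

The walk-based score summarizes each pathway over its *differential*
layered members (test p-value below 0.05): for pathway P_j with members
g_1..g_nj,

    a(P_j)[s] = sum_i Winf(g_i) * score(g_i) * z(g_i)[s]
                / sqrt(sum_i Winf(g_i)^2)

A gene contributes up to two terms — its expression node and its
copy-number node are distinct members. PLAGE (first singular vector of the
standardized member submatrix) and the combined z-score are provided as
single-layer baselines.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import ALPHA, GeneStatTable, standardize_gene
from .types import Layer, OmicsMatrix, PathwayCollection
from .walk import WeightVector

log = logging.getLogger(__name__)

__all__ = [
    "PathwayActivityMatrix",
    "idrw_activity",
    "zscore_activity",
    "plage_activity",
]


@dataclass
class PathwayActivityMatrix:
    """Pathway x sample activities plus per-pathway member bookkeeping.

    ``membership`` has one row per pathway: n_total (members found in the
    data/graph), n_exp_sig and n_cna_sig (differential members per layer —
    the audit columns of a top-pathway table). Pathways in ``excluded``
    had no contributing member; their rows are all-zero and they must not
    reach feature selection.
    """

    values: pd.DataFrame
    membership: pd.DataFrame
    excluded: frozenset[str] = field(default_factory=frozenset)

    @property
    def usable(self) -> pd.DataFrame:
        return self.values.drop(index=list(self.excluded))


def idrw_activity(
    pathways: PathwayCollection,
    stats: GeneStatTable,
    winf: WeightVector,
    z: pd.DataFrame | None = None,
) -> PathwayActivityMatrix:
    """Walk-weighted pathway activities.

    ``z`` defaults to the standardized matrix stored in ``stats`` (the
    samples the statistics were built on); pass ``stats.transform(...)``
    output to score held-out samples with training parameters.
    """
    if z is None:
        z = stats.z
    samples = list(z.columns)
    weight = {node: w for node, w in zip(winf.nodes, winf.values)}

    rows, member_rows, excluded = [], [], []
    for pid, pw in pathways.items():
        contrib_w, contrib_rows = [], []
        n_total = n_exp = n_cna = 0
        for layer in (Layer.EXPR, Layer.CNA):
            for gene in pw.members:
                node = (gene, layer)
                if node not in weight:
                    continue
                n_total += 1
                row = stats.lookup(gene, layer)
                if row is None or row["p_value"] >= ALPHA:
                    continue
                key = (layer.value, gene)
                if key not in z.index:
                    continue
                if layer is Layer.EXPR:
                    n_exp += 1
                else:
                    n_cna += 1
                contrib_w.append(weight[node])
                contrib_rows.append(row["score"] * z.loc[key].to_numpy())
        norm = np.sqrt(np.sum(np.square(contrib_w)))
        if not contrib_w or norm == 0:
            if contrib_w:
                warnings.warn(
                    f"pathway {pid}: all contributing walk weights are zero",
                    stacklevel=2,
                )
            excluded.append(pid)
            rows.append(np.zeros(len(samples)))
        else:
            acc = np.zeros(len(samples))
            for w, term in zip(contrib_w, contrib_rows):
                acc += w * term
            rows.append(acc / norm)
        member_rows.append((pid, n_total, n_exp, n_cna))

    values = pd.DataFrame(rows, index=list(pathways), columns=samples)
    membership = pd.DataFrame(
        member_rows, columns=["pathway", "n_total", "n_exp_sig", "n_cna_sig"]
    ).set_index("pathway")
    return PathwayActivityMatrix(values, membership, frozenset(excluded))


def _member_submatrix(pw, expr: OmicsMatrix) -> pd.DataFrame | None:
    genes = [g for g in pw.members if g in expr.values.index]
    if not genes:
        return None
    return expr.values.loc[genes]


def zscore_activity(
    pathways: PathwayCollection, expr: OmicsMatrix
) -> PathwayActivityMatrix:
    """Combined z-score activity: sum of member z-vectors over sqrt(set size)."""
    rows, member_rows, excluded = [], [], []
    for pid, pw in pathways.items():
        sub = _member_submatrix(pw, expr)
        if sub is None:
            excluded.append(pid)
            rows.append(np.zeros(len(expr.samples)))
            member_rows.append((pid, 0, 0, 0))
            continue
        z = np.vstack([standardize_gene(v) for v in sub.to_numpy(dtype=float)])
        rows.append(z.sum(axis=0) / np.sqrt(len(sub)))
        member_rows.append((pid, len(sub), len(sub), 0))
    values = pd.DataFrame(rows, index=list(pathways), columns=expr.samples)
    membership = pd.DataFrame(
        member_rows, columns=["pathway", "n_total", "n_exp_sig", "n_cna_sig"]
    ).set_index("pathway")
    return PathwayActivityMatrix(values, membership, frozenset(excluded))


def plage_activity(
    pathways: PathwayCollection, expr: OmicsMatrix
) -> PathwayActivityMatrix:
    """PLAGE activity: first right-singular vector of the standardized
    member-gene submatrix, sign-fixed so its correlation with the mean
    member z-profile is nonnegative (the SVD sign is arbitrary).
    """
    rows, member_rows, excluded = [], [], []
    for pid, pw in pathways.items():
        sub = _member_submatrix(pw, expr)
        if sub is None:
            excluded.append(pid)
            rows.append(np.zeros(len(expr.samples)))
            member_rows.append((pid, 0, 0, 0))
            continue
        z = np.vstack([standardize_gene(v) for v in sub.to_numpy(dtype=float)])
        if not z.any():
            excluded.append(pid)
            rows.append(np.zeros(len(expr.samples)))
            member_rows.append((pid, len(sub), 0, 0))
            continue
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        v = vt[0]
        ref = z.mean(axis=0)
        if np.dot(v, ref) < 0:
            v = -v
        rows.append(v)
        member_rows.append((pid, len(sub), len(sub), 0))
    values = pd.DataFrame(rows, index=list(pathways), columns=expr.samples)
    membership = pd.DataFrame(
        member_rows, columns=["pathway", "n_total", "n_exp_sig", "n_cna_sig"]
    ).set_index("pathway")
    return PathwayActivityMatrix(values, membership, frozenset(excluded))
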