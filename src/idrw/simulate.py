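"""Synthetic two-layer cohorts with planted pathway signal.

The generator emulates the structure of a two-class survival cohort
measured on two omics layers: a continuous expression matrix (or,
optionally, negative-binomial RNA-seq counts), a discrete copy-number
call matrix, pathway gene sets, and directed within-pathway gene-gene
edges. Signal is planted in a chosen number of pathways: their member
genes are shifted upward in the poor-survival group by ``delta_expr``
standard deviations (or by fold change ``fold_change`` in count mode),
and their copy-number gain probability is raised by ``delta_cna_gain``.
Everything is seeded and byte-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .types import (
    GOOD,
    POOR,
    LayerKind,
    OmicsMatrix,
    Pathway,
    PathwayCollection,
    SampleLabels,
)

__all__ = ["SimulationConfig", "simulate_cohort", "make_worked_example"]

# baseline call probabilities over {-2,-1,0,1,2}; sparsity resembles
# GISTIC-style call matrices where most genes are neutral in most samples
CNA_BASELINE = (0.02, 0.08, 0.80, 0.08, 0.02)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Defaults describe the reference study condition used throughout the
    test-bench: 50 + 50 samples, 30 disjoint 20-gene pathways, one planted
    pathway with a 2-sd expression shift and a 0.15 copy-number gain-
    probability shift in the poor group.
    """

    n_good: int = 50
    n_poor: int = 50
    n_pathways: int = 30
    pathway_size: int = 20
    n_extra_genes: int = 0          # background genes outside every pathway
    n_planted: int = 1
    delta_expr: float = 2.0         # POOR-group mean shift, in sd units
    delta_cna_gain: float = 0.15    # added P(call = +1) in POOR for planted genes
    fold_change: float = 4.0        # POOR/GOOD mean ratio in count mode
    nb_dispersion: float = 0.1
    edge_density: float = 0.15      # P(directed edge) within a pathway
    cna_overlap: float = 0.8        # fraction of genes also measured on the CNA layer
    expression_kind: LayerKind = LayerKind.MICROARRAY
    cna_baseline: tuple[float, ...] = CNA_BASELINE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > self.n_pathways:
            raise ValueError("cannot plant more pathways than exist")
        for name in ("n_good", "n_poor", "n_pathways", "pathway_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.cna_overlap <= 1 or not 0 <= self.edge_density <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(self.cna_baseline) - 1) > 1e-9:
            raise ValueError("cna_baseline must sum to 1")


@dataclass
class GroundTruth:
    planted_pathways: list[str]
    planted_genes: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [("pathway", p) for p in self.planted_pathways]
            + [("gene", g) for g in self.planted_genes],
            columns=["kind", "id"],
        )


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _shift_cna_probs(base: np.ndarray, delta: float) -> np.ndarray:
    """Move probability mass from the neutral call to +1."""
    probs = base.copy()
    moved = min(delta, probs[2])
    probs[2] -= moved
    probs[3] += moved
    return probs


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[
    OmicsMatrix, OmicsMatrix, SampleLabels, PathwayCollection, set[tuple[str, str]], GroundTruth
]:
    """Draw one cohort: (expression, CNA calls, labels, pathways, edges, truth)."""
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_pathways * config.pathway_size + config.n_extra_genes
    genes = _gene_names(n_genes)
    samples = [f"S{i:04d}" for i in range(config.n_good + config.n_poor)]
    poor = np.array([False] * config.n_good + [True] * config.n_poor)
    labels = SampleLabels(
        pd.Series(np.where(poor, POOR, GOOD), index=samples, name="group")
    )

    pathways = PathwayCollection()
    for j in range(config.n_pathways):
        members = genes[j * config.pathway_size : (j + 1) * config.pathway_size]
        pathways.add(Pathway(f"PW{j:03d}", f"synthetic pathway {j}", tuple(members)))
    planted_ids = list(pathways)[: config.n_planted]
    planted_genes = [g for pid in planted_ids for g in pathways[pid].members]
    planted_mask = np.isin(genes, planted_genes)

    # expression layer
    if config.expression_kind is LayerKind.MICROARRAY:
        vals = rng.standard_normal((n_genes, len(samples)))
        vals[np.ix_(planted_mask, poor)] += config.delta_expr
        expr = OmicsMatrix(
            LayerKind.MICROARRAY, pd.DataFrame(vals, index=genes, columns=samples)
        )
    elif config.expression_kind is LayerKind.RNASEQ_COUNTS:
        base_mean = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=n_genes)
        mu = np.tile(base_mean[:, None], (1, len(samples)))
        mu[np.ix_(planted_mask, poor)] *= config.fold_change
        # NB via gamma-Poisson mixture, dispersion alpha: var = mu + alpha mu^2
        alpha = config.nb_dispersion
        lam = rng.gamma(shape=1 / alpha, scale=mu * alpha)
        counts = rng.poisson(lam)
        expr = OmicsMatrix(
            LayerKind.RNASEQ_COUNTS, pd.DataFrame(counts, index=genes, columns=samples)
        )
    else:
        raise ValueError("expression_kind must be MICROARRAY or RNASEQ_COUNTS")

    # copy-number layer on a subset of genes
    n_cna = int(round(config.cna_overlap * n_genes))
    cna_genes = list(rng.choice(genes, size=n_cna, replace=False))
    cna_genes.sort()
    base = np.asarray(config.cna_baseline)
    shifted = _shift_cna_probs(base, config.delta_cna_gain)
    cats = np.array([-2, -1, 0, 1, 2])
    is_planted_cna = np.isin(cna_genes, planted_genes)
    u = rng.random((n_cna, len(samples)))
    use_shifted = np.outer(is_planted_cna, poor)
    cum = np.where(
        use_shifted[..., None], np.cumsum(shifted)[None, None, :], np.cumsum(base)[None, None, :]
    )
    calls = cats[(u[..., None] > cum).sum(axis=-1)]
    cna = OmicsMatrix(
        LayerKind.CNA_CALLS, pd.DataFrame(calls, index=cna_genes, columns=samples)
    )

    # within-pathway directed edges at the stated density
    edges: set[tuple[str, str]] = set()
    for pid in pathways:
        members = pathways[pid].members
        m = len(members)
        draw = rng.random((m, m)) < config.edge_density
        np.fill_diagonal(draw, False)
        for a in range(m):
            for b in range(m):
                if draw[a, b]:
                    edges.add((members[a], members[b]))

    truth = GroundTruth(planted_ids, planted_genes)
    return expr, cna, labels, pathways, edges, truth


def write_cohort(outdir, expr, cna, labels, pathways, edges, truth) -> dict[str, Path]:
    """Write one simulated cohort to disk in the canonical formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expr": outdir / "expression.tsv",
        "cna": outdir / "cna_calls.tsv",
        "labels": outdir / "labels.tsv",
        "pathways": outdir / "pathways.gmt",
        "edges": outdir / "edges.tsv",
        "truth": outdir / "ground_truth.tsv",
    }
    io.write_omics_matrix(expr, paths["expr"])
    io.write_omics_matrix(cna, paths["cna"])
    io.write_labels(labels, paths["labels"])
    io.write_gmt(pathways, paths["pathways"])
    io.write_edge_list(edges, paths["edges"])
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths


def make_worked_example(outdir=None) -> dict:
    """Tiny deterministic fixtures used throughout the documentation.

    * ``cycle``: the 2-node cycle A->B->A with seed weights (1, 0) — its
      converged walk at r = 0.7 is (0.7/0.91, 0.21/0.91).
    * ``activity``: a 2-member pathway with walk weights (0.3, 0.4),
      scores (+1, -1) and z-vectors (1, -1) — activity (-0.2, 0.2).
    * ``cohort``: a 20-gene, 2 x 6-sample two-layer mini-cohort (4
      pathways of 5 genes, one planted).

    With ``outdir`` set, the cohort is also written in every supported
    on-disk format.
    """
    cycle = {
        "edges": {("A", "B"), ("B", "A")},
        "w0": np.array([1.0, 0.0]),
        "r": 0.7,
        "winf": np.array([0.7 / 0.91, 0.21 / 0.91]),
    }
    act = {
        "winf": np.array([0.3, 0.4]),
        "scores": np.array([1.0, -1.0]),
        "z": np.array([[1.0, -1.0], [1.0, -1.0]]),
        "activity": np.array([-0.2, 0.2]),
    }
    config = SimulationConfig(
        n_good=6,
        n_poor=6,
        n_pathways=4,
        pathway_size=5,
        n_planted=1,
        delta_expr=2.0,
        edge_density=0.4,
        seed=20,
    )
    cohort = simulate_cohort(config)
    out = {"cycle": cycle, "activity": act, "cohort": cohort, "config": config}
    if outdir is not None:
        out["paths"] = write_cohort(outdir, *cohort)
    return out
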