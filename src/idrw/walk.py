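"""Random walk with restart on the integrated graph.

The seed distribution W_0 encodes per-gene differential significance,
W_0 = -log(w_g + eps) rescaled per layer to [0, 1] and L1-normalized; the
walk W_{t+1} = (1 - r) M^T W_t + r W_0 diffuses that significance along
the directed pathway topology until the L1 change drops below ``tol``.
A direct sparse linear solve of the same fixed point is provided as an
independent cross-check.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graph import IntegratedGraph
from .stats import GeneStatTable

log = logging.getLogger(__name__)

__all__ = ["WeightVector", "initialize_weights", "walk", "solve_direct"]

EPS = 2.2e-16        # offset inside the log so p = 0 stays finite
RESTART_PROB = 0.7   # default restart probability r
WALK_TOL = 1e-10     # L1 convergence threshold


@dataclass
class WeightVector:
    """Node weights aligned to an IntegratedGraph's node order."""

    values: np.ndarray
    nodes: tuple
    role: str  # W0 | Wt | Winf
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.nodes):
            raise ValueError("weight vector length does not match node count")

    def as_series(self):
        import pandas as pd

        idx = pd.MultiIndex.from_tuples(
            [(layer.value, gene) for gene, layer in self.nodes]
        )
        return pd.Series(self.values, index=idx, name=self.role)


def initialize_weights(
    stats: GeneStatTable, graph: IntegratedGraph, eps: float = EPS
) -> WeightVector:
    """Seed distribution W_0 from per-gene p-values.

    raw_i = -log(w_g + eps); within each layer the raw values are min-max
    rescaled to [0, 1] (a layer with constant raw values gets uniform 0.5);
    the concatenated vector is then L1-normalized to sum 1. Nodes absent
    from the statistics table get w_g = 1 (no evidence).
    """
    p = np.array([stats.p_value(gene, layer) for gene, layer in graph.nodes])
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    raw = -np.log(p + eps)
    scaled = np.empty_like(raw)
    for layer, ix in graph.layer_slices().items():
        lo, hi = raw[ix].min(), raw[ix].max()
        if hi > lo:
            scaled[ix] = (raw[ix] - lo) / (hi - lo)
        else:
            scaled[ix] = 0.5
    total = scaled.sum()
    if total == 0:  # every layer constant at its minimum cannot happen (0.5 fill)
        scaled[:] = 1.0
        total = scaled.sum()
    return WeightVector(scaled / total, graph.nodes, role="W0")


def walk(
    M: sp.spmatrix,
    w0: WeightVector,
    r: float = RESTART_PROB,
    tol: float = WALK_TOL,
    max_iter: int = 10_000,
) -> WeightVector:
    """Iterate W_{t+1} = (1 - r) M^T W_t + r W_0 from W_0 to its fixed point.

    Convergence when the L1 norm of the update falls below ``tol``. Raises
    if ``max_iter`` is hit (reporting the residual); with 0 < r <= 1 and a
    substochastic M the iteration contracts geometrically, so the guard is
    a safety net only.
    """
    if not (0 < r <= 1):
        raise ValueError("restart probability must be in (0, 1]")
    MT = M.T.tocsr()
    w = w0.values.copy()
    for it in range(1, max_iter + 1):
        w_next = (1 - r) * (MT @ w) + r * w0.values
        delta = np.abs(w_next - w).sum()
        w = w_next
        if delta < tol:
            log.debug("walk converged in %d iterations (delta=%.3e)", it, delta)
            return WeightVector(w, w0.nodes, role="Winf", n_iter=it)
    raise RuntimeError(
        f"walk did not converge in {max_iter} iterations (residual {delta:.3e})"
    )


def solve_direct(M: sp.spmatrix, w0: WeightVector, r: float = RESTART_PROB) -> WeightVector:
    """Closed-form fixed point: solve (I - (1 - r) M^T) W = r W_0.

    For r > 0 and row-substochastic M the system matrix is nonsingular
    (spectral radius of (1 - r) M^T is below 1).
    """
    if not (0 < r <= 1):
        raise ValueError("restart probability must be in (0, 1]")
    n = len(w0.values)
    A = sp.eye(n, format="csc") - (1 - r) * M.T.tocsc()
    w = spla.spsolve(A, r * w0.values)
    return WeightVector(w, w0.nodes, role="Winf", n_iter=0)
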