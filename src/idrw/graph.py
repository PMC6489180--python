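"""Construction of the integrated two-layer directed gene-gene graph.

The expression layer carries the pathway-derived directed edges restricted
to genes actually measured. The copy-number layer is wired strictly
downstream of nothing: each CNA node has exactly one out-edge to the
expression node of the same gene and never receives an edge, so
copy-number state can influence expression weights through the walk but
not vice versa.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp

from .types import Layer

log = logging.getLogger(__name__)

__all__ = ["IntegratedGraph", "build_expression_layer", "add_cna_layer", "row_normalize"]

Node = tuple[str, Layer]


@dataclass
class IntegratedGraph:
    """Directed graph over (gene, layer) nodes.

    Node order is deterministic — sorted by (layer value, gene) — so that
    transition matrices and weight vectors are reproducible across runs.
    """

    nodes: tuple[Node, ...]
    edges: frozenset[tuple[int, int]]
    node_index: dict[Node, int] = field(repr=False)

    @classmethod
    def from_nodes_edges(
        cls, nodes: Iterable[Node], edges: Iterable[tuple[Node, Node]]
    ) -> "IntegratedGraph":
        ordered = tuple(sorted(set(nodes), key=lambda n: (n[1].value, n[0])))
        index = {n: i for i, n in enumerate(ordered)}
        idx_edges = frozenset((index[u], index[v]) for u, v in edges)
        return cls(ordered, idx_edges, index)

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def layer_slices(self) -> dict[Layer, np.ndarray]:
        """Index arrays of the nodes belonging to each layer."""
        out: dict[Layer, list[int]] = {}
        for i, (_, layer) in enumerate(self.nodes):
            out.setdefault(layer, []).append(i)
        return {layer: np.asarray(ix) for layer, ix in out.items()}

    def adjacency(self) -> sp.csr_matrix:
        n = len(self.nodes)
        if not self.edges:
            return sp.csr_matrix((n, n))
        rows, cols = zip(*self.edges)
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(n, n))

    def in_degree(self, node: Node) -> int:
        j = self.node_index[node]
        return sum(1 for _, t in self.edges if t == j)

    def out_degree(self, node: Node) -> int:
        i = self.node_index[node]
        return sum(1 for s, _ in self.edges if s == i)


def build_expression_layer(
    edges: Iterable[tuple[str, str]], expr_genes: Iterable[str]
) -> IntegratedGraph:
    """Build the expression layer: nodes are genes appearing in the pathway
    edge set AND measured in the expression data; edges are the input edges
    restricted to those nodes.
    """
    expr_genes = set(expr_genes)
    edges = list(edges)
    kept_edges = [(u, v) for u, v in edges if u in expr_genes and v in expr_genes]
    # genes named in edges but unmeasured are dropped; a measured endpoint is
    # kept even when its partner was dropped
    edge_genes = {g for e in edges for g in e}
    graph_genes = edge_genes & expr_genes
    if not graph_genes:
        raise ValueError("no overlap between edge-set genes and expression genes")
    nodes = [(g, Layer.EXPR) for g in graph_genes]
    node_edges = [((u, Layer.EXPR), (v, Layer.EXPR)) for u, v in kept_edges]
    return IntegratedGraph.from_nodes_edges(nodes, node_edges)


def add_cna_layer(graph: IntegratedGraph, cna_genes: Iterable[str]) -> IntegratedGraph:
    """Add the copy-number layer: one node (g, CNA) and one directed edge
    (g, CNA) -> (g, EXPR) for every gene measured in the CNA data whose
    expression node exists. CNA genes without an expression counterpart are
    silently omitted (counted in the log). Idempotent.
    """
    cna_genes = set(cna_genes)
    expr_present = {g for g, layer in graph.nodes if layer is Layer.EXPR}
    overlap = cna_genes & expr_present
    omitted = len(cna_genes) - len(overlap)
    if omitted:
        log.info("omitting %d CNA genes with no expression node", omitted)
    nodes = list(graph.nodes) + [(g, Layer.CNA) for g in overlap]
    rev = {i: n for n, i in graph.node_index.items()}
    edges = [(rev[i], rev[j]) for i, j in graph.edges]
    edges += [((g, Layer.CNA), (g, Layer.EXPR)) for g in overlap]
    return IntegratedGraph.from_nodes_edges(nodes, edges)


def row_normalize(graph: IntegratedGraph) -> sp.csr_matrix:
    """Row-normalized adjacency (transition) matrix M.

    M[i, j] = 1/outdeg(i) if the edge i->j exists, else 0. Rows of dangling
    nodes are left all-zero; the restart term of the walk keeps the
    iteration well-posed.
    """
    if len(graph) == 0:
        raise ValueError("empty graph")
    adj = graph.adjacency().astype(float)
    outdeg = np.asarray(adj.sum(axis=1)).ravel()
    inv = np.divide(1.0, outdeg, out=np.zeros_like(outdeg), where=outdeg > 0)
    return sp.diags(inv) @ adj
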