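"""Readers and writers for the on-disk formats.

Canonical matrix format is TSV with a header row of sample ids and gene
symbols in the first column; gzip-compressed files are accepted
transparently (pandas infers from the ``.gz`` suffix). Gene sets use GMT,
pathway topology comes from either a plain directed edge-list TSV or KEGG
KGML XML, and network exports are GraphML plus an edge-list TSV.
"""
from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from lxml import etree

from .types import (
    GOOD,
    POOR,
    Layer,
    LayerKind,
    OmicsMatrix,
    Pathway,
    PathwayCollection,
    SampleLabels,
)

log = logging.getLogger(__name__)

__all__ = [
    "read_omics_matrix",
    "write_omics_matrix",
    "read_labels",
    "write_labels",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "parse_kgml",
    "read_id_mapping",
    "read_activity_matrix",
    "write_activity_matrix",
    "export_subnetwork",
]


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    return df


def read_omics_matrix(path, layer_kind: LayerKind) -> OmicsMatrix:
    """Read a gene x sample TSV and apply the standard cleaning steps.

    Duplicate gene rows are collapsed by their median. For discrete-call
    and count layers, genes missing in more than half of the samples are
    dropped; remaining missing cells are imputed with the median of the
    corresponding sample (column). Copy-number calls are validated to lie
    in {-2,-1,0,1,2}.
    """
    layer_kind = LayerKind(layer_kind)
    try:
        df = _read_table(path)
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc

    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        log.info("collapsing %d duplicate gene rows by median in %s", n_dup, path)
        df = df.groupby(level=0, sort=False).median()

    if layer_kind in (LayerKind.RNASEQ_COUNTS, LayerKind.CNA_CALLS) and df.shape[1]:
        frac_missing = df.isna().mean(axis=1)
        dropped = df.index[frac_missing > 0.5]
        if len(dropped):
            log.info("dropping %d genes with >50%% missing values", len(dropped))
            df = df.drop(index=dropped)

    if df.isna().any().any():
        medians = df.median(axis=0, skipna=True)
        if layer_kind is LayerKind.CNA_CALLS:
            medians = np.rint(medians)
        df = df.fillna(medians)

    if layer_kind is LayerKind.CNA_CALLS:
        vals = df.to_numpy()
        bad = ~np.isin(vals, [-2, -1, 0, 1, 2])
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise ValueError(
                f"CNA call {vals[g, s]!r} outside {{-2..2}} at gene "
                f"{df.index[g]!r}, sample {df.columns[s]!r}"
            )
        df = df.astype(int)
    if layer_kind is LayerKind.RNASEQ_COUNTS and (df.to_numpy() < 0).any():
        raise ValueError("negative value in RNA-seq count matrix")
    return OmicsMatrix(layer_kind, df)


def write_omics_matrix(matrix: OmicsMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_labels(path) -> SampleLabels:
    """Read a two-column TSV (sample id, GOOD/POOR)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] != 1:
        raise ValueError(f"labels file must have exactly 2 columns, got {df.shape[1] + 1}")
    return SampleLabels(df.iloc[:, 0].astype(str).rename("group"))


def write_labels(labels: SampleLabels, path) -> None:
    labels.labels.rename("group").to_csv(path, sep="\t", index_label="sample")


def read_gmt(path) -> PathwayCollection:
    """Read a GMT file: name TAB description TAB member1 TAB member2 ..."""
    collection = PathwayCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            pid, name, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: pathway {pid!r} has no members")
            collection.add(Pathway(pid, name, tuple(members)))
    return collection


def write_gmt(collection: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for pw in collection.values():
            fh.write("\t".join([pw.id, pw.name, *pw.members]) + "\n")


def read_edge_list(path) -> set[tuple[str, str]]:
    """Read a directed edge list TSV with columns (source, target[, pathway_id]).

    Edges are de-duplicated; self-loops are preserved; direction matters.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "source" not in cols or "target" not in cols:
        raise ValueError(f"{path}: edge list needs 'source' and 'target' columns")
    df.columns = cols
    return set(zip(df["source"], df["target"]))


def write_edge_list(edges: Iterable[tuple[str, str]], path) -> None:
    df = pd.DataFrame(sorted(edges), columns=["source", "target"])
    df.to_csv(path, sep="\t", index=False)


def read_id_mapping(path) -> dict[str, str]:
    """Two-column TSV mapping KEGG gene ids (e.g. ``hsa:2475``) to symbols."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: id mapping needs 2 columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def _kgml_entry_genes(entry, id_map: dict[str, str]) -> list[str]:
    names = entry.get("name", "").split()
    return [id_map[n] for n in names if n in id_map]


def parse_kgml(
    paths: Sequence, id_map: dict[str, str]
) -> tuple[PathwayCollection, set[tuple[str, str]]]:
    """Parse KGML pathway XML files into a pathway collection and a directed
    gene-gene edge set.

    Entries of type ``gene`` contribute nodes (KEGG ids mapped to symbols via
    ``id_map``; unmapped ids are skipped). ``group`` entries expand to their
    component genes. Each relation between two entries expands to the full
    cross product of the source and target gene lists. Relations that
    reference unknown entries produce a warning and are skipped. Compound
    and map entries contribute nothing.
    """
    collection = PathwayCollection()
    edges: set[tuple[str, str]] = set()
    for path in paths:
        try:
            tree = etree.parse(str(path))
        except etree.XMLSyntaxError as exc:
            raise ValueError(f"malformed KGML in {path}: {exc}") from exc
        root = tree.getroot()
        entry_genes: dict[str, list[str]] = {}
        entries = {e.get("id"): e for e in root.findall("entry")}
        for eid, entry in entries.items():
            etype = entry.get("type")
            if etype == "gene":
                entry_genes[eid] = _kgml_entry_genes(entry, id_map)
        for eid, entry in entries.items():
            if entry.get("type") == "group":
                genes: list[str] = []
                for comp in entry.findall("component"):
                    genes.extend(entry_genes.get(comp.get("id"), []))
                entry_genes[eid] = genes

        for rel in root.findall("relation"):
            e1, e2 = rel.get("entry1"), rel.get("entry2")
            if e1 not in entries or e2 not in entries:
                warnings.warn(
                    f"{path}: relation references unknown entry {e1!r} or {e2!r}; skipped",
                    stacklevel=2,
                )
                continue
            for src in entry_genes.get(e1, []):
                for dst in entry_genes.get(e2, []):
                    edges.add((src, dst))

        pid = root.get("name", str(path)).replace("path:", "")
        title = root.get("title", pid)
        members = sorted({g for genes in entry_genes.values() for g in genes})
        if members:
            collection.add(Pathway(pid, title, tuple(members)))
    return collection, edges


def read_activity_matrix(path) -> pd.DataFrame:
    return _read_table(path)


def write_activity_matrix(activity: pd.DataFrame, path) -> None:
    activity.to_csv(path, sep="\t", index_label="pathway")


def export_subnetwork(
    graph,
    pathways: PathwayCollection,
    selected: Sequence[str],
    stats,
    degree_cut: int = 3,
    graphml_path=None,
    edgelist_path=None,
) -> nx.DiGraph:
    """Export the induced subnetwork of significant genes in selected pathways.

    Nodes are the layered genes of the selected pathways whose test p-value
    is below 0.05 ("significant"), with a ``layer`` attribute; a node is
    flagged as a hub when its total degree within the induced subgraph is at
    least ``degree_cut``. Returns the subgraph; optionally writes GraphML
    and an edge-list TSV.
    """
    unknown = [p for p in selected if p not in pathways]
    if unknown:
        raise KeyError(f"unknown pathway ids: {unknown}")
    member_genes = {g for pid in selected for g in pathways[pid].members}
    keep = []
    for node in graph.nodes:
        gene, layer = node
        if gene not in member_genes:
            continue
        row = stats.lookup(gene, layer)
        if row is not None and row["p_value"] < 0.05:
            keep.append(node)
    keep_set = set(keep)

    sub = nx.DiGraph()
    for gene, layer in keep:
        sub.add_node(f"{gene}|{layer.value}", gene=gene, layer=layer.value)
    for i, j in graph.edges:
        u, v = graph.nodes[i], graph.nodes[j]
        if u in keep_set and v in keep_set:
            sub.add_edge(f"{u[0]}|{u[1].value}", f"{v[0]}|{v[1].value}")
    degrees = dict(sub.degree())
    nx.set_node_attributes(
        sub, {n: bool(d >= degree_cut) for n, d in degrees.items()}, "hub"
    )
    if graphml_path is not None:
        nx.write_graphml(sub, graphml_path)
    if edgelist_path is not None:
        write_edge_list(set(sub.edges()), edgelist_path)
    return sub
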