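"""Readers and writers for the on-disk artifacts.

Tabular files are TSV (tab-separated, header row, UTF-8, "." decimal).
Gene identifiers are opaque case-sensitive strings; no symbol mapping is
attempted.  Networks round-trip losslessly through the TSV edge-list
format; SIF export (relation token ``pp``) drops weights — a limitation
of the format — while GraphML keeps them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

VALID_UNITS = ("counts", "cpm", "log2cpm")


@dataclass
class ExpressionMatrix:
    """A genes x samples expression table with a unit tag."""

    data: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self):
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        if self.unit in ("counts", "cpm") and (self.data.to_numpy() < 0).any():
            raise ValueError(f"negative values are invalid under unit {self.unit!r}")

    @property
    def genes(self) -> list:
        return list(self.data.index)

    @property
    def samples(self) -> list:
        return list(self.data.columns)


def read_expression_matrix(path, unit: str = "counts") -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float), unit)


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene")


def validate_network(net: nx.Graph) -> nx.Graph:
    """Check the gene-network invariants: no self-loops, weights in [0, 1]."""
    for u, v, data in net.edges(data=True):
        if u == v:
            raise ValueError(f"self-loop on {u!r}")
        w = data.get("weight", 1.0)
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"edge ({u!r}, {v!r}) weight {w} outside [0, 1]")
    return net


def read_edge_list(path, weighted: bool = True) -> nx.Graph:
    """Read a TSV edge list ``geneA<TAB>geneB[<TAB>weight]``.

    Symmetric duplicates collapse to one undirected edge; unweighted
    input receives weight 1.0.  A later duplicate of an edge overwrites
    its weight (last one wins).
    """
    net = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 tab-separated fields")
            u, v = parts[0], parts[1]
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop on {u!r}")
            if weighted and len(parts) >= 3:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
                if not 0.0 <= w <= 1.0:
                    raise ValueError(f"{path}:{lineno}: weight {w} outside [0, 1]")
            else:
                w = 1.0
            net.add_edge(u, v, weight=w)
    return net


def write_network(net: nx.Graph, path, format: str = "tsv") -> None:
    """Write a network as ``tsv`` (lossless), ``sif`` or ``graphml``."""
    if net.number_of_edges() == 0:
        raise ValueError("refusing to write an empty network")
    validate_network(net)
    edges = sorted((sorted((str(u), str(v))) + [d.get("weight", 1.0)])
                   for u, v, d in net.edges(data=True))
    if format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v, w in edges:
                fh.write(f"{u}\t{v}\t{w!r}\n")
    elif format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v, _ in edges:
                fh.write(f"{u} pp {v}\n")
    elif format == "graphml":
        nx.write_graphml(net, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def write_kds_report(kds, scores: pd.DataFrame, path, params: dict | None = None) -> None:
    """Write the JSON report for an extracted KDS.

    ``kds`` is a :class:`ckds.kds.KDSResult`; ``scores`` the centrality
    table covering exactly the KDS nodes (``score_t`` computed).
    """
    missing = kds.nodes - set(scores.index)
    if missing:
        raise ValueError(f"scores table is missing nodes: {sorted(missing)}")
    extra = set(scores.index) - kds.nodes
    if extra:
        raise ValueError(f"scores table has unknown nodes: {sorted(extra)}")
    nodes = []
    for g in sorted(kds.nodes, key=str):
        rec = {"gene": str(g), "d_value": kds.d_values.get(g, 0.0)}
        for col in scores.columns:
            val = scores.at[g, col]
            rec[col] = bool(val) if col == "top_flag" else float(val)
        nodes.append(rec)
    report = {
        "nodes": nodes,
        "edges": [
            {"source": str(u), "target": str(v), "weight": float(d.get("weight", 1.0))}
            for u, v, d in sorted(kds.graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
        ],
        "connected": kds.connected,
        "n_components": kds.n_components,
        "params": params or {},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)


def read_gene_list(path) -> list:
    """One gene id per line; blank lines ignored."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")
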