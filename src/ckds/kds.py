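"""Greedy extraction of the kernel differential subgraph (KDS).

The KDS is a small connected subgraph concentrating the genes whose local
topology differs most between two states.  Exact extraction is a
Steiner-tree-type problem (NP-hard); the criterion here grows each
per-network subgraph greedily:

1. seed with the highest-d selected differential gene present in the
   network;
2. visit the remaining selected genes in descending d order: a gene
   adjacent to the current subgraph is absorbed together with its edges
   to it; otherwise every minimum-hop path from the gene to a current
   subgraph node is scored with

       Score_path = a * sum(d_v over path nodes) + b * sum(W_e over path edges)

   and the highest-scoring path (nodes and edges) is added whole;
3. the two per-network subgraphs are intersected: nodes by set
   intersection, edges as the union of both edge sets restricted to the
   intersected nodes (weight = max of the two sources).

With the default a = b = 1 the path score is simply sum(d) + sum(W).
Unreachable selected genes are skipped with a warning.  All ties are
broken deterministically: higher score, then shorter path, then
lexicographically smallest node sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx


@dataclass
class KDSParams:
    """Extraction parameters: path-score coefficients and selection cut."""

    a: float = 1.0
    b: float = 1.0
    d_threshold: float = 0.4

    def __post_init__(self):
        if self.a < 0 or self.b < 0:
            raise ValueError("a and b must be non-negative")
        if self.a + self.b <= 0:
            raise ValueError("a + b must be positive")


@dataclass
class KDSResult:
    """An extracted kernel differential subgraph with provenance."""

    graph: nx.Graph
    d_values: dict
    growth_log: list = field(default_factory=list)

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def connected(self) -> bool:
        if self.graph.number_of_nodes() == 0:
            return False
        return nx.is_connected(self.graph)

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.graph)


def score_path(d_values_on_path, edge_weights_on_path, params: KDSParams) -> float:
    """a * sum(d) + b * sum(W) for one candidate path."""
    d_values_on_path = list(d_values_on_path)
    edge_weights_on_path = list(edge_weights_on_path)
    if not edge_weights_on_path:
        raise ValueError("a path must contain at least one edge")
    return params.a * sum(d_values_on_path) + params.b * sum(edge_weights_on_path)


def _selected_in_net(diff, net):
    sel = diff.index[diff["selected"]]
    present = [g for g in sel if g in net]
    # diff is sorted descending by d already; keep that order
    return present


def _candidate_paths(net: nx.Graph, source, targets):
    """All minimum-hop paths from source to each target, as node lists."""
    lengths = nx.single_source_shortest_path_length(net, source)
    paths = []
    for t in targets:
        if t not in lengths:
            continue
        for p in nx.all_shortest_paths(net, source, t):
            paths.append(p)
    return paths


def extract_kds_single(net: nx.Graph, diff, params: KDSParams) -> KDSResult:
    """Grow one per-network KDS by the greedy path criterion.

    ``diff`` is the differential-node table from
    :func:`ckds.signature.differential_nodes` (sorted descending by
    d-value).  Raises ``ValueError`` if no selected gene occurs in the
    network.  The result is connected by construction.
    """
    d_of = diff["d_value"].to_dict()
    order = _selected_in_net(diff, net)
    if not order:
        raise ValueError("no selected differential node occurs in the network")

    kds = nx.Graph()
    log = []
    seed = order[0]
    kds.add_node(seed)
    log.append({"kind": "seed", "node": seed, "d_value": d_of[seed]})

    for gene in order[1:]:
        if gene in kds:
            log.append({"kind": "already_present", "node": gene})
            continue
        touching = [u for u in net[gene] if u in kds]
        if touching:
            kds.add_node(gene)
            for u in touching:
                kds.add_edge(gene, u, weight=net[gene][u].get("weight", 1.0))
            log.append({"kind": "direct", "node": gene, "edges_added": sorted(touching)})
            continue
        candidates = _candidate_paths(net, gene, list(kds.nodes))
        if not candidates:
            warnings.warn(f"selected gene {gene!r} unreachable from the KDS; skipped")
            log.append({"kind": "unreachable", "node": gene})
            continue
        best = None
        for p in candidates:
            s = score_path(
                (d_of.get(v, 0.0) for v in p),
                (net[u][v].get("weight", 1.0) for u, v in zip(p, p[1:])),
                params,
            )
            key = (-s, len(p), tuple(str(v) for v in p))
            if best is None or key < best[0]:
                best = (key, p, s)
        _, path, s = best
        for u, v in zip(path, path[1:]):
            kds.add_edge(u, v, weight=net[u][v].get("weight", 1.0))
        log.append({"kind": "path", "node": gene, "path": list(path), "score": s})
        assert nx.is_connected(kds)

    return KDSResult(graph=kds, d_values={g: d_of.get(g, 0.0) for g in kds.nodes}, growth_log=log)


def intersect_kds(kds1: KDSResult, kds2: KDSResult) -> KDSResult:
    """Intersect two per-network KDSs.

    Nodes: set intersection.  Edges: union of both edge sets restricted
    to the intersected nodes, with weight = max of the two sources when
    both define the edge.  The result may be disconnected.
    """
    common = kds1.nodes & kds2.nodes
    if not common:
        raise ValueError("per-network KDSs share no nodes")
    out = nx.Graph()
    out.add_nodes_from(common)
    for g in (kds1.graph, kds2.graph):
        for u, v, data in g.edges(data=True):
            if u in common and v in common:
                w = data.get("weight", 1.0)
                if out.has_edge(u, v):
                    out[u][v]["weight"] = max(out[u][v]["weight"], w)
                else:
                    out.add_edge(u, v, weight=w)
    d_values = {g: kds1.d_values.get(g, kds2.d_values.get(g, 0.0)) for g in common}
    return KDSResult(graph=out, d_values=d_values, growth_log=[])


def extract_kds(net_a: nx.Graph, net_b: nx.Graph, diff, params: KDSParams | None = None) -> KDSResult:
    """Full extraction: per-network growth on both states, then intersection.

    The growth logs of both per-network runs are retained in the
    result's ``growth_log`` as two tagged sections.
    """
    params = params or KDSParams()
    kds1 = extract_kds_single(net_a, diff, params)
    kds2 = extract_kds_single(net_b, diff, params)
    result = intersect_kds(kds1, kds2)
    result.growth_log = [
        {"network": "A", "log": kds1.growth_log},
        {"network": "B", "log": kds2.growth_log},
    ]
    return result
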