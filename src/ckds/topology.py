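"""Centrality scoring of an extracted subgraph.

Four indexes are combined: degree centrality DC(v) = |N_v| (local), and
three global measures — betweenness BC(v) = sum over pairs s!=v!=t of
sigma_st(v)/sigma_st, closeness CC(v) = (n-1)/sum_t dist(v,t), and
eigenvector centrality EC(v), the v-entry of the principal eigenvector of
the adjacency matrix.  Each raw column is min-max normalised to [0, 1]
and summed into

    Score_T(v) = DC'(v) + BC'(v) + CC'(v) + EC'(v)

and the top 10% of nodes by Score_T are flagged as the genes with the
largest topological role.  Because an intersected KDS may be
disconnected, CC and EC are computed per connected component (closeness
with the component's size, EC from the component's adjacency block,
scaled to unit maximum).  Distances are hop counts; edge weights are
ignored throughout.
"""

from __future__ import annotations

import math
import warnings

import networkx as nx
import numpy as np
import pandas as pd

_RAW = ["dc", "bc", "cc", "ec"]


def compute_centralities(net: nx.Graph) -> pd.DataFrame:
    """Raw DC/BC/CC/EC per node (index = node id, sorted)."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    if net.number_of_nodes() < 2:
        raise ValueError("centralities need at least 2 nodes")
    nodes = sorted(net.nodes)
    dc = {v: net.degree(v) for v in nodes}
    bc = nx.betweenness_centrality(net, normalized=False, weight=None)
    cc = nx.closeness_centrality(net, wf_improved=False)
    ec = {}
    for comp in nx.connected_components(net):
        comp = sorted(comp)
        if len(comp) == 1:
            ec[comp[0]] = 1.0
            continue
        a = nx.to_numpy_array(net.subgraph(comp), nodelist=comp, weight=None)
        vals, vecs = np.linalg.eigh(a)
        v = np.abs(vecs[:, -1])
        v = v / v.max()
        for node, x in zip(comp, v):
            ec[node] = float(x)
    return pd.DataFrame(
        {
            "dc": [float(dc[v]) for v in nodes],
            "bc": [float(bc[v]) for v in nodes],
            "cc": [float(cc[v]) for v in nodes],
            "ec": [float(ec[v]) for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


def combined_score(table: pd.DataFrame) -> pd.DataFrame:
    """Min-max normalise each raw column and sum into ``score_t``.

    A constant column carries no ranking information; it is mapped to
    0.5 everywhere (logged) so the combined score stays well defined.
    """
    out = table.copy()
    for col in _RAW:
        lo, hi = out[col].min(), out[col].max()
        if math.isclose(lo, hi):
            warnings.warn(f"centrality column {col!r} is constant; normalised to 0.5")
            out[f"{col}_n"] = 0.5
        else:
            out[f"{col}_n"] = (out[col] - lo) / (hi - lo)
    out["score_t"] = out[[f"{c}_n" for c in _RAW]].sum(axis=1)
    return out


def top_nodes(table: pd.DataFrame, fraction: float = 0.10) -> list:
    """The ceil(fraction * n) highest-``score_t`` genes.

    Ties at the boundary are broken by gene name; the returned genes are
    also flagged in the table's ``top_flag`` column (in place).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if "score_t" not in table:
        raise ValueError("run combined_score first")
    k = math.ceil(fraction * len(table))
    ranked = sorted(table.index, key=lambda g: (-table.at[g, "score_t"], str(g)))
    top = ranked[:k]
    table["top_flag"] = table.index.isin(top)
    return top
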