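"""Graphlet-orbit counting for 2--4-node graphlets.

Graphlets are the nine small connected non-isomorphic induced subgraphs on
2--4 nodes (G0, the edge, through G8, the 4-clique).  Their automorphism
groups partition node positions into 15 orbits:

====  ===========  =================================
G0    edge         orbit 0
G1    path-3       orbit 1 (end), orbit 2 (middle)
G2    triangle     orbit 3
G3    path-4       orbit 4 (end), orbit 5 (middle)
G4    star-4       orbit 6 (leaf), orbit 7 (center)
G5    cycle-4      orbit 8
G6    paw          orbit 9 (pendant), orbit 10 (triangle, deg 2),
                   orbit 11 (triangle, deg 3)
G7    diamond      orbit 12 (deg 2), orbit 13 (deg 3)
G8    4-clique     orbit 14
====  ===========  =================================

A node's *graphlet degree signature* is the 15-vector whose i-th entry is
the number of induced occurrences of orbit i touching the node.  Counting
is exact: every connected induced 2-, 3- and 4-node subgraph is enumerated
once (ESU-style enumeration) and classified by its degree sequence, which
uniquely identifies both the graphlet and each node's orbit at this size.
Edge weights are ignored; the signature is purely topological.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd

N_ORBITS = 15

#: orbit of a node inside a connected induced subgraph on 3 or 4 nodes,
#: keyed by (#nodes, #edges, max degree, node's own degree inside the
#: subgraph).  At sizes 3-4 this invariant separates every orbit.
_ORBIT_KEY = {
    # size 3: path (2 edges) or triangle (3 edges)
    (3, 2, 2, 1): 1,
    (3, 2, 2, 2): 2,
    (3, 3, 2, 2): 3,
    # size 4, 3 edges: path-4 or star-4
    (4, 3, 2, 1): 4,
    (4, 3, 2, 2): 5,
    (4, 3, 3, 1): 6,
    (4, 3, 3, 3): 7,
    # size 4, 4 edges: cycle or paw
    (4, 4, 2, 2): 8,
    (4, 4, 3, 1): 9,
    (4, 4, 3, 2): 10,
    (4, 4, 3, 3): 11,
    # size 4, 5 edges: diamond
    (4, 5, 3, 2): 12,
    (4, 5, 3, 3): 13,
    # size 4, 6 edges: clique
    (4, 6, 3, 3): 14,
}

#: number of orbits whose counts affect each orbit's count (itself
#: included): the distinct orbits obtainable as connected induced
#: sub-positions of the orbit's graphlet at its representative node.
#: Re-derived from the canonical graphlets in the test suite.
ORBIT_DEPENDENCY_COUNTS = np.array(
    [1, 2, 2, 2, 3, 4, 3, 3, 4, 3, 4, 4, 4, 4, 3], dtype=int
)


def orbit_dependency_weights(override: np.ndarray | None = None) -> np.ndarray:
    """Orbit weights ``w_i = 1 - log(o_i)/log(15)`` in (0, 1].

    ``o_i`` counts the orbits (including orbit *i* itself) whose
    occurrence influences orbit *i*'s count, so heavily redundant orbits
    are down-weighted in the signature distance.  Orbit 0 (plain degree)
    depends only on itself, hence ``w_0 = 1``.

    Parameters
    ----------
    override : array-like of length 15, optional
        Replacement weight vector (e.g. all-ones for an unweighted
        distance).  Must be positive and of length 15.
    """
    if override is not None:
        w = np.asarray(override, dtype=float)
        if w.shape != (N_ORBITS,):
            raise ValueError(f"weight override must have length {N_ORBITS}")
        if not np.all(w > 0):
            raise ValueError("all orbit weights must be positive")
        return w
    return 1.0 - np.log(ORBIT_DEPENDENCY_COUNTS) / math.log(N_ORBITS)


def _connected_subgraph_sets(adj: dict, order: dict, k: int):
    """Yield every connected induced k-node subgraph exactly once (ESU)."""
    for v, rank in order.items():
        ext = {u for u in adj[v] if order[u] > rank}
        yield from _extend({v}, ext, adj[v], rank, adj, order, k)


def _extend(sub, ext, closed, root_rank, adj, order, k):
    if len(sub) == k:
        yield tuple(sub)
        return
    ext = set(ext)
    while ext:
        w = ext.pop()
        # exclusive neighbourhood of w w.r.t. the current subgraph
        new_ext = ext | {
            u
            for u in adj[w]
            if order[u] > root_rank and u not in sub and u not in closed
        }
        yield from _extend(sub | {w}, new_ext, closed | adj[w], root_rank, adj, order, k)


def count_orbits(net: nx.Graph) -> pd.DataFrame:
    """Count the 15 graphlet-orbit occurrences touching each node.

    Parameters
    ----------
    net : networkx.Graph
        Simple undirected graph; edge weights are ignored.

    Returns
    -------
    pandas.DataFrame
        One row per node (index = node id, sorted), columns
        ``orbit0`` ... ``orbit14`` of non-negative integers.  ``orbit0``
        equals the node degree.
    """
    nodes = sorted(net.nodes)
    counts = {v: np.zeros(N_ORBITS, dtype=np.int64) for v in nodes}
    adj = {v: set(net[v]) for v in nodes}
    order = {v: i for i, v in enumerate(nodes)}

    for v in nodes:  # orbit 0: each incident edge
        counts[v][0] = len(adj[v])

    for k in (3, 4):
        for sub in _connected_subgraph_sets(adj, order, k):
            members = set(sub)
            degs = {u: len(adj[u] & members) for u in sub}
            n_edges = sum(degs.values()) // 2
            dmax = max(degs.values())
            for u in sub:
                counts[u][_ORBIT_KEY[(k, n_edges, dmax, degs[u])]] += 1

    table = pd.DataFrame(
        [counts[v] for v in nodes],
        index=pd.Index(nodes, name="node"),
        columns=[f"orbit{i}" for i in range(N_ORBITS)],
    )
    return table
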