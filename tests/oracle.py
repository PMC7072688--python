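"""Independent brute-force oracles used to validate the fast paths.

The graphlet oracle enumerates every 2-, 3- and 4-node subset of a
graph, keeps the connected induced ones, and assigns orbits by explicit
isomorphism against hand-built reference graphlets with hand-labelled
orbit positions.  It shares no code with the package's counter (which
uses ESU enumeration and degree-sequence classification).
"""

from itertools import combinations

import networkx as nx
import numpy as np
from networkx.algorithms.isomorphism import GraphMatcher

# reference graphlets: edges over positions 0..k-1, with the orbit of
# each position taken from the canonical 2-4-node orbit numbering
_REFERENCE = [
    ([(0, 1)], {0: 0, 1: 0}),                                          # edge
    ([(0, 1), (1, 2)], {0: 1, 1: 2, 2: 1}),                            # path-3
    ([(0, 1), (1, 2), (0, 2)], {0: 3, 1: 3, 2: 3}),                    # triangle
    ([(0, 1), (1, 2), (2, 3)], {0: 4, 1: 5, 2: 5, 3: 4}),              # path-4
    ([(0, 1), (0, 2), (0, 3)], {0: 7, 1: 6, 2: 6, 3: 6}),              # star-4
    ([(0, 1), (1, 2), (2, 3), (3, 0)], {i: 8 for i in range(4)}),      # cycle-4
    ([(0, 1), (1, 2), (0, 2), (2, 3)], {0: 10, 1: 10, 2: 11, 3: 9}),   # paw
    ([(0, 1), (1, 2), (0, 2), (0, 3), (1, 3)], {0: 13, 1: 13, 2: 12, 3: 12}),  # diamond
    ([list(e) for e in combinations(range(4), 2)], {i: 14 for i in range(4)}),  # K4
]


def _reference_graphs():
    out = []
    for edges, orbits in _REFERENCE:
        g = nx.Graph()
        g.add_nodes_from(orbits)
        g.add_edges_from(edges)
        out.append((g, orbits))
    return out


_REFS = _reference_graphs()


def brute_force_orbits(graph: nx.Graph) -> dict:
    """Exact per-node orbit counts by subset enumeration + isomorphism."""
    counts = {v: np.zeros(15, dtype=int) for v in graph.nodes}
    nodes = list(graph.nodes)
    for k in (2, 3, 4):
        for subset in combinations(nodes, k):
            sub = graph.subgraph(subset)
            if sub.number_of_edges() < k - 1 or not nx.is_connected(sub):
                continue
            for ref, orbits in _REFS:
                if ref.number_of_nodes() != k or ref.number_of_edges() != sub.number_of_edges():
                    continue
                matcher = GraphMatcher(ref, sub)
                if matcher.is_isomorphic():
                    for ref_node, sub_node in matcher.mapping.items():
                        counts[sub_node][orbits[ref_node]] += 1
                    break
    return counts


def brute_force_dependency_counts() -> np.ndarray:
    """o_i derived from the reference graphlets alone: the number of
    distinct orbits reachable as connected induced sub-positions of
    orbit i's graphlet at its representative node (itself included)."""
    o = np.zeros(15, dtype=int)
    for g, orbits in _REFS:
        for node, orbit in orbits.items():
            reachable = set()
            k = g.number_of_nodes()
            for size in range(2, k + 1):
                for subset in combinations(g.nodes, size):
                    if node not in subset:
                        continue
                    sub = g.subgraph(subset)
                    if not nx.is_connected(sub):
                        continue
                    for ref, ref_orbits in _REFS:
                        if (ref.number_of_nodes() != size
                                or ref.number_of_edges() != sub.number_of_edges()):
                            continue
                        matcher = GraphMatcher(ref, sub)
                        if matcher.is_isomorphic():
                            inv = {v: r for r, v in matcher.mapping.items()}
                            reachable.add(ref_orbits[inv[node]])
                            break
            o[orbit] = len(reachable)
    return o


def brute_force_metrics(tp, fp, fn, tn):
    """Plain-arithmetic confusion metrics, coded independently."""
    total = tp + fp + fn + tn
    acc = (tp + tn) / total if total else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return acc, prec, rec, f1
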