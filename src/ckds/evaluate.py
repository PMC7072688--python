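"""Benchmark harness: confusion metrics, a shortest-path baseline, the
per-pair pipeline, and the a/b grid sweep.

A KDS is scored as a gene-level binary classifier against the planted
essential genes.  The evaluation universe for a simulated pair is the
common-node set of the two state networks united with the planted
essential genes (so recall is always out of all m planted genes):

    TP = |essential  ∩ KDS|        FP = |KDS \\ essential|
    FN = |essential \\ KDS|         TN = |universe \\ (KDS ∪ essential)|

    Accuracy  = (TP+TN) / (TP+TN+FP+FN)
    Precision = TP / (TP+FP)
    Recall    = TP / (TP+FN)
    F1        = 2 * Precision * Recall / (Precision + Recall)

The hit fraction Np/(Np+Np') — the share of planted genes recovered —
is also reported separately as ``p_kds``; despite its name in some
presentations it is numerically identical to recall, so both are
surfaced and neither silently replaces the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .kds import KDSParams, KDSResult, extract_kds, extract_kds_single, intersect_kds
from .signature import DEFAULT_D_THRESHOLD, differential_nodes


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int


def confusion(kds_nodes, essential, universe) -> ConfusionCounts:
    """Gene-level confusion counts of a predicted node set."""
    kds_nodes, essential, universe = set(kds_nodes), set(essential), set(universe)
    if not essential <= universe:
        raise ValueError("essential genes must lie within the evaluation universe")
    kds_nodes &= universe
    tp = len(kds_nodes & essential)
    fp = len(kds_nodes - essential)
    fn = len(essential - kds_nodes)
    tn = len(universe - kds_nodes - essential)
    return ConfusionCounts(tp, fp, fn, tn)


def metrics(counts: ConfusionCounts) -> dict:
    """Accuracy/precision/recall/F1 (plus the hit fraction ``p_kds``).

    Zero-denominator cases return 0 and set ``degenerate``.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + fn + tn
    degenerate = False

    def _ratio(num, den):
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    accuracy = _ratio(tp + tn, total)
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    f1 = _ratio(2 * precision * recall, precision + recall) if (precision + recall) else 0.0
    if precision + recall == 0:
        degenerate = True
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "p_kds": recall,
        "degenerate": degenerate,
    }


def baseline_shortest_path_union(net_a, net_b, diff) -> KDSResult:
    """Shortest-path baseline: connect selected genes by hop-shortest
    paths in descending d order (no path scoring), per network, then
    intersect exactly as the criterion does."""

    def _single(net):
        sel = [g for g in diff.index[diff["selected"]] if g in net]
        if not sel:
            raise ValueError("no selected differential node occurs in the network")
        d_of = diff["d_value"].to_dict()
        sub = nx.Graph()
        sub.add_node(sel[0])
        for gene in sel[1:]:
            if gene in sub:
                continue
            best = None
            for target in sub.nodes:
                try:
                    for p in nx.all_shortest_paths(net, gene, target):
                        key = (len(p), tuple(str(v) for v in p))
                        if best is None or key < best:
                            best = key
                except nx.NetworkXNoPath:
                    continue
            if best is None:
                warnings.warn(f"selected gene {gene!r} unreachable; skipped by baseline")
                continue
            p = list(best[1])
            for u, v in zip(p, p[1:]):
                sub.add_edge(u, v, weight=net[u][v].get("weight", 1.0))
        return KDSResult(graph=sub, d_values={g: d_of.get(g, 0.0) for g in sub.nodes})

    return intersect_kds(_single(net_a), _single(net_b))


_ALGORITHMS = {
    "ckds": lambda na, nb, diff, params: extract_kds(na, nb, diff, params),
    "sp-baseline": lambda na, nb, diff, params: baseline_shortest_path_union(na, nb, diff),
}


def prepare_pair(pair, d_threshold: float = DEFAULT_D_THRESHOLD):
    """Front half of the benchmark pipeline for one simulated pair.

    The generator's state networks are the analysis networks (they are
    its declared outputs, already carrying |PCC| weights from the
    simulated expression); this computes the d-value table over their
    common genes.  Returns ``(net_a, net_b, diff_table)``.
    """
    diff = differential_nodes(pair.net_a, pair.net_b, threshold=d_threshold)
    return pair.net_a, pair.net_b, diff


def evaluate_pair(pair, kds_nodes, net_a, net_b) -> dict:
    universe = set(nx.Graph(net_a).nodes) & set(nx.Graph(net_b).nodes)
    universe |= set(pair.essential)
    return metrics(confusion(kds_nodes, pair.essential, sorted(universe)))


def benchmark(dataset, algorithms=("ckds", "sp-baseline"),
              params: KDSParams | None = None) -> pd.DataFrame:
    """Run each algorithm over every simulated pair and score it.

    Returns a tidy per-pair table (columns: pair, algorithm, the four
    metrics, n_kds, error).  A pair failing preprocessing or extraction
    is recorded with an empty prediction, not raised.  Means per
    algorithm are available via ``summarize_benchmark``.
    """
    params = params or KDSParams()
    unknown = set(algorithms) - set(_ALGORITHMS)
    if unknown:
        raise ValueError(f"unknown algorithm(s): {sorted(unknown)}")
    rows = []
    for i, pair in enumerate(dataset):
        try:
            net_a, net_b, diff = prepare_pair(pair, params.d_threshold)
        except ValueError as exc:
            for alg in algorithms:
                m = metrics(confusion([], pair.essential, pair.essential))
                rows.append({"pair": i, "algorithm": alg, "n_kds": 0,
                             "error": str(exc), **m})
            continue
        for alg in algorithms:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    result = _ALGORITHMS[alg](net_a, net_b, diff, params)
                nodes, err = result.nodes, ""
            except ValueError as exc:
                nodes, err = set(), str(exc)
            m = evaluate_pair(pair, nodes, net_a, net_b)
            rows.append({"pair": i, "algorithm": alg, "n_kds": len(nodes),
                         "error": err, **m})
    return pd.DataFrame(rows)


def summarize_benchmark(table: pd.DataFrame) -> pd.DataFrame:
    """Mean metrics per algorithm (Table-style summary)."""
    cols = ["accuracy", "precision", "recall", "f1"]
    return table.groupby("algorithm")[cols].mean()


def ab_sweep(dataset, grid_step: float = 0.1,
             d_threshold: float = DEFAULT_D_THRESHOLD) -> pd.DataFrame:
    """Sweep the path-score coefficient a over {0, step, ..., 1} with
    b = 1 - a and report mean precision per cell.

    Preprocessing and d-values are computed once per pair and reused
    across the grid.  Returns a table (a, b, mean_precision) whose
    ``attrs['argmax_a']`` is the precision-maximising a (ties broken to
    the smallest a).
    """
    n_cells = round(1.0 / grid_step) + 1
    grid = [round(i * grid_step, 10) for i in range(n_cells)]
    prepared = []
    for pair in dataset:
        try:
            prepared.append((pair, *prepare_pair(pair, d_threshold)))
        except ValueError:
            prepared.append((pair, None, None, None))
    rows = []
    for a in grid:
        b = 1.0 - a
        if a + b <= 0:
            continue
        params = KDSParams(a=a, b=b, d_threshold=d_threshold)
        precisions = []
        for pair, net_a, net_b, diff in prepared:
            if net_a is None:
                precisions.append(0.0)
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    nodes = extract_kds(net_a, net_b, diff, params).nodes
            except ValueError:
                nodes = set()
            precisions.append(evaluate_pair(pair, nodes, net_a, net_b)["precision"])
        rows.append({"a": a, "b": b, "mean_precision": float(np.mean(precisions))})
    table = pd.DataFrame(rows)
    best = table.sort_values(["mean_precision", "a"], ascending=[False, True]).iloc[0]
    table.attrs["argmax_a"] = float(best["a"])
    return table
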