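"""Expression preprocessing and co-expression network construction.

The pipeline from raw counts to a pair of weighted state networks:

1. counts -> CPM (per-sample library-size scaling to one million);
2. DEG calling between the two states at p < 0.01, BH-adjusted
   p < 0.05 and |log2FC| > 2.  The differential test is Welch's t-test
   on log2(CPM+1) with Benjamini-Hochberg adjustment — a deliberate,
   clearly labelled stand-in for a negative-binomial exact test;
   externally computed DEG lists can be supplied instead and are used
   verbatim;
3. per state, candidate edges are the protein-interaction backbone
   edges with both endpoints among the DEGs; each candidate is weighted
   by |Pearson correlation| of the two genes' log2(CPM+1) profiles
   across that state's samples, and kept only if it ranks within the
   top 10% of candidates by |PCC| *and* |PCC| >= 0.6.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix


@dataclass
class DEGThresholds:
    """DEG cut-offs; the defaults are the standard single-cell thresholds."""

    p_value_max: float = 0.01
    p_adjust_max: float = 0.05
    abs_log2fc_min: float = 2.0
    adjust_method: str = "fdr_bh"

    def __post_init__(self):
        if self.p_value_max <= 0 or self.p_adjust_max <= 0 or self.abs_log2fc_min <= 0:
            raise ValueError("all thresholds must be strictly positive")


@dataclass
class EdgeFilterParams:
    """Co-expression edge filter: top fraction by |PCC| and a hard floor."""

    top_fraction: float = 0.10
    min_abs_pcc: float = 0.6

    def __post_init__(self):
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if not 0 <= self.min_abs_pcc < 1:
            raise ValueError("min_abs_pcc must be in [0, 1)")


def cpm_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million: value[g, s] = counts[g, s] / library_size(s) * 1e6."""
    if counts.unit != "counts":
        raise ValueError(f"expected unit 'counts', got {counts.unit!r}")
    lib = counts.data.sum(axis=0)
    zero = lib.index[lib <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero library size: {list(zero)}")
    return ExpressionMatrix(counts.data / lib * 1e6, "cpm")


def _as_cpm(expr: ExpressionMatrix) -> ExpressionMatrix:
    if expr.unit == "counts":
        return cpm_normalize(expr)
    if expr.unit == "cpm":
        return expr
    raise ValueError(f"cannot interpret unit {expr.unit!r} as CPM")


def call_degs(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    thresholds: DEGThresholds | None = None,
) -> tuple[list, pd.DataFrame]:
    """Differentially expressed genes between two states.

    Returns ``(deg_list, stats_table)``.  log2FC is the log ratio of
    state mean CPM with pseudocount 1; the p-value is Welch's t-test on
    log2(CPM+1) across samples, BH-adjusted over the shared genes.
    """
    thresholds = thresholds or DEGThresholds()
    a, b = _as_cpm(expr_a), _as_cpm(expr_b)
    if a.data.shape[1] < 2 or b.data.shape[1] < 2:
        raise ValueError("each condition needs at least 2 samples")
    genes = sorted(set(a.genes) & set(b.genes))
    if not genes:
        raise ValueError("empty gene intersection between conditions")
    mat_a = a.data.loc[genes].to_numpy()
    mat_b = b.data.loc[genes].to_numpy()
    log_a = np.log2(mat_a + 1.0)
    log_b = np.log2(mat_b + 1.0)
    lfc = np.log2(mat_a.mean(axis=1) + 1.0) - np.log2(mat_b.mean(axis=1) + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(log_a, log_b, axis=1, equal_var=False)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)  # zero-variance genes: no call
    _, padj, _, _ = multipletests(pvals, method=thresholds.adjust_method)
    table = pd.DataFrame(
        {"log2fc": lfc, "p_value": pvals, "p_adjust": padj},
        index=pd.Index(genes, name="gene"),
    )
    table["deg"] = (
        (table["p_value"] < thresholds.p_value_max)
        & (table["p_adjust"] < thresholds.p_adjust_max)
        & (table["log2fc"].abs() > thresholds.abs_log2fc_min)
    )
    table.attrs["test"] = "welch_t_log2cpm1"
    return list(table.index[table["deg"]]), table


def build_network(
    expr: ExpressionMatrix,
    degs,
    backbone: nx.Graph,
    params: EdgeFilterParams | None = None,
) -> nx.Graph:
    """One state's weighted co-expression network on the PPI backbone.

    Candidate edges are backbone edges with both endpoints in ``degs``;
    each gets weight |PCC| of the two genes' log2(CPM+1) profiles, and
    survives only if it ranks in the top ``ceil(top_fraction * n_candidates)``
    by |PCC| and |PCC| >= ``min_abs_pcc``.  Isolated nodes are dropped.
    """
    params = params or EdgeFilterParams()
    expr = _as_cpm(expr)
    degs = set(degs)
    missing = degs - set(expr.genes)
    if missing:
        raise ValueError(f"DEGs missing from expression matrix: {sorted(missing)[:5]}")
    if backbone.number_of_edges() == 0:
        raise ValueError("backbone network is empty")
    candidates = [
        tuple(sorted((str(u), str(v))))
        for u, v in backbone.edges
        if u in degs and v in degs
    ]
    if not candidates:
        raise ValueError("no candidate edges: no backbone edge joins two DEGs")
    log_expr = np.log2(expr.data.to_numpy() + 1.0)
    row = {g: i for i, g in enumerate(expr.genes)}
    weighted = []
    for u, v in sorted(set(candidates)):
        x, y = log_expr[row[u]], log_expr[row[v]]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(f"zero-variance gene in candidate edge ({u}, {v}); skipped")
            continue
        pcc = abs(float(np.corrcoef(x, y)[0, 1]))
        weighted.append((u, v, min(pcc, 1.0)))
    k = math.ceil(params.top_fraction * len(candidates))
    weighted.sort(key=lambda t: (-t[2], t[0], t[1]))
    net = nx.Graph()
    for u, v, w in weighted[:k]:
        if w >= params.min_abs_pcc:
            net.add_edge(u, v, weight=w)
    if net.number_of_edges() == 0:
        raise ValueError("no candidate edge passed the |PCC| filter")
    return net


def common_nodes(net_a: nx.Graph, net_b: nx.Graph) -> list:
    """Sorted intersection of the two node sets (may be empty)."""
    return sorted(set(net_a.nodes) & set(net_b.nodes))
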