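import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ckds.io import ExpressionMatrix
from ckds.preprocess import (
    DEGThresholds,
    EdgeFilterParams,
    build_network,
    call_degs,
    common_nodes,
    cpm_normalize,
)


def matrix(values, genes=None, samples=None, unit="counts"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"c{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), unit)


class TestCPM:
    def test_direct_formula(self):
        counts = matrix([[200.0], [1_999_800.0]])
        cpm = cpm_normalize(counts)
        assert cpm.data.iloc[0, 0] == pytest.approx(100.0)

    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(0)
        counts = matrix(rng.integers(0, 500, size=(30, 8)))
        cpm = cpm_normalize(counts)
        assert np.allclose(cpm.data.sum(axis=0), 1e6)

    def test_zero_library_named(self):
        counts = matrix([[1.0, 0.0], [2.0, 0.0]], samples=["ok", "dead"])
        with pytest.raises(ValueError, match="dead"):
            cpm_normalize(counts)


class TestCallDegs:
    def synthetic_pair(self, mean_a=1000.0, mean_b=10.0, n=50, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        flat = np.full((20, n), 500.0)
        expr_a = np.vstack([np.full(n, mean_a), flat]) * rng.lognormal(0, noise, (21, n))
        expr_b = np.vstack([np.full(n, mean_b), flat]) * rng.lognormal(0, noise, (21, n))
        genes = ["target"] + [f"bg{i}" for i in range(20)]
        return (matrix(expr_a, genes=genes, unit="cpm"),
                matrix(expr_b, genes=genes, unit="cpm"))

    def test_strong_fold_change_called(self):
        a, b = self.synthetic_pair()
        degs, table = call_degs(a, b)
        assert "target" in degs
        assert abs(table.loc["target", "log2fc"]) > 2

    def test_identical_gene_not_called(self):
        a, b = self.synthetic_pair()
        assert not table_row_deg(a, b, "bg0")

    def test_infinite_threshold_empty(self):
        a, b = self.synthetic_pair()
        degs, _ = call_degs(a, b, DEGThresholds(abs_log2fc_min=math.inf))
        assert degs == []

    def test_sample_order_invariance(self):
        a, b = self.synthetic_pair()
        degs1, _ = call_degs(a, b)
        perm = list(reversed(a.samples))
        a2 = ExpressionMatrix(a.data[perm], a.unit)
        degs2, _ = call_degs(a2, b)
        assert degs1 == degs2

    def test_too_few_samples(self):
        a = matrix([[1.0]], unit="cpm")
        with pytest.raises(ValueError, match="2 samples"):
            call_degs(a, a)


def table_row_deg(a, b, gene):
    _, table = call_degs(a, b)
    return bool(table.loc[gene, "deg"])


class TestBuildNetwork:
    def correlated_expr(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(n)
        rows = {
            "g1": z,
            "g2": 2.0 * z + 0.01 * rng.standard_normal(n),      # |PCC| ~ 1 with g1
            "g3": rng.standard_normal(n),                        # uncorrelated
            "g4": -z + 0.01 * rng.standard_normal(n),            # strong negative
        }
        values = 2.0 ** (8 + np.vstack(list(rows.values()))) - 1
        return matrix(values, genes=list(rows), unit="cpm")

    def backbone(self):
        g = nx.Graph()
        g.add_edges_from([("g1", "g2"), ("g1", "g3"), ("g2", "g4"), ("g3", "g4")])
        return g

    def test_proportional_profiles_retained(self):
        expr = self.correlated_expr()
        net = build_network(expr, expr.genes, self.backbone(),
                            EdgeFilterParams(top_fraction=1.0))
        assert net.has_edge("g1", "g2")
        assert net["g1"]["g2"]["weight"] > 0.99

    def test_hard_pcc_floor(self):
        expr = self.correlated_expr()
        net = build_network(expr, expr.genes, self.backbone(),
                            EdgeFilterParams(top_fraction=1.0, min_abs_pcc=0.6))
        assert not net.has_edge("g1", "g3")  # uncorrelated pair dropped

    def test_negative_correlation_kept_as_abs(self):
        expr = self.correlated_expr()
        net = build_network(expr, expr.genes, self.backbone(),
                            EdgeFilterParams(top_fraction=1.0))
        assert net.has_edge("g2", "g4")
        assert 0.9 < net["g2"]["g4"]["weight"] <= 1.0

    def test_top_fraction_counting(self):
        rng = np.random.default_rng(3)
        n_genes = 30
        values = 2.0 ** (8 + rng.standard_normal((n_genes, 40))) - 1
        expr = matrix(values, unit="cpm")
        backbone = nx.complete_graph(expr.genes)  # 435 candidates
        net = build_network(expr, expr.genes, backbone,
                            EdgeFilterParams(top_fraction=0.10, min_abs_pcc=0.0))
        assert net.number_of_edges() <= math.ceil(0.10 * 435)

    def test_output_subgraph_of_backbone(self):
        expr = self.correlated_expr()
        bb = self.backbone()
        net = build_network(expr, expr.genes, bb, EdgeFilterParams(top_fraction=1.0))
        assert all(bb.has_edge(u, v) for u, v in net.edges)

    def test_raising_floor_never_adds_edges(self):
        expr = self.correlated_expr()
        lo = build_network(expr, expr.genes, self.backbone(),
                           EdgeFilterParams(top_fraction=1.0, min_abs_pcc=0.1))
        hi = build_network(expr, expr.genes, self.backbone(),
                           EdgeFilterParams(top_fraction=1.0, min_abs_pcc=0.7))
        assert set(map(frozenset, hi.edges)) <= set(map(frozenset, lo.edges))

    def test_no_candidates_errors(self):
        expr = self.correlated_expr()
        bb = nx.Graph([("x", "y")])  # no overlap with DEGs
        with pytest.raises(ValueError, match="candidate"):
            build_network(expr, expr.genes, bb)


def test_common_nodes():
    a = nx.path_graph(["a", "b", "c"])
    b = nx.path_graph(["b", "c", "d"])
    assert common_nodes(a, b) == ["b", "c"]
    assert common_nodes(a, nx.path_graph(["x", "y"])) == []
    assert common_nodes(a, a) == ["a", "b", "c"]
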