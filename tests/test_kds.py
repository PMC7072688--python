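import networkx as nx
import pandas as pd
import pytest

from ckds.kds import (
    KDSParams,
    extract_kds,
    extract_kds_single,
    intersect_kds,
    score_path,
)


def diff_table(d_values, threshold=0.4):
    table = pd.DataFrame({"d_value": pd.Series(d_values)})
    table.index.name = "gene"
    table["selected"] = table["d_value"] >= threshold
    return table.sort_values(by="d_value", ascending=False, kind="mergesort")


class TestScorePath:
    def test_direct_sum_with_defaults(self):
        assert score_path([0.5, 0.2], [0.7], KDSParams()) == pytest.approx(1.4)

    def test_a_zero_reduces_to_weight_sum(self):
        assert score_path([0.9, 0.9], [0.3, 0.4], KDSParams(a=0.0, b=2.0)) == pytest.approx(1.4)

    def test_homogeneity_preserves_ranking(self):
        p1 = ([0.5, 0.1], [0.9])
        p2 = ([0.2, 0.2], [0.5, 0.4])
        s1, s2 = (score_path(*p, KDSParams()) for p in (p1, p2))
        d1, d2 = (score_path(*p, KDSParams(a=2.0, b=2.0)) for p in (p1, p2))
        assert d1 == pytest.approx(2 * s1) and d2 == pytest.approx(2 * s2)
        assert (s1 > s2) == (d1 > d2)

    def test_empty_path_rejected(self):
        with pytest.raises(ValueError):
            score_path([0.5], [], KDSParams())


class TestExtractSingle:
    def test_adjacent_selected_nodes_no_path_search(self):
        net = nx.complete_graph(["a", "b", "c"])
        nx.set_edge_attributes(net, 0.9, "weight")
        diff = diff_table({"a": 0.9, "b": 0.8, "c": 0.7})
        res = extract_kds_single(net, diff, KDSParams())
        assert res.nodes == {"a", "b", "c"}
        assert res.connected
        assert all(log["kind"] in ("seed", "direct") for log in res.growth_log)

    def test_path_through_low_d_interior(self):
        # seed a, selected c two hops away: the unique shortest path
        # a-b-c is added whole
        net = nx.Graph()
        net.add_edge("a", "b", weight=0.5)
        net.add_edge("b", "c", weight=0.5)
        diff = diff_table({"a": 0.9, "c": 0.8, "b": 0.1})
        res = extract_kds_single(net, diff, KDSParams())
        assert res.nodes == {"a", "b", "c"}
        assert len(res.edges) == 2
        assert res.connected

    def test_diamond_picks_heavier_path(self):
        # two 2-hop routes from d to seed a; equal d on interiors,
        # weights 1.5 vs 0.9 decide
        net = nx.Graph()
        net.add_edge("a", "x", weight=0.8)
        net.add_edge("x", "d", weight=0.7)   # route via x: 1.5
        net.add_edge("a", "y", weight=0.5)
        net.add_edge("y", "d", weight=0.4)   # route via y: 0.9
        diff = diff_table({"a": 0.9, "d": 0.8, "x": 0.1, "y": 0.1})
        res = extract_kds_single(net, diff, KDSParams())
        assert "x" in res.nodes and "y" not in res.nodes
        path_log = [e for e in res.growth_log if e["kind"] == "path"]
        assert path_log[0]["path"] == ["d", "x", "a"]

    def test_unreachable_selected_node_skipped_with_warning(self):
        net = nx.Graph()
        net.add_edge("a", "b", weight=0.5)
        net.add_edge("u", "v", weight=0.5)  # separate component
        diff = diff_table({"a": 0.9, "u": 0.8})
        with pytest.warns(UserWarning, match="unreachable"):
            res = extract_kds_single(net, diff, KDSParams())
        assert res.nodes == {"a"}

    def test_no_selected_node_in_net_errors(self):
        net = nx.path_graph(["p", "q"])
        diff = diff_table({"x": 0.9})
        with pytest.raises(ValueError):
            extract_kds_single(net, diff, KDSParams())


class TestIntersect:
    def test_idempotent(self):
        net = nx.Graph()
        net.add_edge("a", "b", weight=0.5)
        diff = diff_table({"a": 0.9, "b": 0.8})
        k = extract_kds_single(net, diff, KDSParams())
        out = intersect_kds(k, k)
        assert out.nodes == k.nodes and out.edges == k.edges

    def test_node_intersection_edge_union_restricted(self):
        from ckds.kds import KDSResult

        g1 = nx.Graph()
        g1.add_edge("a", "b", weight=0.5)
        g1.add_edge("b", "c", weight=0.6)
        g2 = nx.Graph()
        g2.add_edge("b", "c", weight=0.9)
        g2.add_edge("c", "d", weight=0.7)
        k1 = KDSResult(graph=g1, d_values={})
        k2 = KDSResult(graph=g2, d_values={})
        out = intersect_kds(k1, k2)
        assert out.nodes == {"b", "c"}
        assert out.edges == {frozenset(("b", "c"))}
        assert out.graph["b"]["c"]["weight"] == pytest.approx(0.9)  # max rule

    def test_disjoint_errors(self):
        from ckds.kds import KDSResult

        k1 = KDSResult(graph=nx.path_graph(["a", "b"]), d_values={})
        k2 = KDSResult(graph=nx.path_graph(["x", "y"]), d_values={})
        with pytest.raises(ValueError):
            intersect_kds(k1, k2)


class TestExtractFull:
    def test_identical_networks_equal_single(self):
        net = nx.Graph()
        net.add_edge("a", "b", weight=0.5)
        net.add_edge("b", "c", weight=0.5)
        diff = diff_table({"a": 0.9, "c": 0.8, "b": 0.1})
        single = extract_kds_single(net, diff, KDSParams())
        full = extract_kds(net, net.copy(), diff, KDSParams())
        assert full.nodes == single.nodes and full.edges == single.edges

    def test_deterministic_on_simulated_pair(self, small_dataset):
        from ckds.evaluate import prepare_pair

        pair = small_dataset[0]
        na, nb, diff = prepare_pair(pair)
        r1 = extract_kds(na, nb, diff, KDSParams())
        r2 = extract_kds(na, nb, diff, KDSParams())
        assert r1.nodes == r2.nodes and r1.edges == r2.edges
        assert r1.growth_log == r2.growth_log

    def test_kds_smaller_than_common_node_set(self, small_dataset):
        from ckds.evaluate import prepare_pair

        for pair in small_dataset[:5]:
            na, nb, diff = prepare_pair(pair)
            res = extract_kds(na, nb, diff, KDSParams())
            assert len(res.nodes) < len(set(na) & set(nb))

    def test_threshold_monotonicity(self, small_dataset):
        """Lowering the selection cut never removes a selected gene
        that a stricter cut had included."""
        from ckds.signature import differential_nodes

        pair = small_dataset[1]
        strict = differential_nodes(pair.net_a, pair.net_b, threshold=0.5)
        loose = differential_nodes(pair.net_a, pair.net_b, threshold=0.4)
        hi = extract_kds(pair.net_a, pair.net_b, strict, KDSParams(d_threshold=0.5))
        lo = extract_kds(pair.net_a, pair.net_b, loose, KDSParams(d_threshold=0.4))
        strict_sel = set(strict.index[strict["selected"]])
        assert (hi.nodes & strict_sel) <= lo.nodes
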