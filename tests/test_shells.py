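"""Global metrics: K-shell peeling, IKS, tenacity, cut sets, HTGC."""

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcicnet.fixtures import fig4_edges_by_label, synthetic_graph
from hcicnet.shells import (
    edge_tenacity_bruteforce,
    htgc,
    iks,
    is_cut_set,
    kshell_decompose,
    node_tenacity,
)

from conftest import complete_graph, cycle_graph, path_graph, star_graph


class TestKshell:
    def test_cycle_is_all_shell_two(self):
        d = kshell_decompose(cycle_graph(7))
        assert set(d.ks.values()) == {2}

    def test_tree_is_all_shell_one(self):
        tree = nx.relabel_nodes(nx.balanced_tree(2, 3), str)
        assert set(kshell_decompose(tree).ks.values()) == {1}

    def test_fig5_shell_assignment(self, fig5, expectations):
        d = kshell_decompose(fig5)
        assert d.ks == expectations["fig5"]["kshell"]

    def test_isolated_nodes_get_shell_zero(self):
        g = nx.Graph([("a", "b")])
        g.add_node("z")
        assert kshell_decompose(g).ks["z"] == 0

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_core_number_oracle(self, seed):
        g = synthetic_graph("erdos-renyi", seed=seed, n=50, p=0.08)
        d = kshell_decompose(g)
        assert d.ks == nx.core_number(g)

    def test_strip_order_bookkeeping(self, fig5):
        d = kshell_decompose(fig5)
        for n, shell in d.ks.items():
            assert 1 <= d.strip_order[n] <= d.layer_sweeps[shell]
        # leaves go in the first sweep of shell 1; their hubs in a later one
        assert d.strip_order["A"] == 1
        assert d.strip_order["F"] > d.strip_order["A"]


class TestIks:
    def test_fig5_full_table(self, fig5, expectations):
        table = iks(fig5)
        for node, printed in expectations["fig5"]["iks"].items():
            assert table[node] == pytest.approx(printed, abs=5.1e-4), node

    def test_single_clique_defaults_next_shell(self):
        table = iks(complete_graph(4))
        assert all(v == pytest.approx(3.75) for v in table.values.values())

    def test_bracketing_invariant(self, small_graph):
        """KS_i <= IKS_i < KS_next for every node."""
        d = kshell_decompose(small_graph)
        table = iks(small_graph, d)
        for n in small_graph.nodes:
            s = d.ks[n]
            assert s <= table[n] < d.layer_next[s]


class TestNodeTenacity:
    def test_fig1_boundary_and_hub(self, fig1):
        assert node_tenacity(fig1, "A") == 15
        assert node_tenacity(fig1, "G") == 5.5

    def test_full_worked_example_column(self, fig1, expectations):
        for node, printed in expectations["fig1"]["tenacity"].items():
            assert node_tenacity(fig1, node) == pytest.approx(printed), node

    def test_leaf_of_connected_graph(self):
        g = path_graph(8)
        assert node_tenacity(g, "0") == 8  # (1 + 7) / 1

    def test_single_node_graph_rejected(self):
        g = nx.Graph()
        g.add_node("x")
        with pytest.raises(ValueError):
            node_tenacity(g, "x")

    def test_disconnected_input_accepted(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        assert node_tenacity(g, "a") == (1 + 2) / 2


class TestCutSets:
    def test_published_cut_set_facts(self, fig4):
        by_label = fig4_edges_by_label(fig4)
        assert is_cut_set(fig4, [by_label[x] for x in "cdfg"])
        assert not is_cut_set(fig4, [by_label[x] for x in "bcf"])

    def test_removing_s1_disconnects(self, fig4):
        by_label = fig4_edges_by_label(fig4)
        h = fig4.copy()
        h.remove_edges_from(by_label[x] for x in "cdfg")
        assert not nx.is_connected(h)

    def test_removing_s2_stays_connected(self, fig4):
        by_label = fig4_edges_by_label(fig4)
        h = fig4.copy()
        h.remove_edges_from(by_label[x] for x in "bcf")
        assert nx.is_connected(h)

    def test_bridge_is_a_cut_set(self):
        g = path_graph(3)
        assert is_cut_set(g, [("0", "1")])

    def test_superset_of_cut_set_is_not_minimal(self, fig4):
        by_label = fig4_edges_by_label(fig4)
        assert not is_cut_set(fig4, [by_label[x] for x in "cdfga"])

    def test_disconnected_graph_rejected(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        with pytest.raises(ValueError):
            is_cut_set(g, [("a", "b")])


class TestEdgeTenacity:
    @pytest.mark.parametrize(
        "graph,expected",
        [
            (path_graph(2), 1.0),
            (path_graph(3), 1.5),
            (complete_graph(3), 2.0),
        ],
        ids=["K2", "P3", "K3"],
    )
    def test_small_graph_oracle_values(self, graph, expected):
        assert edge_tenacity_bruteforce(graph) == pytest.approx(expected)

    def test_guard_on_large_graphs(self):
        with pytest.raises(ValueError, match="node_tenacity"):
            edge_tenacity_bruteforce(complete_graph(8))


class TestHtgc:
    def test_fig1_named_values(self, fig1):
        table = htgc(fig1)
        assert table["G"] == pytest.approx(1.925, abs=5.1e-4)
        assert table["C"] == pytest.approx(1.647, abs=5.1e-4)
        assert table["L"] == pytest.approx(12.5)

    def test_full_worked_example_column(self, fig1, expectations):
        """Printed values divide T by 3-decimal-rounded IKS; both conventions
        must agree within half an ulp of the printed precision."""
        iks_t = iks(fig1)
        for node, printed in expectations["fig1"]["htgc"].items():
            got = node_tenacity(fig1, node) / round(iks_t[node], 3)
            assert got == pytest.approx(printed, abs=5.1e-4), node

    def test_discriminates_equal_tenacity_boundaries(self, fig1):
        """A and M tie on tenacity, but A's denser surroundings must give
        it the smaller (more important) global coefficient."""
        assert node_tenacity(fig1, "A") == node_tenacity(fig1, "M")
        table = htgc(fig1)
        assert table["A"] < table["M"]

    def test_internal_consistency_t_over_iks(self, fig1):
        assert node_tenacity(fig1, "G") / iks(fig1)["G"] == pytest.approx(
            1.925, abs=5.1e-4
        )
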