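"""Unit tests for connectivity, tree pruning and spectral decomposition."""

import numpy as np
import networkx as nx
import pytest

from orthograph import (
    FilterParams,
    OrthologyGraph,
    algebraic_connectivity,
    connected_components,
    decompose,
    fiedler_split,
    prune_trees,
)
from .conftest import complete_multipartite, mk_component, two_cliques_with_bridges


def graph_from_edges(edges):
    """OrthologyGraph from (u, v) pairs; species = first char of the id."""
    g = OrthologyGraph()
    for u, v in edges:
        g.adj.setdefault(u, []).append((v, 100.0))
        g.adj.setdefault(v, []).append((u, 100.0))
        g.species[u] = u[0]
        g.species[v] = v[0]
    for u in g.adj:
        g.adj[u].sort()
    return g


class TestConnectedComponents:
    def test_two_disjoint_triangles(self):
        g = graph_from_edges(
            [("a1", "b1"), ("b1", "c1"), ("a1", "c1"),
             ("a2", "b2"), ("b2", "c2"), ("a2", "c2")]
        )
        comps = connected_components(g)
        assert [c.n for c in comps] == [3, 3]
        assert comps[0].vertex_ids == ["a1", "b1", "c1"]

    def test_empty_graph(self):
        assert connected_components(OrthologyGraph()) == []

    def test_path_plus_isolated_edge(self):
        g = graph_from_edges([("a1", "b1"), ("b1", "c1"), ("d1", "e1")])
        comps = connected_components(g)
        assert [set(c.vertex_ids) for c in comps] == [
            {"a1", "b1", "c1"}, {"d1", "e1"},
        ]

    def test_matches_networkx_on_random_graph(self):
        rng = np.random.default_rng(5)
        G = nx.gnp_random_graph(30, 0.08, seed=12)
        g = graph_from_edges(
            [(f"a{u}", f"b{v}") for u, v in G.edges()]
        )
        ours = {frozenset(c.vertex_ids) for c in connected_components(g)}
        H = nx.Graph((f"a{u}", f"b{v}") for u, v in G.edges())
        theirs = {frozenset(c) for c in nx.connected_components(H)}
        assert ours == theirs


class TestPruneTrees:
    def test_pendant_removed_triangle_kept(self):
        c = mk_component(
            [("a1", "A"), ("b1", "B"), ("c1", "C"), ("d1", "D")],
            [("a1", "b1"), ("b1", "c1"), ("a1", "c1"), ("c1", "d1")],
        )
        core, removed = prune_trees(c, n_species_total=4)
        assert removed == ["d1"]
        assert set(core.vertex_ids) == {"a1", "b1", "c1"}
        assert len(core.edges) == 3

    def test_pure_tree_vanishes(self):
        ids = [("v%d" % i, "S%d" % i) for i in range(5)]
        c = mk_component(ids, [("v%d" % i, "v%d" % (i + 1)) for i in range(4)])
        core, removed = prune_trees(c, n_species_total=5)
        assert core is None and sorted(removed) == [n for n, _ in ids]

    def test_two_species_analysis_never_prunes(self):
        c = mk_component(
            [("a1", "A"), ("b1", "B"), ("b2", "B"), ("b3", "B")],
            [("a1", "b1"), ("a1", "b2"), ("a1", "b3")],
        )
        core, removed = prune_trees(c, n_species_total=2)
        assert removed == [] and core.vertex_ids == c.vertex_ids


class TestAlgebraicConnectivity:
    def test_complete_graph_k4(self):
        c = complete_multipartite([[("a", "A")], [("b", "B")], [("c", "C")], [("d", "D")]])
        res = algebraic_connectivity(c)
        assert res.alpha2 == pytest.approx(4.0)
        assert res.normalized_conn == pytest.approx(1.0)

    def test_path_p3(self):
        c = mk_component(
            [("a", "A"), ("b", "B"), ("c", "C")], [("a", "b"), ("b", "c")]
        )
        res = algebraic_connectivity(c)
        assert res.alpha2 == pytest.approx(1.0)
        assert res.normalized_conn == pytest.approx(1 / 3)

    def test_single_edge_k2(self):
        c = mk_component([("a", "A"), ("b", "B")], [("a", "b")])
        res = algebraic_connectivity(c)
        assert res.alpha2 == pytest.approx(2.0)
        assert res.normalized_conn == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "sizes", [(1, 1, 2), (2, 2), (3, 1), (2, 2, 2), (4, 2, 1)]
    )
    def test_complete_multipartite_closed_form(self, sizes):
        parts = [
            [(f"s{k}v{i}", f"S{k}") for i in range(sz)]
            for k, sz in enumerate(sizes)
        ]
        c = complete_multipartite(parts)
        res = algebraic_connectivity(c)
        n = sum(sizes)
        assert res.normalized_conn == pytest.approx((n - max(sizes)) / n)

    def test_fiedler_orthogonal_to_ones_and_unit(self):
        c = two_cliques_with_bridges(4, 1)
        res = algebraic_connectivity(c)
        assert abs(res.fiedler.sum()) < 1e-8
        assert np.linalg.norm(res.fiedler) == pytest.approx(1.0)

    def test_iterative_matches_dense_on_random_graphs(self):
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 50:
            n = int(rng.integers(3, 65))
            G = nx.gnp_random_graph(n, 0.25, seed=int(rng.integers(2**31)))
            if not nx.is_connected(G):
                continue
            checked += 1
            c = mk_component(
                [(f"v{i:03d}", f"S{i}") for i in range(n)],
                [(f"v{u:03d}", f"v{v:03d}") for u, v in G.edges()],
            )
            dense = algebraic_connectivity(c, method="dense")
            it = algebraic_connectivity(c, method="iterative", seed=7)
            assert it.alpha2 == pytest.approx(dense.alpha2, rel=1e-6)

    def test_disconnected_input_is_an_error(self):
        c = mk_component(
            [("a", "A"), ("b", "B"), ("c", "A"), ("d", "B")],
            [("a", "b"), ("c", "d")],
        )
        with pytest.raises(ValueError, match="disconnected"):
            algebraic_connectivity(c)


class TestFiedlerSplit:
    def test_bridge_between_cliques_is_severed(self):
        c = two_cliques_with_bridges(4, 1)
        res = algebraic_connectivity(c)
        pos, neg = fiedler_split(c, res)
        sides = {frozenset(pos), frozenset(neg)}
        assert sides == {
            frozenset(f"a{i}" for i in range(4)),
            frozenset(f"b{i}" for i in range(4)),
        }

    def test_k2_antisymmetric_vector_splits_one_each(self):
        c = mk_component([("a", "A"), ("b", "B")], [("a", "b")])
        res = algebraic_connectivity(c)
        assert np.allclose(np.sort(np.abs(res.fiedler)), [2**-0.5] * 2)
        pos, neg = fiedler_split(c, res)
        assert len(pos) == 1 and len(neg) == 1

    def test_barbell_k5_two_bridges(self):
        c = two_cliques_with_bridges(5, 2)
        res = algebraic_connectivity(c)
        pos, neg = fiedler_split(c, res)
        assert {frozenset(pos), frozenset(neg)} == {
            frozenset(f"a{i}" for i in range(5)),
            frozenset(f"b{i}" for i in range(5)),
        }


def params(threshold=0.1):
    return FilterParams(conn_threshold=threshold)


class TestDecompose:
    def test_complete_multipartite_group_emitted_intact(self):
        c = complete_multipartite(
            [[("a1", "A")], [("b1", "B")], [("c1", "C")], [("d1", "D")]]
        )
        groups = decompose(c, params(), n_species_total=4)
        assert len(groups) == 1
        assert groups[0].conn == pytest.approx(1.0)
        assert groups[0].members == {
            "A": ["a1"], "B": ["b1"], "C": ["c1"], "D": ["d1"]
        }

    def test_bridged_groups_split_and_bridge_discarded(self):
        c = two_cliques_with_bridges(4, 1)
        groups = decompose(c, params(), n_species_total=4)
        assert len(groups) == 2
        assert {frozenset(g.all_ids()) for g in groups} == {
            frozenset(f"a{i}" for i in range(4)),
            frozenset(f"b{i}" for i in range(4)),
        }
        assert all(g.conn == pytest.approx(1.0) for g in groups)

    def test_star_component_fully_pruned_in_multispecies_analysis(self):
        c = mk_component(
            [("a1", "A"), ("b1", "B"), ("c1", "C"), ("d1", "D")],
            [("a1", "b1"), ("a1", "c1"), ("a1", "d1")],
        )
        assert decompose(c, params(), n_species_total=4) == []

    def test_same_star_survives_two_species_analysis(self):
        c = mk_component(
            [("a1", "A"), ("b1", "B"), ("b2", "B"), ("b3", "B")],
            [("a1", "b1"), ("a1", "b2"), ("a1", "b3")],
        )
        groups = decompose(c, params(), n_species_total=2)
        assert len(groups) == 1 and groups[0].n_proteins == 4

    def test_threshold_sweep_monotone_on_waist_fixture(self):
        c = two_cliques_with_bridges(4, 4)
        counts, largest = [], []
        for t in (0.1, 0.25, 0.5, 0.75):
            groups = decompose(c, params(t), n_species_total=4)
            counts.append(len(groups))
            largest.append(max(g.n_proteins for g in groups))
        assert counts == sorted(counts)
        assert largest == sorted(largest, reverse=True)
        assert counts[0] == 1 and largest[0] == 8
        assert counts[2] == 2 and largest[2] == 4

    def test_output_disjoint_and_within_component(self):
        rng = np.random.default_rng(99)
        G = nx.gnp_random_graph(18, 0.2, seed=3)
        G = G.subgraph(max(nx.connected_components(G), key=len))
        c = mk_component(
            [(f"v{i:02d}", f"S{i % 5}") for i in G.nodes()],
            [(f"v{u:02d}", f"v{v:02d}") for u, v in G.edges()],
        )
        groups = decompose(c, params(0.5), n_species_total=5)
        seen = set()
        for g in groups:
            ids = set(g.all_ids())
            assert not ids & seen
            seen |= ids
        assert seen <= set(c.vertex_ids)

    def test_deterministic_given_seed(self):
        c = two_cliques_with_bridges(5, 2)
        a = decompose(c, params(0.3), n_species_total=5, seed=9)
        b = decompose(c, params(0.3), n_species_total=5, seed=9)
        assert a == b
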