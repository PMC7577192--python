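"""Centralities, cliques, communities, topology, small-world index."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from metabonet.metrics import (
    characteristic_path_length,
    eigencentrality,
    flow_betweenness,
    hub_authority,
    largest_cliques,
    louvain,
    membership_frequency,
    modularity,
    small_world_index,
    spinglass,
    topology_summary,
    weighted_clustering,
)


def _weighted_graph(edges) -> nx.Graph:
    g = nx.Graph()
    g.add_weighted_edges_from(edges)
    return g


class TestEigencentrality:
    def test_complete_graph_symmetry(self):
        g = nx.complete_graph(5)
        ec = eigencentrality(g)
        np.testing.assert_allclose(ec.to_numpy(), 1.0, atol=1e-9)

    def test_star_center_dominates(self):
        ec = eigencentrality(nx.star_graph(6))
        assert ec.idxmax() == 0
        assert (ec.drop(0) < 1.0).all()

    def test_weighted_path_matches_dense_eigendecomposition(self):
        g = _weighted_graph([(0, 1, 0.5), (1, 2, 0.9), (2, 3, 0.2)])
        ec = eigencentrality(g)
        a = nx.to_numpy_array(g, nodelist=[0, 1, 2, 3])
        w, v = np.linalg.eigh(a)
        oracle = np.abs(v[:, -1])
        oracle /= oracle.max()
        np.testing.assert_allclose(ec.to_numpy(), oracle, atol=1e-8)

    def test_invariant_under_weight_rescaling(self):
        g = _weighted_graph([(0, 1, 0.5), (1, 2, 0.9), (0, 2, 0.3)])
        ec1 = eigencentrality(g)
        h = _weighted_graph([(u, v, 10 * d["weight"]) for u, v, d in g.edges(data=True)])
        ec2 = eigencentrality(h)
        np.testing.assert_allclose(ec1.to_numpy(), ec2.to_numpy(), atol=1e-9)

    def test_empty_graph_all_zero(self):
        g = nx.empty_graph(4)
        assert (eigencentrality(g) == 0).all()


class TestHubAuthority:
    def test_single_arc(self):
        g = nx.DiGraph()
        g.add_edge("u", "v", weight=1.0)
        hub, auth = hub_authority(g)
        assert hub["u"] == pytest.approx(1.0)
        assert hub["v"] == pytest.approx(0.0, abs=1e-12)
        assert auth["v"] == pytest.approx(1.0)
        assert auth["u"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_converged_hits_iteration(self):
        rng = np.random.default_rng(3)
        g = nx.DiGraph()
        nodes = list(range(6))
        for u, v in itertools.permutations(nodes, 2):
            if rng.random() < 0.4:
                g.add_edge(u, v, weight=float(rng.uniform(0.1, 2.0)))
        hub, auth = hub_authority(g)
        # oracle: 1000 normalized HITS iterations
        a = nx.to_numpy_array(g, nodelist=nodes)
        h = np.ones(len(nodes))
        for _ in range(1000):
            au = a.T @ h
            au /= np.linalg.norm(au) or 1.0
            h = a @ au
            h /= np.linalg.norm(h) or 1.0
        np.testing.assert_allclose(hub.loc[nodes].to_numpy(), h / h.max(), atol=1e-8)
        np.testing.assert_allclose(auth.loc[nodes].to_numpy(), au / au.max(), atol=1e-8)

    def test_no_outgoing_arcs_zero_hub(self):
        g = nx.DiGraph([(0, 2), (1, 2)])
        hub, auth = hub_authority(g)
        assert hub[2] == pytest.approx(0.0, abs=1e-12)
        assert auth[2] == pytest.approx(1.0)


class TestFlowBetweenness:
    def test_path_middle_node(self):
        g = _weighted_graph([("A", "B", 0.5), ("B", "C", 0.3)])
        fb = flow_betweenness(g)
        assert fb["B"] == pytest.approx(0.3)
        assert fb["A"] == pytest.approx(0.0)
        assert fb["C"] == pytest.approx(0.0)

    def test_pendant_node_scores_zero(self):
        g = _weighted_graph(
            [(0, 1, 1.0), (1, 2, 1.0), (2, 0, 1.0), (2, 3, 0.7)]
        )
        assert flow_betweenness(g)[3] == pytest.approx(0.0)

    def test_directed_ordered_pairs(self):
        g = nx.DiGraph()
        g.add_edge("A", "B", weight=0.4)
        g.add_edge("B", "C", weight=0.9)
        fb = flow_betweenness(g)
        # only A->C flow (0.4) passes through B
        assert fb["B"] == pytest.approx(0.4)


class TestCliques:
    def test_complete_graph_single_clique(self):
        rep = largest_cliques(nx.complete_graph(5))
        assert rep.largest_cliques == [frozenset(range(5))]

    def test_two_overlapping_four_cliques(self):
        g = nx.Graph()
        for clique in ([0, 1, 2, 3], [3, 4, 5, 6]):
            g.add_edges_from(itertools.combinations(clique, 2))
        rep = largest_cliques(g)
        assert rep.size == 4
        assert set(rep.largest_cliques) == {
            frozenset({0, 1, 2, 3}), frozenset({3, 4, 5, 6})
        }

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            g = nx.gnp_random_graph(8, 0.5, seed=int(rng.integers(1 << 30)))
            rep = largest_cliques(g)
            # oracle: check all subsets
            best, size = [], 0
            for r in range(1, 9):
                for sub in itertools.combinations(g.nodes, r):
                    if all(g.has_edge(a, b) for a, b in itertools.combinations(sub, 2)):
                        if r > size:
                            best, size = [frozenset(sub)], r
                        elif r == size:
                            best.append(frozenset(sub))
            assert rep.size == size
            assert set(rep.largest_cliques) == set(best)

    def test_membership_frequency_range(self):
        reports = [largest_cliques(nx.complete_graph(4)) for _ in range(7)]
        freq = membership_frequency(reports)
        assert all(v == 7 for v in freq.values())


class TestCommunities:
    def test_two_triangles_q_half(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)])
        part = louvain(g, seed=0)
        assert part.modularity == pytest.approx(0.5, abs=1e-12)
        assert {frozenset(c) for c in part.communities} == {
            frozenset({0, 1, 2}), frozenset({3, 4, 5})
        }

    def test_complete_graph_single_community_q_zero(self):
        part = louvain(nx.complete_graph(6), seed=0)
        assert len(part.communities) == 1
        assert part.modularity == pytest.approx(0.0, abs=1e-12)

    def test_q_matches_independent_modularity_evaluation(self):
        rng = np.random.default_rng(2)
        for seed in range(5):
            g = nx.gnp_random_graph(20, 0.2, seed=seed)
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.1, 2.0))
            part = louvain(g, seed=seed)
            oracle = nx.community.modularity(
                g, part.communities, weight="weight"
            )
            assert part.modularity == pytest.approx(oracle, abs=1e-12)

    def test_spinglass_two_disconnected_cliques(self):
        g = nx.Graph()
        g.add_edges_from(itertools.combinations([0, 1, 2, 3], 2))
        g.add_edges_from(itertools.combinations([4, 5, 6, 7], 2))
        part = spinglass(g, seed=0)
        assert {frozenset(c) for c in part.communities} == {
            frozenset({0, 1, 2, 3}), frozenset({4, 5, 6, 7})
        }
        oracle = nx.community.modularity(g, part.communities, weight="weight")
        assert part.modularity == pytest.approx(oracle, abs=1e-12)

    def test_spinglass_seed_reproducible(self):
        g = nx.gnp_random_graph(15, 0.3, seed=4)
        a = spinglass(g, seed=9)
        b = spinglass(g, seed=9)
        assert a.assignment == b.assignment


class TestTopology:
    def test_triangle(self):
        t = topology_summary(nx.complete_graph(3))
        assert t.density == pytest.approx(1.0)
        assert t.global_transitivity == pytest.approx(1.0)
        assert t.char_path_length == pytest.approx(1.0)

    def test_directed_reciprocity(self):
        g = nx.DiGraph()
        arcs = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0), (0, 2), (2, 4)]
        g.add_edges_from(arcs)
        g.add_edges_from([(1, 0), (9, 8)])  # one mutual pair; total 10 arcs
        g.add_node(7)
        t = topology_summary(g)
        assert g.number_of_edges() == 10
        assert t.reciprocity == pytest.approx(0.2)

    def test_disconnected_pairs_excluded_from_L(self):
        g = nx.Graph([(0, 1), (2, 3)])
        assert characteristic_path_length(g) == pytest.approx(1.0)


class TestWeightedClustering:
    def test_unit_weights_reduce_to_unweighted(self):
        g = nx.gnp_random_graph(12, 0.4, seed=8)
        for u, v in g.edges:
            g[u][v]["weight"] = 1.0
        c = weighted_clustering(g, mode="barrat_local")
        ref = nx.clustering(g)
        for node in g.nodes:
            if g.degree(node) >= 2:
                assert c[node] == pytest.approx(ref[node], abs=1e-12)
            else:
                assert np.isnan(c[node])

    def test_hand_evaluated_toy(self):
        # triangle (0,1,2) with weights 0.2/0.4/0.6 plus pendant 3
        g = _weighted_graph([(0, 1, 0.2), (1, 2, 0.4), (0, 2, 0.6), (2, 3, 0.1)])
        c = weighted_clustering(g, mode="barrat_local")
        # node 0: s=0.8, k=2; triangle term (w01+w02)/2 = 0.4, both orders
        assert c[0] == pytest.approx(2 * 0.4 / (0.8 * 1), abs=1e-12)
        # node 2: s=1.1, k=3, one triangle via (0,1): (0.6+0.4)/2 = 0.5
        assert c[2] == pytest.approx(2 * 0.5 / (1.1 * 2), abs=1e-12)
        assert np.isnan(c[3])

    def test_complete_weighted_graph_saturates(self):
        rng = np.random.default_rng(6)
        g = nx.complete_graph(6)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.1, 1.0))
        c = weighted_clustering(g, mode="barrat_local")
        np.testing.assert_allclose(c.to_numpy(), 1.0, atol=1e-12)

    def test_matches_igraph_barrat(self):
        import igraph as ig

        rng = np.random.default_rng(13)
        g = nx.gnp_random_graph(10, 0.5, seed=21)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.1, 2.0))
        c = weighted_clustering(g, mode="barrat_local")
        h = ig.Graph(n=10, edges=list(g.edges))
        ref = h.transitivity_local_undirected(
            mode="nan", weights=[g[u][v]["weight"] for u, v in g.edges]
        )
        for node in g.nodes:
            if np.isnan(c[node]):
                assert np.isnan(ref[node])
            else:
                assert c[node] == pytest.approx(ref[node], abs=1e-10)

    def test_directed_symmetric_graph_matches_barrat(self):
        # a directed graph with every arc reciprocated and symmetric
        # weights must reproduce the undirected Barrat values
        rng = np.random.default_rng(17)
        und = nx.gnp_random_graph(9, 0.5, seed=30)
        for u, v in und.edges:
            und[u][v]["weight"] = float(rng.uniform(0.1, 2.0))
        d = nx.DiGraph()
        d.add_nodes_from(und.nodes)
        for u, v, data in und.edges(data=True):
            d.add_edge(u, v, weight=data["weight"])
            d.add_edge(v, u, weight=data["weight"])
        cb = weighted_clustering(und, mode="barrat_local")
        cd = weighted_clustering(d, mode="directed_weighted")
        np.testing.assert_allclose(cd.to_numpy(), cb.to_numpy(), atol=1e-12)


class TestSmallWorld:
    def test_er_self_consistency(self):
        vals = []
        for seed in range(100):
            g = nx.gnp_random_graph(15, 0.5, seed=seed)
            if nx.is_connected(g):
                vals.append(small_world_index(g))
        assert 0.8 < np.mean(vals) < 1.2

    def test_clustered_ring_beats_rewired_ring(self):
        lattice = nx.watts_strogatz_graph(20, 4, 0.0, seed=1)
        random_g = nx.watts_strogatz_graph(20, 4, 1.0, seed=1)
        assert small_world_index(lattice) > small_world_index(random_g)

    def test_mean_degree_below_one_undefined(self):
        g = nx.Graph([(0, 1)])
        g.add_nodes_from([2, 3, 4, 5])
        assert np.isnan(small_world_index(g))
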