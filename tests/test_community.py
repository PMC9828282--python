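import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from multiplexpsn import (
    MultiplexGirvanNewman,
    Partition,
    best_partition,
    build_dendrogram,
    build_multiplex,
    departure_steps,
    edge_betweenness,
    girvan_newman_trace,
    modularity_multiplex,
    modularity_single,
    multing,
    organism_components,
    to_newick,
)
from multiplexpsn.errors import InputError, SelectionError
from multiplexpsn.synth import PlantedSpec, generate

from conftest import graph_from_edges, random_layer

TIE_TOL = 1e-9


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_edge_betweenness(nodes, edges):
    """Enumerate all shortest paths explicitly; unordered-pair counting."""
    G = nx.Graph()
    G.add_nodes_from(nodes)
    G.add_edges_from(edges)
    scores = {frozenset(e): 0.0 for e in edges}
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(G, s, t))
        except nx.NetworkXNoPath:
            continue
        for path in paths:
            for u, v in zip(path, path[1:]):
                scores[frozenset((u, v))] += 1.0 / len(paths)
    return scores


def reference_girvan_newman_order(graph):
    """Single-layer NG with networkx betweenness and the package's tie-break."""
    G = nx.Graph()
    G.add_nodes_from(range(graph.n))
    G.add_edges_from(graph.edges())
    order = []
    while G.number_of_edges():
        eb = nx.edge_betweenness_centrality(G, normalized=False)
        best = max(eb.values())
        candidates = sorted(
            tuple(sorted(e)) for e, s in eb.items() if s >= best - TIE_TOL * max(1.0, best)
        )
        e = candidates[0]
        order.append((0, e[0], e[1]))
        G.remove_edge(*e)
    return order


def global_graph_edges(m):
    """Explicit node/edge lists of the multiplex global graph."""
    nodes = [(a, i) for a in range(m.n_layers) for i in range(m.n)]
    edges = [((a, i), (a, j)) for a, i, j in m.intra_edges]
    for i in range(m.n):
        for a, b in itertools.combinations(range(m.n_layers), 2):
            edges.append(((a, i), (b, i)))
    return nodes, edges


# ---------------------------------------------------------------------------
# betweenness


class TestEdgeBetweenness:
    def test_path_graph_hand_count(self):
        g = graph_from_edges(list("abc"), [(0, 1), (1, 2)])
        eb = edge_betweenness(build_multiplex([g]))
        assert eb[(0, 0, 1)] == pytest.approx(2.0)
        assert eb[(0, 1, 2)] == pytest.approx(2.0)

    def test_bridge_has_unique_maximum(self, two_triangles_bridge):
        eb = edge_betweenness(build_multiplex([two_triangles_bridge]))
        assert max(eb, key=eb.get) == (0, 2, 3)

    def test_edgeless_graph_empty_map(self):
        g = graph_from_edges(list("ab"), [])
        eb = edge_betweenness(build_multiplex([g]))
        assert eb == {}

    @settings(deadline=None, max_examples=15)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 10), st.integers(1, 2))
    def test_matches_brute_force_on_global_graph(self, seed, n, L):
        rng = np.random.default_rng(seed)
        m = build_multiplex([random_layer(rng, n, name=f"l{a}") for a in range(L)])
        eb = edge_betweenness(m)
        nodes, edges = global_graph_edges(m)
        oracle = brute_force_edge_betweenness(nodes, edges)
        for a, i, j in m.intra_edges:
            assert eb[(a, i, j)] == pytest.approx(
                oracle[frozenset(((a, i), (a, j)))], abs=1e-9
            )


# ---------------------------------------------------------------------------
# modularity


class TestModularity:
    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 10))
    def test_single_community_partition_scores_zero(self, seed, n):
        g = random_layer(np.random.default_rng(seed), n)
        part = Partition({f"o{i}": 1 for i in range(n)})
        assert modularity_single(g, part) == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_triangles_half(self, two_disjoint_triangles):
        part = Partition({o: (1 if o in "abc" else 2) for o in "abcdef"})
        assert modularity_single(two_disjoint_triangles, part) == pytest.approx(0.5)

    def test_singleton_partition_negative_closed_form(self):
        g = graph_from_edges(list("abc"), [(0, 1), (1, 2)])
        part = Partition({"a": 1, "b": 2, "c": 3})
        k = g.adjacency.sum(axis=1)
        expected = -float((k**2).sum()) / (k.sum() ** 2)
        assert modularity_single(g, part) == pytest.approx(expected)

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 8))
    def test_multiplex_reduces_to_single_layer(self, seed, n):
        rng = np.random.default_rng(seed)
        g = random_layer(rng, n)
        m = build_multiplex([g])
        labels = {f"o{i}": int(rng.integers(1, 4)) for i in range(n)}
        part = Partition(labels)
        assert abs(
            modularity_multiplex(m, part) - modularity_single(g, part)
        ) < 1e-12

    @settings(deadline=None, max_examples=15)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 6), st.integers(1, 3))
    def test_multiplex_matches_term_by_term_sum(self, seed, n, L):
        rng = np.random.default_rng(seed)
        m = build_multiplex([random_layer(rng, n, name=f"l{a}") for a in range(L)])
        labels = {f"o{i}": int(rng.integers(1, 3)) for i in range(n)}
        part = Partition(labels)
        gamma, omega = 1.3, 0.7
        # brute-force double sum over replicas (i, alpha), (j, beta)
        total, two_mu = 0.0, 0.0
        for g in m.layers:
            A = g.adjacency.astype(float)
            k = A.sum(1)
            two_m = k.sum()
            two_mu += two_m
            for i in range(n):
                for j in range(n):
                    if labels[f"o{i}"] == labels[f"o{j}"] and two_m > 0:
                        total += A[i, j] - gamma * k[i] * k[j] / two_m
        total += omega * n * L * (L - 1)
        two_mu += omega * n * L * (L - 1)
        expected = total / two_mu if two_mu > 0 else 0.0
        assert modularity_multiplex(m, part, gamma, omega) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# the removal loop


class TestMulting:
    def test_single_layer_equals_reference_girvan_newman(self):
        rng = np.random.default_rng(42)
        for _ in range(8):
            n = int(rng.integers(4, 13))
            g = random_layer(rng, n)
            if g.n_edges == 0:
                continue
            trace = girvan_newman_trace(g)
            ref = reference_girvan_newman_order(g)
            got = [(a, int(i), int(j)) for (a, i, j) in (s.edge for s in trace.steps)]
            assert got == ref

    def test_two_layer_bridges_removed_first(self, two_triangles_bridge):
        m = build_multiplex([two_triangles_bridge, two_triangles_bridge])
        trace = multing(m)
        assert {s.edge for s in trace.steps[:2]} == {(0, 2, 3), (1, 2, 3)}
        counts = trace.community_counts()
        assert counts[0] == 1 and counts[1] == 2

    def test_community_count_non_decreasing_and_complete(self):
        rng = np.random.default_rng(7)
        m = build_multiplex([random_layer(rng, 7, name=f"l{a}") for a in range(2)])
        trace = multing(m)
        counts = trace.community_counts()
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        assert trace.complete
        assert trace.partitions[-1].n_communities == counts[-1]

    def test_planted_three_blocks_recovered(self):
        spec = PlantedSpec(
            blocks={
                "A": [f"a{i}" for i in range(5)],
                "B": [f"b{i}" for i in range(5)],
                "C": [f"c{i}" for i in range(5)],
            },
            n_layers=2,
            within=(90.0, 2.0),
            between=(40.0, 2.0),
            seed=11,
        )
        mats = generate(spec)
        est = MultiplexGirvanNewman(thresholds=60.0)
        est.fit(mats)
        got = {frozenset(c) for c in est.partition_.communities()}
        assert got == {frozenset(v) for v in spec.blocks.values()}

    def test_no_intra_edges_rejected(self):
        g = graph_from_edges(["a", "b"], [])
        with pytest.raises(InputError):
            multing(build_multiplex([g]))


class TestBestPartition:
    def test_max_q_on_two_triangles(self, two_disjoint_triangles):
        g = two_disjoint_triangles
        trace = girvan_newman_trace(g)
        part = best_partition(trace, "max_q")
        assert {frozenset(c) for c in part.communities()} == {
            frozenset("abc"),
            frozenset("def"),
        }
        assert part.modularity == pytest.approx(0.5)

    def test_before_first_event_is_initial(self, two_triangles_bridge):
        trace = girvan_newman_trace(two_triangles_bridge)
        part = best_partition(trace, "before_event", event_k=1)
        assert part.n_communities == 1

    def test_at_community_count(self, two_triangles_bridge):
        trace = girvan_newman_trace(two_triangles_bridge)
        part = best_partition(trace, "at_community_count", community_count=2)
        assert part.n_communities == 2
        with pytest.raises(SelectionError):
            best_partition(trace, "at_community_count", community_count=99)


# ---------------------------------------------------------------------------
# dendrogram


class TestDendrogram:
    def test_two_leaf_tree(self):
        g = graph_from_edges(["A", "B"], [(0, 1)])
        trace = girvan_newman_trace(g)
        d = build_dendrogram(trace)
        assert sorted(d.root.leaves()) == ["A", "B"]
        assert to_newick(d, branch_lengths=False) == "(A,B)s1;"

    def test_leaf_count_and_height_monotonicity(self):
        rng = np.random.default_rng(3)
        m = build_multiplex([random_layer(rng, 8, name=f"l{a}") for a in range(2)])
        trace = multing(m)
        d = build_dendrogram(trace)
        assert sorted(d.root.leaves()) == [f"o{i}" for i in range(8)]

        def check(node):
            for c in node.children:
                assert c.height >= node.height
                if not c.is_leaf:
                    assert c.height > node.height
                check(c)

        check(d.root)

    def test_newick_round_trip_preserves_topology(self):
        import dendropy

        rng = np.random.default_rng(9)
        m = build_multiplex([random_layer(rng, 7)])
        trace = multing(m)
        d = build_dendrogram(trace)
        nwk = to_newick(d)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == set(
            d.root.leaves()
        )
        # clades survive the round trip
        ours = {
            frozenset(node.leaves())
            for node in iter_nodes(d.root)
            if not node.is_leaf
        }
        theirs = {
            frozenset(l.taxon.label for l in nd.leaf_iter())
            for nd in tree.preorder_node_iter()
            if not nd.is_leaf()
        }
        assert ours <= theirs

    def test_support_labels_within_range(self, two_triangles_bridge):
        trace = girvan_newman_trace(two_triangles_bridge)
        d = build_dendrogram(trace)
        support = {frozenset("abc"): 97.5, frozenset("def"): 100.0}
        nwk = to_newick(d, with_support=support)
        import re

        labels = [float(x) for x in re.findall(r"\)([\d.]+):", nwk)]
        assert labels and all(0 <= x <= 100 for x in labels)

    def test_escaping_of_awkward_labels(self):
        g = graph_from_edges(["sp one", "sp(2)"], [(0, 1)])
        trace = girvan_newman_trace(g)
        nwk = to_newick(build_dendrogram(trace))
        assert "'sp one'" in nwk and "'sp(2)'" in nwk


def iter_nodes(node):
    yield node
    for c in node.children:
        yield from iter_nodes(c)


# ---------------------------------------------------------------------------
# departures


class TestDepartureSteps:
    def test_departures_match_events(self, two_triangles_bridge):
        trace = girvan_newman_trace(two_triangles_bridge)
        dep = departure_steps(trace, list("abc"))
        # the first split separates d,e,f from the a,b,c lineage
        first_event = trace.events[0]
        for o in ("d", "e", "f"):
            assert dep[o] == first_event.step


# ---------------------------------------------------------------------------
# estimator contract


class TestEstimator:
    def test_sklearn_clone_and_params(self):
        est = MultiplexGirvanNewman(gamma=1.5, stop_at_n_communities=4)
        c = clone(est)
        assert c.get_params() == est.get_params()
        assert c.get_params()["gamma"] == 1.5

    def test_fit_predict_and_determinism(self):
        spec = PlantedSpec(
            blocks={"A": ["a0", "a1", "a2"], "B": ["b0", "b1", "b2"]},
            n_layers=2,
            within=(90.0, 2.0),
            between=(35.0, 2.0),
            seed=2,
        )
        mats = generate(spec)
        l1 = MultiplexGirvanNewman(thresholds=60.0).fit_predict(mats)
        l2 = MultiplexGirvanNewman(thresholds=60.0).fit_predict(mats)
        np.testing.assert_array_equal(l1, l2)
        assert l1.shape == (6,)
        assert len(set(l1.tolist())) == 2

    def test_accepts_plain_arrays(self):
        rng = np.random.default_rng(0)
        w = np.full((4, 4), 30.0)
        w[:2, :2] = w[2:, 2:] = 90.0
        np.fill_diagonal(w, 100.0)
        est = MultiplexGirvanNewman(thresholds=60.0)
        labels = est.fit_predict([w, w])
        assert labels[0] == labels[1] != labels[2]
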