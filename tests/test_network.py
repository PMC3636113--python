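"""Correlation networks, module detection, connector splitting, fishing."""

import itertools

import networkx as nx
import numpy as np
import pytest

from coexfish.network import (
    ExpressionCompendium,
    articulation_candidates,
    build_bait_prey_network,
    build_guide_network,
    correlation_matrix,
    find_modules,
    fished_preys,
    network_summary,
    pearson,
    split_module_at_connectors,
)

from conftest import make_compendium


def pearson_oracle(x, y):
    """Covariance over the product of standard deviations, coded from scratch."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    cov = sum((a - x.mean()) * (b - y.mean()) for a, b in zip(x, y)) / n
    sx = (sum((a - x.mean()) ** 2 for a in x) / n) ** 0.5
    sy = (sum((b - y.mean()) ** 2 for b in y) / n) ** 0.5
    return cov / (sx * sy)


def threshold_oracle(compendium, genes, threshold, keep_pair):
    """Brute-force edge set: pairwise correlations filtered per pair."""
    edges = set()
    cols = compendium.values
    for a, b in itertools.combinations(genes, 2):
        if np.ptp(cols[a]) == 0 or np.ptp(cols[b]) == 0:
            continue
        if keep_pair(a, b) and pearson_oracle(cols[a], cols[b]) >= threshold:
            edges.add(frozenset((a, b)))
    return edges


def components_oracle(graph):
    """Transitive-closure component finder, independent of networkx."""
    remaining = set(graph.nodes)
    parts = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        grew = True
        while grew:
            grew = False
            for u in list(remaining):
                if any(graph.has_edge(u, v) for v in comp):
                    comp.add(u)
                    remaining.discard(u)
                    grew = True
        parts.append(frozenset(comp))
    return set(parts)


class TestPearson:
    def test_self_and_anticorrelation(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_closed_form_oracle(self):
        x, y = [1, 2, 3, 4], [2, 1, 4, 3]
        assert pearson(x, y) == pytest.approx(pearson_oracle(x, y), abs=1e-12)

    def test_zero_variance_is_nan_not_error(self):
        assert np.isnan(pearson([1, 1, 1], [1, 2, 3]))

    @pytest.mark.parametrize("x, y", [([1, 2], [3, 4]), ([1, 2, 3], [1, 2])])
    def test_bad_shapes_rejected(self, x, y):
        with pytest.raises(ValueError):
            pearson(x, y)


class TestCorrelationMatrix:
    def test_matches_pairwise_oracle(self, rng):
        comp = make_compendium({f"g{i}": rng.normal(size=12) for i in range(5)})
        corr = correlation_matrix(comp, comp.gene_ids)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)
        for a, b in itertools.combinations(comp.gene_ids, 2):
            assert corr.loc[a, b] == pytest.approx(
                pearson_oracle(comp.values[a], comp.values[b]), abs=1e-10
            )

    def test_constant_gene_flagged_undefined(self, rng):
        comp = make_compendium({"g1": rng.normal(size=10), "flat": np.ones(10)})
        corr = correlation_matrix(comp, ["g1", "flat"])
        assert corr["flat"].isna().all() and corr.loc["flat"].isna().all()
        assert corr.loc["g1", "g1"] == 1.0

    def test_missing_genes_listed(self, rng):
        comp = make_compendium({"g1": rng.normal(size=10)})
        with pytest.raises(KeyError, match="ghost"):
            correlation_matrix(comp, ["g1", "ghost"])


class TestGuideNetwork:
    def test_perfect_pair_plus_noise(self, rng):
        base = rng.normal(size=30)
        comp = make_compendium({"A": base, "B": 2 * base + 1, "C": rng.normal(size=30)})
        net = build_guide_network(comp, ["A", "B", "C"], 0.7)
        assert set(net.nodes) == {"A", "B"}
        assert net.edges["A", "B"]["r"] == pytest.approx(1.0)

    def test_threshold_boundary_inclusive(self, rng):
        # Build the network with the cutoff set to an observed correlation;
        # the >= rule must keep that pair.
        comp = make_compendium({"A": rng.normal(size=20), "B": rng.normal(size=20)})
        r = correlation_matrix(comp, ["A", "B"]).loc["A", "B"]
        net = build_guide_network(comp, ["A", "B"], threshold=float(r))
        assert net.has_edge("A", "B")

    def test_edge_set_matches_brute_force(self, rng):
        for _ in range(5):
            genes = [f"g{i}" for i in range(20)]
            shared = rng.normal(size=15)
            comp = make_compendium(
                {g: shared * rng.uniform(0, 2) + rng.normal(size=15) for g in genes}
            )
            net = build_guide_network(comp, genes, 0.7)
            expected = threshold_oracle(comp, genes, 0.7, lambda a, b: True)
            assert {frozenset(e) for e in net.edges} == expected

    def test_absolute_mode_keeps_anticorrelation(self, rng):
        base = rng.normal(size=30)
        comp = make_compendium({"A": base, "B": -base + rng.normal(size=30) * 1e-6})
        assert build_guide_network(comp, ["A", "B"], 0.7).number_of_edges() == 0
        assert build_guide_network(comp, ["A", "B"], 0.7, absolute=True).has_edge("A", "B")

    def test_every_edge_weight_reaches_threshold(self, rng):
        shared = rng.normal(size=25)
        comp = make_compendium(
            {f"g{i}": shared + rng.normal(size=25) * 0.5 for i in range(12)}
        )
        net = build_guide_network(comp, list(comp.gene_ids), 0.6)
        for _, _, data in net.edges(data=True):
            assert data["r"] >= 0.6
        assert all(d > 0 for _, d in net.degree)

    def test_empty_guides_and_short_compendium_rejected(self, rng):
        comp = make_compendium({"g": rng.normal(size=10)})
        with pytest.raises(ValueError, match="empty"):
            build_guide_network(comp, [], 0.7)
        short = make_compendium({"g": np.array([1.0, 2.0])})
        with pytest.raises(ValueError, match="3 compendium samples"):
            build_guide_network(short, ["g"], 0.7)

    def test_absent_guides_dropped_not_fatal(self, rng):
        base = rng.normal(size=20)
        comp = make_compendium({"A": base, "B": base + rng.normal(size=20) * 0.1})
        net = build_guide_network(comp, ["A", "B", "ghost"], 0.7)
        assert set(net.nodes) == {"A", "B"}


class TestModules:
    def test_empty_network(self):
        assert find_modules(nx.Graph()) == []

    def test_path_plus_pair(self):
        graph = nx.Graph([("a", "b"), ("b", "c"), ("d", "e")])
        assert find_modules(graph) == [{"a", "b", "c"}, {"d", "e"}]

    def test_ordering_size_then_smallest_member(self):
        graph = nx.Graph([("x", "y"), ("a", "b")])
        assert find_modules(graph) == [{"a", "b"}, {"x", "y"}]

    def test_matches_transitive_closure_oracle(self, rng):
        for _ in range(10):
            graph = nx.gnp_random_graph(50, 0.05, seed=int(rng.integers(2**31)))
            expected = components_oracle(graph)
            assert {frozenset(m) for m in find_modules(graph)} == expected

    def test_no_cross_module_edges(self, rng):
        graph = nx.gnp_random_graph(40, 0.08, seed=7)
        modules = find_modules(graph)
        for m1, m2 in itertools.combinations(modules, 2):
            assert not any(graph.has_edge(u, v) for u in m1 for v in m2)

    def test_module_count_non_increasing_as_threshold_drops(self, rng):
        shared = rng.normal(size=40)
        comp = make_compendium(
            {f"g{i}": shared * rng.uniform(0.3, 1.5) + rng.normal(size=40) for i in range(15)}
        )
        genes = list(comp.gene_ids)
        counts = []
        for threshold in (0.9, 0.7, 0.5, 0.3):
            net = build_guide_network(comp, genes, threshold)
            # count modules over the full candidate set: isolated guides are
            # singleton clusters for the purpose of this monotonicity check
            counts.append(len(find_modules(net)) + (len(genes) - net.number_of_nodes()))
        assert counts == sorted(counts, reverse=True)


class TestConnectorSplitting:
    def test_path_split_at_middle(self):
        graph = nx.Graph([("a", "b"), ("b", "c")])
        parts, connectors = split_module_at_connectors(graph, {"a", "b", "c"}, {"b"})
        assert parts == [{"a"}, {"c"}] and connectors == ["b"]

    def test_clique_has_no_candidates_and_splits_trivially(self):
        graph = nx.complete_graph(["a", "b", "c", "d"])
        module = set(graph.nodes)
        assert articulation_candidates(graph, module) == []
        parts, connectors = split_module_at_connectors(graph, module, set())
        assert parts == [module] and connectors == []

    def test_connector_outside_module_rejected(self):
        graph = nx.Graph([("a", "b")])
        with pytest.raises(ValueError, match="not in module"):
            split_module_at_connectors(graph, {"a", "b"}, {"z"})

    def test_articulation_points_match_removal_oracle(self, rng):
        for _ in range(15):
            graph = nx.gnp_random_graph(int(rng.integers(4, 13)), 0.35,
                                        seed=int(rng.integers(2**31)))
            for module in find_modules(graph):
                sub = graph.subgraph(module)
                expected = sorted(
                    v for v in module
                    if len(components_oracle(sub.subgraph(module - {v}))) > 1
                ) if len(module) > 1 else []
                assert articulation_candidates(graph, module) == expected


class TestBaitPreyNetwork:
    def test_toy_fishing(self, rng):
        base = rng.normal(size=30)
        comp = make_compendium({"B": base, "P1": base * 2, "P2": base + 5})
        net = build_bait_prey_network(comp, ["B"], ["P1", "P2"], 0.7)
        assert {frozenset(e) for e in net.edges} == {frozenset(("B", "P1")),
                                                     frozenset(("B", "P2"))}
        assert fished_preys(net) == ["P1", "P2"]
        summary = network_summary(net)
        assert summary["n_nodes"] == 3 and summary["n_edges"] == 2

    def test_prey_correlated_only_with_preys_excluded(self, rng):
        base = rng.normal(size=30)
        other = rng.normal(size=30)
        comp = make_compendium({"B": base, "P1": other, "P2": other * 3 + 1})
        net = build_bait_prey_network(comp, ["B"], ["P1", "P2"], 0.7)
        assert net.number_of_nodes() == 0

    def test_overlap_resolved_to_bait(self, rng):
        base = rng.normal(size=30)
        comp = make_compendium({"X": base, "Y": base * 2})
        net = build_bait_prey_network(comp, ["X"], ["X", "Y"], 0.7)
        assert net.nodes["X"]["role"] == "bait"

    def test_empty_baits_rejected(self, rng):
        comp = make_compendium({"g": rng.normal(size=10)})
        with pytest.raises(ValueError, match="bait list is empty"):
            build_bait_prey_network(comp, [], ["g"], 0.7)

    def test_edge_set_matches_brute_force(self, rng):
        for _ in range(5):
            baits = [f"b{i}" for i in range(4)]
            preys = [f"p{i}" for i in range(8)]
            shared = rng.normal(size=20)
            comp = make_compendium(
                {g: shared * rng.uniform(0, 1.5) + rng.normal(size=20)
                 for g in baits + preys}
            )
            net = build_bait_prey_network(comp, baits, preys, 0.7)
            bait_set = set(baits)
            expected = threshold_oracle(
                comp, baits + preys, 0.7,
                lambda a, b: a in bait_set or b in bait_set,
            )
            assert {frozenset(e) for e in net.edges} == expected

    def test_node_count_identity(self, rng):
        shared = rng.normal(size=25)
        comp = make_compendium(
            {f"g{i}": shared * rng.uniform(0, 1.5) + rng.normal(size=25) for i in range(15)}
        )
        genes = list(comp.gene_ids)
        net = build_bait_prey_network(comp, genes[:5], genes[5:], 0.7)
        summary = network_summary(net)
        assert summary["n_nodes"] == summary["nodes_by_role"].get("bait", 0) + len(fished_preys(net))


def test_network_summary_empty():
    summary = network_summary(nx.Graph())
    assert summary == {"n_nodes": 0, "n_edges": 0, "nodes_by_role": {},
                       "degree": {}, "n_modules": 0}
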