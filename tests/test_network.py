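"""Phenotype-sharing graph construction and betweenness ranking."""

import itertools

import networkx as nx
import pytest

from genepheno.association import AssociationRecord
from genepheno.network import (betweenness_centrality, build_graph,
                               global_average_npmi, subset_by_phenotype_keyword,
                               top_fraction)
from genepheno.standardize import StandardizedPhenotype


def record(gene, cid, value, name=None):
    return AssociationRecord(
        gene=gene,
        phenotype=StandardizedPhenotype(concept_id=cid,
                                        preferred_name=name or cid,
                                        source="HPO"),
        n_G=20, n_P=20, n_GP=10, n_tot=1000, npmi=value,
    )


class TestGlobalAverage:
    def test_mean_of_two(self):
        assert global_average_npmi([record("A", "P", 0.2),
                                    record("B", "P", 0.4)]) == pytest.approx(0.3)

    def test_single_record(self):
        assert global_average_npmi([record("A", "P", 0.7)]) == 0.7

    def test_seven_record_hand_sum(self):
        vals = [0.1, 0.2, 0.3, 0.15, 0.45, 0.05, 0.6]
        recs = [record("A", f"P{i}", v) for i, v in enumerate(vals)]
        assert global_average_npmi(recs) == pytest.approx(sum(vals) / 7)

    def test_positive_only_flag(self):
        recs = [record("A", "P1", -0.5), record("A", "P2", 0.5)]
        assert global_average_npmi(recs) == 0.0
        assert global_average_npmi(recs, positive_only=True) == 0.5

    def test_empty_fatal(self):
        with pytest.raises(ValueError):
            global_average_npmi([])


class TestBuildGraph:
    def test_shared_phenotypes_compress_to_weight(self):
        recs = [record(g, p, 0.5) for g in ("G1", "G2") for p in ("P1", "P2", "P3")]
        graph = build_graph(recs, ["G1", "G2"], threshold=0.3)
        assert graph.number_of_edges() == 1
        assert graph["G1"]["G2"]["weight"] == 3

    def test_phenotype_qualifying_for_one_gene_only_makes_no_edge(self):
        recs = [record("G1", "P1", 0.5), record("G2", "P1", 0.1)]
        graph = build_graph(recs, ["G1", "G2"], threshold=0.3)
        assert graph.number_of_edges() == 0

    def test_threshold_is_inclusive(self):
        recs = [record("G1", "P1", 0.3), record("G2", "P1", 0.3)]
        assert build_graph(recs, ["G1", "G2"], 0.3).number_of_edges() == 1

    def test_three_genes_sharing_one_phenotype_form_triangle(self):
        recs = [record(g, "P1", 0.5) for g in ("G1", "G2", "G3")]
        graph = build_graph(recs, ["G1", "G2", "G3"], 0.2)
        assert graph.number_of_edges() == 3
        assert all(d["weight"] == 1 for _, _, d in graph.edges(data=True))

    def test_record_order_does_not_change_graph(self):
        recs = [record(g, p, 0.5) for g in ("G1", "G2", "G3") for p in ("P1", "P2")]
        g1 = build_graph(recs, ["G1", "G2", "G3"], 0.2)
        g2 = build_graph(list(reversed(recs)), ["G1", "G2", "G3"], 0.2)
        assert nx.utils.graphs_equal(g1, g2)

    def test_nodes_restricted_but_isolated_nodes_kept(self):
        recs = [record("G1", "P1", 0.5), record("GX", "P1", 0.5)]
        graph = build_graph(recs, ["G1", "G2"], 0.2)
        assert set(graph) == {"G1", "G2"}
        assert graph.number_of_edges() == 0


# ---------------------------------------------------------------------------
# Exhaustive shortest-path enumeration oracle (independent of networkx)
# ---------------------------------------------------------------------------

def _all_simple_paths(adj, s, t):
    paths = []

    def walk(node, seen, path):
        if node == t:
            paths.append(list(path))
            return
        for nbr in sorted(adj[node]):
            if nbr not in seen:
                walk(nbr, seen | {nbr}, path + [nbr])

    walk(s, {s}, [s])
    return paths


def brute_betweenness(graph, lengths=None):
    """Sum over pairs of fraction of shortest paths through each node."""
    adj = {v: set(graph[v]) for v in graph}
    scores = {v: 0.0 for v in graph}
    for s, t in itertools.combinations(sorted(graph), 2):
        paths = _all_simple_paths(adj, s, t)
        if not paths:
            continue

        def plen(p):
            if lengths is None:
                return len(p) - 1
            return sum(lengths[frozenset((a, b))] for a, b in zip(p, p[1:]))

        best = min(plen(p) for p in paths)
        shortest = [p for p in paths if abs(plen(p) - best) < 1e-9]
        for v in graph:
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            scores[v] += through / len(shortest)
    return scores


def random_graph(seed, n, p):
    import random
    rng = random.Random(seed)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p:
            g.add_edge(i, j, weight=rng.randint(1, 4))
    return g


class TestBetweenness:
    def test_path_graph_center_scores_one(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        nx.set_edge_attributes(g, 1, "weight")
        scores = betweenness_centrality(g)
        assert scores == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_star_center_counts_all_leaf_pairs(self):
        g = nx.star_graph(3)  # center 0, three leaves
        nx.set_edge_attributes(g, 1, "weight")
        scores = betweenness_centrality(g)
        assert scores[0] == 3.0
        assert all(scores[leaf] == 0.0 for leaf in (1, 2, 3))

    def test_complete_graph_all_zero(self):
        g = nx.complete_graph(4)
        nx.set_edge_attributes(g, 1, "weight")
        assert set(betweenness_centrality(g).values()) == {0.0}

    @pytest.mark.parametrize("seed,n,p", [(0, 6, 0.4), (1, 8, 0.3), (2, 10, 0.3),
                                          (3, 12, 0.25), (4, 9, 0.5)])
    def test_unweighted_matches_path_enumeration_oracle(self, seed, n, p):
        g = random_graph(seed, n, p)
        oracle = brute_betweenness(g)
        got = betweenness_centrality(g, weighted=False)
        for v in g:
            assert got[v] == pytest.approx(oracle[v], abs=1e-9)

    @pytest.mark.parametrize("seed,n,p", [(5, 6, 0.5), (6, 8, 0.35), (7, 10, 0.3),
                                          (8, 12, 0.25)])
    def test_weighted_matches_oracle_with_inverse_weight_lengths(self, seed, n, p):
        g = random_graph(seed, n, p)
        lengths = {frozenset((a, b)): 1.0 / d["weight"]
                   for a, b, d in g.edges(data=True)}
        oracle = brute_betweenness(g, lengths)
        got = betweenness_centrality(g, weighted=True)
        for v in g:
            assert got[v] == pytest.approx(oracle[v], abs=1e-9)

    def test_disconnected_pairs_contribute_zero(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("x", "y")])
        nx.set_edge_attributes(g, 1, "weight")
        scores = betweenness_centrality(g)
        assert scores["b"] == 1.0 and scores["x"] == 0.0


class TestTopFraction:
    def test_ceil_selection(self):
        scores = {f"G{i:03d}": float(600 - i) for i in range(600)}
        assert len(top_fraction(scores, 0.10)) == 60

    def test_fraction_one_selects_all(self):
        scores = {"A": 1.0, "B": 0.5}
        assert set(top_fraction(scores, 1.0)) == {"A", "B"}

    def test_selection_matches_sort_oracle(self):
        import random
        rng = random.Random(3)
        scores = {f"G{i}": rng.random() for i in range(37)}
        oracle = [g for g, _ in sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))]
        assert top_fraction(scores, 0.25) == oracle[:10]  # ceil(9.25)

    def test_tie_at_cut_broken_by_symbol(self):
        scores = {"B": 1.0, "A": 1.0, "C": 2.0}
        assert top_fraction(scores, 0.5) == ["C", "A"]  # ceil(1.5) = 2


class TestKeywordSubset:
    def test_keyword_filters_and_induces_graph(self):
        recs = [
            record("G1", "P1", 0.5, name="Language impairment"),
            record("G2", "P1", 0.5, name="Language impairment"),
            record("G3", "P2", 0.5, name="Specific language disorder"),
            record("G3", "P3", 0.5, name="Seizure"),
        ]
        subset, graph = subset_by_phenotype_keyword(recs, ["language"], threshold=0.0)
        assert {r.phenotype.concept_id for r in subset} == {"P1", "P2"}
        assert set(graph) == {"G1", "G2"}

    def test_no_match_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            subset, graph = subset_by_phenotype_keyword(
                [record("G1", "P1", 0.5, name="Seizure")], ["xyz"], 0.0)
        assert subset == [] and graph.number_of_nodes() == 0

    def test_empty_keywords_fatal(self):
        with pytest.raises(ValueError):
            subset_by_phenotype_keyword([], [], 0.0)
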