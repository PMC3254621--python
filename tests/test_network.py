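"""High-confidence network filtering and degree-preserving prioritization:
filter rules, swap-chain invariants, enumeration-exact null probabilities,
and BH adjustment."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from _oracles import bh_stepup, exact_null_probs
from qtlspan import (
    CandidateSets,
    cross_locus_subgraph,
    edge_priority,
    fdr_adjust,
    filter_string_edges,
    node_priority,
    prioritize,
    randomize_network,
)
from qtlspan.network import NetworkError, STRING_CHANNELS


def _records(rows):
    cols = ["protein1", "protein2", *STRING_CHANNELS, "combined_score"]
    return pd.DataFrame(rows, columns=cols)


def _row(u, v, combined, **channels):
    scores = {c: 0 for c in STRING_CHANNELS}
    scores.update(channels)
    return [u, v, *[scores[c] for c in STRING_CHANNELS], combined]


class TestFilterStringEdges:
    def test_experimental_evidence_above_cutoff_retained(self):
        g = filter_string_edges(_records([_row("a", "b", 900, experimental=400)]))
        assert g.has_edge("a", "b")

    def test_pure_textmining_removed(self):
        g = filter_string_edges(_records([_row("a", "b", 950, textmining=950)]))
        assert g.number_of_edges() == 0

    def test_combined_exactly_at_cutoff_removed(self):
        g = filter_string_edges(_records([_row("a", "b", 800, database=500)]))
        assert g.number_of_edges() == 0

    def test_duplicate_orientations_merged_by_max(self):
        recs = _records(
            [
                _row("a", "b", 850, experimental=300),
                _row("b", "a", 900, database=200),
            ]
        )
        g = filter_string_edges(recs)
        assert g.number_of_edges() == 1
        d = g.edges["a", "b"]
        assert d["combined_score"] == 900
        assert d["experimental"] == 300 and d["database"] == 200

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        rows = []
        for k in range(40):
            rows.append(
                _row(
                    f"p{rng.integers(0, 15)}", f"p{rng.integers(0, 15)}",
                    int(rng.integers(500, 1001)),
                    experimental=int(rng.integers(0, 800)),
                    textmining=int(rng.integers(0, 800)),
                )
            )
        first = filter_string_edges(_records(rows))
        back = _records(
            [
                _row(u, v, d["combined_score"], **{c: d.get(c, 0) for c in STRING_CHANNELS})
                for u, v, d in first.edges(data=True)
            ]
        )
        second = filter_string_edges(back)
        assert set(map(frozenset, first.edges())) == set(map(frozenset, second.edges()))


class TestCrossLocusSubgraph:
    def test_toy_graph_exhaustive(self):
        g = nx.Graph()
        edges = [("a1", "b1"), ("a2", "b2"), ("a1", "a2"), ("b1", "b2"), ("a1", "c")]
        g.add_edges_from(edges)
        sets = CandidateSets({"a1", "a2"}, {"b1", "b2"})
        got = cross_locus_subgraph(g, sets)
        expected = sorted(
            (u, v)
            for u, v in itertools.product(sets.set_a, sets.set_b)
            if g.has_edge(u, v)
        )
        assert got == expected == [("a1", "b1"), ("a2", "b2")]

    def test_disjoint_sets_enforced(self):
        with pytest.raises(NetworkError):
            CandidateSets({"a"}, {"a", "b"})

    def test_absent_members_give_empty(self):
        g = nx.Graph([("x", "y")])
        assert cross_locus_subgraph(g, CandidateSets({"a"}, {"b"})) == []


class TestRandomizeNetwork:
    def test_triangle_is_rigid(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        out = randomize_network(g, seed=0)
        assert set(map(frozenset, out.edges())) == set(map(frozenset, g.edges()))

    @pytest.mark.parametrize("seed", range(5))
    def test_degree_sequence_and_simplicity_conserved(self, seed):
        g = nx.gnm_random_graph(30, 60, seed=seed)
        out = randomize_network(g, seed=seed)
        assert dict(out.degree()) == dict(g.degree())
        assert out.number_of_edges() == g.number_of_edges()
        assert not any(u == v for u, v in out.edges())

    def test_two_edge_matching_uniform_over_configurations(self):
        # degree-1 nodes a,b,c,d: the 3 perfect matchings each have mass 1/3
        g = nx.Graph([("a", "b"), ("c", "d")])
        counts = {}
        for seed in range(3000):
            out = randomize_network(g, seed=seed)
            key = frozenset(map(frozenset, out.edges()))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 3
        for c in counts.values():
            assert abs(c / 3000 - 1 / 3) < 0.03


class TestPriorities:
    def test_zero_cross_degree_gives_p_one(self):
        g = nx.Graph([("a", "x"), ("b", "y")])
        res = node_priority(g, CandidateSets({"a"}, {"b"}), n_rand=50, seed=0)
        assert (res["observed_cross_degree"] == 0).all()
        assert (res["p_value"] == 1.0).all()

    def test_rigid_triangle_p_one(self):
        g = nx.Graph([("a", "b"), ("a", "c"), ("b", "c")])
        sets = CandidateSets({"a"}, {"b", "c"})
        nodes = node_priority(g, sets, n_rand=100, seed=1)
        edges = edge_priority(g, sets, n_rand=100, seed=1)
        assert (nodes["p_value"] == 1.0).all()
        assert (edges["p_value"] == 1.0).all()

    def test_matching_edge_probability_one_third(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        sets = CandidateSets({"a"}, {"b"})
        n_rand = 3000
        edges = edge_priority(g, sets, n_rand=n_rand, seed=2)
        assert len(edges) == 1
        p = float(edges["p_value"].iloc[0])
        se = np.sqrt((1 / 3) * (2 / 3) / n_rand)
        assert abs(p - 1 / 3) < 3 * se
        nodes = node_priority(g, sets, n_rand=n_rand, seed=2)
        pa = float(nodes.loc[nodes["protein"] == "a", "p_value"].iloc[0])
        assert abs(pa - 1 / 3) < 3 * se

    def test_absent_protein_reported_with_p_one(self):
        g = nx.Graph([("a", "b")])
        res = node_priority(g, CandidateSets({"a", "ghost"}, {"b"}), n_rand=20, seed=0)
        row = res[res["protein"] == "ghost"].iloc[0]
        assert row["observed_cross_degree"] == 0 and row["p_value"] == 1.0

    def test_pvalues_match_exhaustive_enumeration(self):
        # 6-node graph with a flexible degree sequence
        edge_list = [
            ("u1", "v1"), ("u1", "w1"), ("u2", "w2"), ("v2", "w1"), ("w1", "w2"),
        ]
        g = nx.Graph(edge_list)
        set_a, set_b = {"u1", "u2"}, {"v1", "v2"}
        node_p, edge_p, n_graphs = exact_null_probs(
            list(g.nodes()), {frozenset(e) for e in edge_list}, set_a, set_b
        )
        assert n_graphs > 1
        n_rand = 5000
        sets = CandidateSets(set_a, set_b)
        nodes = node_priority(g, sets, n_rand=n_rand, seed=3)
        edges = edge_priority(g, sets, n_rand=n_rand, seed=3)
        for protein, exact in node_p.items():
            got = float(nodes.loc[nodes["protein"] == protein, "p_value"].iloc[0])
            se = np.sqrt(max(exact * (1 - exact), 1e-9) / n_rand)
            assert abs(got - exact) < 3 * se + 1 / n_rand
        for e, exact in edge_p.items():
            u, v = sorted(e)
            hit = edges[
                ((edges["protein_a"] == u) & (edges["protein_b"] == v))
                | ((edges["protein_a"] == v) & (edges["protein_b"] == u))
            ]
            got = float(hit["p_value"].iloc[0])
            se = np.sqrt(max(exact * (1 - exact), 1e-9) / n_rand)
            assert abs(got - exact) < 3 * se + 1 / n_rand


class TestFdrAdjust:
    def test_single_p(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_worked_stepup_example(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_hand_stepup_and_dominates_p(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1.0, size=25)
        q = fdr_adjust(p)
        np.testing.assert_allclose(q, bh_stepup(p), atol=1e-12)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        hst.lists(
            hst.floats(min_value=1e-9, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=40,
        )
    )
    def test_stepup_property_holds_for_arbitrary_p_vectors(self, p):
        q = fdr_adjust(p)
        np.testing.assert_allclose(q, bh_stepup(np.asarray(p)), atol=1e-12)
        assert (q <= 1.0 + 1e-12).all()

    def test_empty_and_invalid(self):
        assert len(fdr_adjust([])) == 0
        with pytest.raises(NetworkError):
            fdr_adjust([0.0, 0.5])


class TestPrioritize:
    def test_all_isolated_proteins_get_q_one(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b", "x", "y"])
        g.add_edge("x", "y")
        res = prioritize(g, CandidateSets({"a"}, {"b"}), n_rand=20, seed=0)
        assert (res.nodes["p_value"] == 1.0).all()
        assert (res.nodes["q_value"] == 1.0).all()
        assert res.edges.empty and res.strong_edges == ()

    def test_planted_dense_pair_tops_both_families(self):
        rng = np.random.default_rng(4)
        g = nx.gnm_random_graph(40, 120, seed=5)
        g = nx.relabel_nodes(g, {i: f"bg{i}" for i in range(40)})
        # planted pair: all their edges are cross-locus
        g.add_edge("pa", "pb")
        g.add_edge("pa", "pb2")
        g.add_edge("pa2", "pb")
        # decoy cross edge hanging off two hubs
        hubs = sorted(g.degree(), key=lambda t: -t[1])[:2]
        g.add_edge("da", "db")
        for h, _ in hubs:
            g.add_edge("da", h)
            g.add_edge("db", h)
        sets = CandidateSets({"pa", "pa2", "da"}, {"pb", "pb2", "db"})
        res = prioritize(g, sets, n_rand=400, seed=6)
        nodes = res.nodes.set_index("protein")
        edges = res.edges
        decoy_q = float(
            edges.loc[(edges["protein_a"] == "da") & (edges["protein_b"] == "db"),
                      "q_value"].iloc[0]
        )
        planted_q = edges.loc[edges["protein_a"] == "pa", "q_value"]
        assert planted_q.max() <= decoy_q
        assert nodes.loc["pa", "q_value"] <= nodes.loc["da", "q_value"]

    def test_q_never_below_p_and_never_zero(self):
        g = nx.gnm_random_graph(20, 40, seed=7)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(20)})
        sets = CandidateSets({"n0", "n1", "n2"}, {"n3", "n4", "n5"})
        res = prioritize(g, sets, n_rand=50, seed=8)
        for table in (res.nodes, res.edges):
            if len(table):
                assert (table["p_value"] > 0).all()
                assert (table["q_value"] >= table["p_value"] - 1e-12).all()
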