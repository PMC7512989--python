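"""Coupled similarity stack: value-pair primitives, node-pair measures,
the two-phase matrix driver, and the closed-form/enumeration equivalence."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cnsnet import (
    AttributedGraph,
    attribute_structure_similarity,
    baseline_similarity,
    build_value_pair_table,
    cas,
    cns,
    coupled_attribute_value_similarity,
    icp,
    inter_attribute_similarity,
    inter_relative_similarity,
    intra_attribute_similarity,
    similarity_matrix,
)
from conftest import brute_force_inter_relative, random_attributed_graph


class TestIntraAttribute:
    @pytest.mark.parametrize(
        "m,x,y,expected",
        [
            ("country", "AU", "CN", 6 / 11),
            ("topic", "DM", "DM", 5 / 7),  # 25 / (5 + 5 + 25)
            ("country", "AU", "US", 1 / 2),
        ],
    )
    def test_toy_values(self, toy, m, x, y, expected):
        assert intra_attribute_similarity(toy, m, x, y) == pytest.approx(expected)

    def test_singleton_pair_attains_minimum_third(self):
        g = AttributedGraph(
            nx.Graph([("a", "b")]), pd.DataFrame({"m": ["x", "y"]}, index=["a", "b"])
        )
        assert intra_attribute_similarity(g, "m", "x", "y") == pytest.approx(1 / 3)

    def test_unknown_value_rejected(self, toy):
        with pytest.raises(KeyError):
            intra_attribute_similarity(toy, "country", "AU", "XX")


class TestICP:
    def test_toy_values(self, toy):
        assert icp(toy, "topic", "country", {"DM"}, "AU") == pytest.approx(1.0)
        assert icp(toy, "topic", "country", {"ML"}, "CN") == pytest.approx(1 / 3)

    def test_boundary_subsets(self, toy):
        assert icp(toy, "topic", "country", frozenset(), "AU") == 0.0
        assert icp(toy, "topic", "country", {"DM", "ML"}, "CN") == 1.0

    def test_monotone_in_subset(self, toy):
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = random_attributed_graph(rng)
            m, n = g.attribute_names[:2]
            domain = g.domain(n)
            x = g.domain(m)[0]
            vals = [
                icp(g, n, m, frozenset(domain[:r]), x) for r in range(len(domain) + 1)
            ]
            assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))


class TestInterRelative:
    def test_toy_values(self, toy):
        assert inter_relative_similarity(toy, "country", "topic", "AU", "CN") == (
            pytest.approx(2 / 3)
        )
        assert inter_relative_similarity(toy, "country", "topic", "AU", "US") == (
            pytest.approx(0.5)
        )

    def test_matched_values_give_one(self, toy):
        for m, n in [("country", "topic"), ("topic", "country")]:
            for x in toy.domain(m):
                assert inter_relative_similarity(toy, m, n, x, x) == pytest.approx(1.0)

    def test_same_attribute_rejected(self, toy):
        with pytest.raises(ValueError):
            inter_relative_similarity(toy, "country", "country", "AU", "CN")

    def test_closed_form_equals_subset_enumeration(self):
        """The O(|Fn|) closed form must match exhaustive minimisation."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            g = random_attributed_graph(rng, max_domain=5)
            m, n = rng.permutation(g.attribute_names)[:2]
            xs = g.domain(m)
            x, y = xs[int(rng.integers(len(xs)))], xs[int(rng.integers(len(xs)))]
            fast = inter_relative_similarity(g, m, n, x, y)
            slow = brute_force_inter_relative(g, m, n, x, y)
            assert fast == pytest.approx(slow, abs=1e-12)


class TestInterAndCoupled:
    def test_toy_inter_attribute(self, toy):
        assert inter_attribute_similarity(toy, "country", "AU", "CN") == (
            pytest.approx(2 / 3)
        )
        assert inter_attribute_similarity(toy, "country", "AU", "US") == (
            pytest.approx(0.5)
        )

    def test_alpha_scheme_all_uniform_halves_m2(self, toy):
        # with M=2, all-uniform weights 1/2 instead of 1
        assert inter_attribute_similarity(
            toy, "country", "AU", "CN", "all-uniform"
        ) == pytest.approx(1 / 3)

    def test_single_attribute_defined_as_one(self):
        g = AttributedGraph(
            nx.Graph([("a", "b")]), pd.DataFrame({"m": ["x", "y"]}, index=["a", "b"])
        )
        assert inter_attribute_similarity(g, "m", "x", "y") == 1.0

    @pytest.mark.parametrize(
        "m,x,y,expected",
        [("country", "AU", "CN", 6 / 11 * 2 / 3), ("topic", "DM", "DM", 5 / 7)],
    )
    def test_coupled_value_similarity_is_product(self, toy, m, x, y, expected):
        assert coupled_attribute_value_similarity(toy, m, x, y) == pytest.approx(expected)


class TestStructureSimilarity:
    def test_toy_cross_country(self, toy):
        assert attribute_structure_similarity(toy, "country", "AU", "CN") == 0.5

    def test_matched_value_counts_internal_edges_twice(self, toy):
        # 4 edges among the 5 DM authors -> 8 ordered pairs over 25
        assert attribute_structure_similarity(toy, "topic", "DM", "DM") == 8 / 25

    def test_no_cross_edges_gives_zero(self, toy):
        # David(US) and Hua(CN) are the only ML authors and are not linked
        assert attribute_structure_similarity(toy, "topic", "ML", "ML") == 0.0


class TestNodeSimilarities:
    def test_cas_toy(self, toy):
        assert cas(toy, "George", "Ying") == pytest.approx(83 / 77)

    def test_cns_printed_values(self, toy):
        assert round(cns(toy, "George", "Ying"), 2) == 0.41
        assert round(cns(toy, "George", "Jones"), 2) == 0.29
        assert cns(toy, "George", "Ying") == pytest.approx(158 / 385)

    def test_george_more_similar_to_ying_than_jones(self, toy):
        assert cns(toy, "George", "Ying") > cns(toy, "George", "Jones")

    def test_variants_cover_combinations(self, toy):
        # for each attribute the three factors are in [0,1], so
        # cns1 <= cns2/cns3 <= cns4 pairwise where algebra guarantees it
        v = {k: cns(toy, "George", "Ying", variant=k) for k in
             ("cns1", "cns2", "cns3", "cns4")}
        assert v["cns1"] <= v["cns2"] + 1e-12
        assert v["cns1"] <= v["cns3"] + 1e-12
        assert v["cns3"] <= v["cns4"] + 1e-12
        with pytest.raises(ValueError):
            cns(toy, "George", "Ying", variant="cns5")

    def test_symmetry_all_pairs_all_variants(self, toy):
        for i, j in itertools.combinations(toy.nodes, 2):
            for variant in ("cns1", "cns2", "cns3", "cns4"):
                assert cns(toy, i, j, variant) == pytest.approx(cns(toy, j, i, variant))
            assert cas(toy, i, j) == pytest.approx(cas(toy, j, i))

    @pytest.mark.parametrize(
        "kind,i,j,expected",
        [
            ("smc", "George", "Ying", 0.5),
            ("smc", "George", "Pitt", 1.0),
            ("adjacency", "George", "Pitt", 0.0),
            ("adjacency", "George", "Ying", 1.0),
            ("jaccard", "David", "Jia", 1 / 3),
        ],
    )
    def test_baselines_on_toy(self, toy, kind, i, j, expected):
        assert baseline_similarity(toy, i, j, kind) == pytest.approx(expected)

    def test_jaccard_of_identical_neighborhoods_is_one(self):
        g = AttributedGraph(
            nx.Graph([("a", "c"), ("b", "c")]),
            pd.DataFrame({"m": ["x", "x", "y"]}, index=["a", "b", "c"]),
        )
        assert baseline_similarity(g, "a", "b", "jaccard") == 1.0

    def test_isolated_node_cosine_jaccard_zero(self):
        g = AttributedGraph(
            nx.Graph([("a", "b")]),
            pd.DataFrame({"m": ["x", "y", "z"]}, index=["a", "b", "c"]),
        )
        assert baseline_similarity(g, "a", "c", "cosine") == 0.0
        assert baseline_similarity(g, "a", "c", "jaccard") == 0.0


class TestValuePairTable:
    def test_table_invariants(self, toy):
        for m in toy.attribute_names:
            t = build_value_pair_table(toy, m)
            for arr in (t.delta_intra, t.delta_inter, t.delta_attr, t.delta_struct):
                assert np.allclose(arr, arr.T)
            assert np.allclose(t.delta_attr, t.delta_intra * t.delta_inter)
            assert (t.delta_intra >= 1 / 3 - 1e-12).all() and (t.delta_intra < 1).all()
            assert (t.delta_inter >= -1e-12).all() and (t.delta_inter <= 1 + 1e-12).all()
            assert (t.delta_struct >= 0).all() and (t.delta_struct <= 1 + 1e-12).all()
            assert np.allclose(np.diag(t.delta_inter), 1.0)

    def test_table_matches_scalar_primitives(self, toy):
        rng = np.random.default_rng(7)
        for _ in range(10):
            g = random_attributed_graph(rng, n_attrs=3)
            m = g.attribute_names[int(rng.integers(3))]
            t = build_value_pair_table(g, m)
            for a, x in enumerate(t.values):
                for b, y in enumerate(t.values):
                    assert t.delta_intra[a, b] == pytest.approx(
                        intra_attribute_similarity(g, m, x, y)
                    )
                    assert t.delta_inter[a, b] == pytest.approx(
                        inter_attribute_similarity(g, m, x, y)
                    )
                    assert t.delta_struct[a, b] == pytest.approx(
                        attribute_structure_similarity(g, m, x, y)
                    )


class TestSimilarityMatrix:
    def test_cns_matrix_matches_pairwise_on_edges(self, toy):
        s = similarity_matrix(toy, "cns1")
        idx = {u: a for a, u in enumerate(s.nodes)}
        nonzero = 0
        for u, v in toy.edges():
            assert s.matrix[idx[u], idx[v]] == pytest.approx(cns(toy, u, v))
            nonzero += s.matrix[idx[u], idx[v]] != 0
        assert nonzero == 8
        assert np.count_nonzero(s.matrix) == 16  # symmetric pairs only

    def test_adjacency_matrix(self, toy):
        s = similarity_matrix(toy, "adjacency")
        assert s.matrix.sum() == 16
        assert np.allclose(s.matrix, s.matrix.T)

    def test_empty_edge_graph_gives_zero_cns(self):
        g = AttributedGraph(
            nx.empty_graph(0),
            pd.DataFrame({"m": ["x", "y", "x"]}, index=["a", "b", "c"]),
        )
        assert similarity_matrix(g, "cns1").matrix.sum() == 0.0

    def test_cns1_bounded_by_cas(self, toy):
        s_cns = similarity_matrix(toy, "cns1", full=True)
        s_cas = similarity_matrix(toy, "cas")
        assert (s_cns.matrix <= s_cas.matrix + 1e-12).all()

    def test_label_permutation_invariance(self):
        """Renaming nodes permutes the similarity matrix identically."""
        rng = np.random.default_rng(11)
        g = random_attributed_graph(rng, n_nodes=8)
        perm = rng.permutation(8)
        renamed = {g.nodes[i]: f"y{perm[i]}" for i in range(8)}
        h = AttributedGraph(
            nx.relabel_nodes(g.graph, renamed),
            g.attributes.rename(index=renamed),
        )
        for measure in ("cns1", "cas", "smc", "jaccard"):
            s_g = similarity_matrix(g, measure, full=True)
            s_h = similarity_matrix(h, measure, full=True)
            for i in g.nodes:
                for j in g.nodes:
                    assert s_g.value(i, j) == pytest.approx(
                        s_h.value(renamed[i], renamed[j])
                    )
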