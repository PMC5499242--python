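"""The RC importance index and its ingredients, against brute-force oracles."""

import numpy as np
import pytest

from _oracles import (
    oracle_betweenness,
    oracle_distances,
    oracle_efficiency,
    oracle_rc,
)
from conftest import complete_graph, cycle_graph, graph_from, random_graph

from brainhubs import (
    DimensionError,
    EmptyNetworkError,
    contribution_matrix,
    degree_and_strength,
    evaluation_matrix,
    information_efficiency,
    rc_scores,
    select_hubs,
    shortest_weighted_distances,
    weighted_betweenness,
)
from brainhubs.hubscore import make_score_table


class TestDegreeAndStrength:
    def test_triangle(self, triangle):
        ds = degree_and_strength(triangle)
        np.testing.assert_array_equal(ds.degree, [2, 2, 2])
        np.testing.assert_array_equal(ds.strength, [4.0, 4.0, 4.0])
        assert ds.mean_degree == 2.0
        assert ds.mean_strength == 4.0

    def test_star(self, star4):
        ds = degree_and_strength(star4)
        np.testing.assert_array_equal(ds.degree, [3, 1, 1, 1])
        assert ds.mean_degree == 1.5

    def test_handshake_lemma_on_random_graphs(self, rng):
        for _ in range(5):
            g = random_graph(rng, 10, p=0.4)
            ds = degree_and_strength(g)
            assert ds.degree.sum() == 2 * g.m


class TestShortestDistances:
    def test_single_edge(self):
        g = graph_from([[0.0, 4.0], [4.0, 0.0]])
        d = shortest_weighted_distances(g)
        assert d[0, 1] == pytest.approx(0.25)

    def test_two_hop_path_beats_weak_direct_edge(self):
        w = np.array(
            [
                [0.0, 1.0, 0.25],
                [1.0, 0.0, 1.0],
                [0.25, 1.0, 0.0],
            ]
        )
        d = shortest_weighted_distances(graph_from(w))
        assert d[0, 2] == pytest.approx(2.0)  # 1/1 + 1/1 beats 1/0.25

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_path_enumeration_oracle(self, rng, trial):
        g = random_graph(rng, 8, p=0.45)
        np.testing.assert_allclose(
            shortest_weighted_distances(g), oracle_distances(g.weights), rtol=1e-10
        )

    def test_disconnected_pair_is_infinite(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 2.0
        d = shortest_weighted_distances(graph_from(w))
        assert np.isinf(d[0, 2])


class TestInformationEfficiency:
    def test_triangle_hand_value(self, triangle):
        # neighbor pair distance 1/2, two ordered pairs, / (2*1), * 1/3
        np.testing.assert_allclose(information_efficiency(triangle), 2.0 / 3.0)

    def test_leaves_score_zero(self, star4):
        e = information_efficiency(star4)
        assert np.all(e[1:] == 0.0)
        assert e[0] > 0.0  # center's leaves reach each other through it

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_neighbor_pair_oracle(self, rng, trial):
        g = random_graph(rng, 8, p=0.4)
        np.testing.assert_allclose(
            information_efficiency(g), oracle_efficiency(g.weights), rtol=1e-10
        )


class TestContributionMatrix:
    def test_triangle_entries(self, triangle):
        h = contribution_matrix(triangle)
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(h[off], 0.25)
        np.testing.assert_allclose(np.diag(h), 1.0)

    def test_zero_weight_gives_zero_entry(self, star4):
        h = contribution_matrix(star4)
        assert h[1, 2] == 0.0

    def test_scaled_degree_weight_product(self, rng):
        g = random_graph(rng, 9, p=0.5)
        ds = degree_and_strength(g)
        h = contribution_matrix(g, ds)
        scale = ds.mean_strength * ds.mean_degree**2
        for i in range(g.n):
            for j in range(g.n):
                expected = 1.0 if i == j else ds.degree[i] * g.weights[i, j] / scale
                assert h[i, j] == pytest.approx(expected)

    def test_edgeless_graph_rejected(self):
        g = graph_from(np.zeros((3, 3)))
        with pytest.raises(EmptyNetworkError):
            contribution_matrix(g)


class TestEvaluationMatrix:
    def test_unit_efficiency_is_identity_scaling(self, triangle):
        h = contribution_matrix(triangle)
        out = evaluation_matrix(h, np.ones(3))
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(out[off], h[off])
        np.testing.assert_allclose(np.diag(out), 1.0)

    def test_zero_efficiency_zeroes_row(self, triangle):
        h = contribution_matrix(triangle)
        e = np.array([0.0, 1.0, 1.0])
        out = evaluation_matrix(h, e)
        assert np.all(out[0, :] == 0.0)

    def test_triangle_hand_substitution(self, triangle):
        h = contribution_matrix(triangle)
        e = information_efficiency(triangle)
        out = evaluation_matrix(h, e)
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(out[off], 0.25 * (2.0 / 3.0))
        np.testing.assert_allclose(np.diag(out), 2.0 / 3.0)

    def test_shape_mismatch(self, triangle):
        with pytest.raises(DimensionError):
            evaluation_matrix(contribution_matrix(triangle), np.ones(4))


class TestRcScores:
    def test_triangle_equal_scores(self, triangle):
        t = rc_scores(triangle)
        np.testing.assert_allclose(t["score"], 2.0 / 9.0)

    def test_star_all_zero(self, star4):
        t = rc_scores(star4)
        assert np.all(t["score"] == 0.0)

    def test_boosted_node_in_complete_graph_wins(self):
        n = 6
        w = np.full((n, n), 3.0)
        np.fill_diagonal(w, 0.0)
        w[0, :] *= 2.0
        w[:, 0] = w[0, :]
        t = rc_scores(graph_from(w))
        scores = t.set_index("region_index")["score"]
        assert scores[0] > scores.drop(0).max()
        assert t.loc[t["rank"] == 1, "region_index"].item() == 0

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_direct_formula_oracle(self, rng, trial):
        g = random_graph(rng, 8, p=0.5)
        t = rc_scores(g)
        np.testing.assert_allclose(t["score"], oracle_rc(g.weights), rtol=1e-10)

    def test_scores_nonnegative(self, rng):
        g = random_graph(rng, 12, p=0.3)
        assert np.all(rc_scores(g)["score"] >= 0.0)

    def test_permutation_equivariance(self, rng):
        g = random_graph(rng, 9, p=0.5)
        base = rc_scores(g)["score"].to_numpy()
        perm = rng.permutation(9)
        gp = graph_from(g.weights[np.ix_(perm, perm)])
        permuted = rc_scores(gp)["score"].to_numpy()
        np.testing.assert_allclose(permuted, base[perm], rtol=1e-10)

    def test_invariant_under_uniform_weight_scaling(self, rng):
        # E ~ c, strength-sum term ~ c^2 / (S_bar ~ c) => RC ~ c^2... measure it
        g = random_graph(rng, 8, p=0.6)
        base = rc_scores(g)["score"].to_numpy()
        for c in (0.5, 3.0, 10.0):
            scaled = rc_scores(graph_from(c * g.weights))["score"].to_numpy()
            mask = base > 0
            ratio = scaled[mask] / base[mask]
            # empirical power law: RC scales exactly as c^2
            np.testing.assert_allclose(ratio, c**2, rtol=1e-9)

    def test_equal_scores_on_vertex_transitive_graphs(self):
        for g in (cycle_graph(7, 2.5), complete_graph(6, 1.5)):
            s = rc_scores(g)["score"].to_numpy()
            np.testing.assert_allclose(s, s[0], rtol=1e-12)


class TestSelectHubs:
    def test_default_fifteen_hubs_on_83_regions(self, rng):
        g = random_graph(rng, 83, p=0.2)
        t = select_hubs(rc_scores(g))
        assert int(t["is_hub"].sum()) == 15

    def test_clamps_k_to_n(self, triangle):
        t = select_hubs(rc_scores(triangle), k=15)
        assert int(t["is_hub"].sum()) == 3

    def test_tie_at_boundary_goes_to_lower_index(self, triangle):
        scores = np.array([1.0, 0.5, 0.5])
        t = select_hubs(make_score_table(triangle, scores, "rc"), k=2)
        hubs = set(t.loc[t["is_hub"], "region_index"])
        assert hubs == {0, 1}

    def test_rejects_nonpositive_k(self, triangle):
        with pytest.raises(ValueError):
            select_hubs(rc_scores(triangle), k=0)


class TestWeightedBetweenness:
    def test_path_graph_middle_node(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        t = weighted_betweenness(graph_from(w))
        s = t.set_index("region_index")["score"]
        assert s[1] == pytest.approx(1.0)
        assert s[0] == s[2] == 0.0

    def test_complete_equal_weight_graph_is_all_zero(self):
        t = weighted_betweenness(complete_graph(5, 2.0))
        assert np.all(t["score"] == 0.0)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_path_counting_oracle(self, rng, trial):
        g = random_graph(rng, 8, p=0.45)
        t = weighted_betweenness(g)
        np.testing.assert_allclose(
            t["score"], oracle_betweenness(g.weights), atol=1e-8
        )

    def test_permutation_equivariance(self, rng):
        g = random_graph(rng, 8, p=0.5)
        base = weighted_betweenness(g)["score"].to_numpy()
        perm = rng.permutation(8)
        permuted = weighted_betweenness(graph_from(g.weights[np.ix_(perm, perm)]))[
            "score"
        ].to_numpy()
        np.testing.assert_allclose(permuted, base[perm], atol=1e-8)


def test_score_table_ranks_are_permutation(rng):
    g = random_graph(rng, 20, p=0.3)
    t = rc_scores(g)
    assert sorted(t["rank"]) == list(range(1, 21))
    ordered = t.sort_values("rank")["score"].to_numpy()
    assert np.all(np.diff(ordered) <= 1e-15)
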