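import numpy as np
import pytest

from slnet import (
    FEATURE_NAMES,
    NetworkFeatureVector,
    betweenness,
    closeness,
    eigenvector_centrality,
    feature_vector,
    powerlaw_fit,
    strength,
    weighted_clustering,
    weighted_shortest_paths,
)
from slnet.connectivity import ConnectivityMatrix

from conftest import random_connectivity
from oracles import (
    betweenness_oracle,
    clustering_oracle,
    eigenvector_oracle,
    shortest_paths_oracle,
)


def uniform_graph(n, c=0.4):
    w = np.full((n, n), c)
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(w, [f"ch{i}" for i in range(n)])


class TestStrength:
    def test_three_node_hand_computation(self, three_node):
        s, summ = strength(three_node)
        np.testing.assert_allclose(s, [0.7, 0.6, 0.3])
        assert summ["min"] == pytest.approx(0.3)
        assert summ["mean"] == pytest.approx(0.5333333333)
        assert summ["max"] == pytest.approx(0.7)

    def test_uniform_graph_symmetric(self):
        s, _ = strength(uniform_graph(5, 0.4))
        np.testing.assert_allclose(s, 4 * 0.4)

    def test_zero_matrix(self):
        s, _ = strength(np.zeros((4, 4)))
        np.testing.assert_array_equal(s, 0.0)


class TestShortestPaths:
    def test_three_node_direct_edge_wins(self, three_node):
        dist, L, _ = weighted_shortest_paths(three_node)
        # direct 1/0.5 = 2.0 beats detour 1/0.2 + 1/0.1 = 15
        assert dist[0, 1] == pytest.approx(2.0)

    def test_uniform_graph_distances(self):
        dist, L, summ = weighted_shortest_paths(uniform_graph(4, 0.5))
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(dist[off], 2.0)
        np.testing.assert_allclose(L, 2.0)
        assert summ["min"] == summ["max"] == pytest.approx(2.0)

    def test_raising_a_weight_never_lengthens_paths(self, rng):
        M = random_connectivity(rng, 5)
        dist0, _, _ = weighted_shortest_paths(M)
        w = M.values.copy()
        w[1, 3] = w[3, 1] = w[1, 3] * 2
        dist1, _, _ = weighted_shortest_paths(
            ConnectivityMatrix(np.clip(w, 0, 1), M.channel_labels)
        )
        assert np.all(dist1 <= dist0 + 1e-12)

    def test_zero_weight_edge_rejected(self):
        w = np.array([[0.0, 0.5, 0.0], [0.5, 0.0, 0.2], [0.0, 0.2, 0.0]])
        with pytest.raises(ValueError, match="zero or negative"):
            weighted_shortest_paths(ConnectivityMatrix(w, ["a", "b", "c"]))


class TestCloseness:
    def test_uniform_graph_equals_weight(self):
        dist, _, _ = weighted_shortest_paths(uniform_graph(6, 0.3))
        cc, _ = closeness(dist)
        np.testing.assert_allclose(cc, 0.3)

    def test_reciprocal_of_mean_distance(self, three_node):
        dist, L, _ = weighted_shortest_paths(three_node)
        cc, _ = closeness(dist)
        np.testing.assert_allclose(cc, 1.0 / L)

    def test_ordering_reverses_path_length(self, three_node):
        dist, L, _ = weighted_shortest_paths(three_node)
        cc, _ = closeness(dist)
        assert np.array_equal(np.argsort(cc), np.argsort(L)[::-1])


class TestBetweenness:
    def test_uniform_graph_all_zero(self):
        bc, _ = betweenness(uniform_graph(5, 0.7))
        np.testing.assert_array_equal(bc, 0.0)

    def test_star_heavy_weights_route_through_hub(self):
        w = np.array([[0.0, 0.9, 0.1], [0.9, 0.0, 0.9], [0.1, 0.9, 0.0]])
        bc, summ = betweenness(ConnectivityMatrix(w, ["a", "b", "c"]))
        # 1-3 via hub: 1/0.9 + 1/0.9 ≈ 2.22 < 1/0.1 = 10; both ordered pairs
        np.testing.assert_allclose(bc, [0.0, 2.0, 0.0])
        assert summ["max"] == pytest.approx(2.0)

    def test_permutation_equivariance(self, rng):
        M = random_connectivity(rng, 6)
        bc, _ = betweenness(M)
        perm = rng.permutation(6)
        Mp = ConnectivityMatrix(
            M.values[np.ix_(perm, perm)], [M.channel_labels[i] for i in perm]
        )
        bcp, _ = betweenness(Mp)
        np.testing.assert_allclose(bcp, bc[perm], atol=1e-9)

    def test_shared_credit_on_degenerate_paths(self):
        # two exactly tied shortest 0-3 routes (via 1 or via 2)
        w = np.array([
            [0.0, 0.5, 0.5, 0.1],
            [0.5, 0.0, 0.1, 0.5],
            [0.5, 0.1, 0.0, 0.5],
            [0.1, 0.5, 0.5, 0.0],
        ])
        bc, _ = betweenness(ConnectivityMatrix(w, list("abcd")))
        np.testing.assert_allclose(bc, betweenness_oracle(w), atol=1e-9)
        assert bc[1] == pytest.approx(bc[2])
        assert bc[1] > 0


class TestEigenvector:
    def test_uniform_graph_flat_vector(self):
        ec, _ = eigenvector_centrality(uniform_graph(4, 0.2))
        np.testing.assert_allclose(ec, 0.5)

    def test_eigen_equation_residual(self, rng):
        M = random_connectivity(rng, 7)
        ec, _ = eigenvector_centrality(M)
        lam = ec @ M.values @ ec
        assert np.linalg.norm(M.values @ ec - lam * ec) < 1e-10

    def test_three_node_closed_form(self, three_node):
        ec, _ = eigenvector_centrality(three_node)
        # roots of the 3x3 characteristic polynomial, largest eigenvalue
        w = three_node.values
        lam = max(np.roots(np.poly(w)).real)
        v = np.linalg.solve(
            (w - lam * np.eye(3))[:2, :2], -(w - lam * np.eye(3))[:2, 2]
        )
        v = np.append(v, 1.0)
        v = np.abs(v) / np.linalg.norm(v)
        np.testing.assert_allclose(ec, v, atol=1e-9)


class TestClustering:
    def test_uniform_graph_maximal(self):
        C, _ = weighted_clustering(uniform_graph(5, 0.2))
        np.testing.assert_allclose(C, 1.0)

    def test_three_node_single_triangle(self, three_node):
        C, _ = weighted_clustering(three_node)
        expected = (1.0 * 0.4 * 0.2) ** (1 / 3)  # ŵ = w / 0.5
        np.testing.assert_allclose(C, expected)
        assert C[0] == pytest.approx(0.4308869380, abs=1e-9)

    def test_zero_weight_edge_kills_its_triangles(self):
        w = np.array([
            [0.0, 0.5, 0.0, 0.5],
            [0.5, 0.0, 0.5, 0.5],
            [0.0, 0.5, 0.0, 0.5],
            [0.5, 0.5, 0.5, 0.0],
        ])
        C, _ = weighted_clustering(ConnectivityMatrix(w, list("abcd")))
        np.testing.assert_allclose(C, clustering_oracle(w), atol=1e-12)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError, match="3 nodes"):
            weighted_clustering(np.zeros((2, 2)))

    def test_saramaki_variant_is_one_on_uniform_graph(self):
        C, _ = weighted_clustering(uniform_graph(5, 0.3), method="saramaki")
        np.testing.assert_allclose(C, 1.0)


class TestOracleEquivalence:
    """All metrics vs exhaustive enumeration on random graphs, N <= 7."""

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7])
    def test_all_metrics_match_brute_force(self, n, rng):
        for _ in range(5):
            M = random_connectivity(rng, n)
            w = M.values
            dist, L, _ = weighted_shortest_paths(M)
            np.testing.assert_allclose(dist, shortest_paths_oracle(w), atol=1e-9)
            cc, _ = closeness(dist)
            np.testing.assert_allclose(
                cc, (n - 1) / shortest_paths_oracle(w).sum(1), atol=1e-9
            )
            bc, _ = betweenness(M)
            np.testing.assert_allclose(bc, betweenness_oracle(w), atol=1e-9)
            ec, _ = eigenvector_centrality(M)
            np.testing.assert_allclose(ec, eigenvector_oracle(w), atol=1e-9)
            C, _ = weighted_clustering(M)
            np.testing.assert_allclose(C, clustering_oracle(w), atol=1e-9)


class TestPowerLaw:
    def test_closed_form_on_log_spaced_sample(self):
        fit = powerlaw_fit(np.array([1.0, np.e, np.e**2]), d_min=1.0)
        assert fit.alpha == pytest.approx(2.0, abs=1e-12)
        assert fit.n_tail == 3

    def test_recovers_known_index(self, rng):
        alpha = 2.5
        u = rng.uniform(size=10_000)
        draws = (1 - u) ** (-1.0 / (alpha - 1))
        fit = powerlaw_fit(draws)
        assert fit.alpha == pytest.approx(2.5, abs=0.1)

    def test_scale_invariance(self, rng):
        d = rng.uniform(1, 10, size=50)
        a1 = powerlaw_fit(d).alpha
        a2 = powerlaw_fit(d * 37.0).alpha
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_nonpositive_strengths_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            powerlaw_fit(np.array([1.0, 0.0, 2.0]))

    def test_all_equal_reported_distinctly(self):
        with pytest.raises(ValueError, match="undefined"):
            powerlaw_fit(np.full(5, 3.0))

    def test_ks_scan_mode_runs(self, rng):
        alpha = 2.5
        u = rng.uniform(size=2000)
        draws = (1 - u) ** (-1.0 / (alpha - 1))
        fit = powerlaw_fit(draws, scan_xmin=True)
        assert fit.alpha == pytest.approx(2.5, abs=0.3)
        assert fit.n_tail >= 2


class TestFeatureVector:
    def test_schema_is_18_named_features(self, rng):
        fv = feature_vector(random_connectivity(rng, 6))
        assert len(FEATURE_NAMES) == 18
        assert fv.as_array().shape == (18,)
        assert list(fv.as_dict()) == list(FEATURE_NAMES)

    def test_symmetric_graph_collapses_min_mean_max(self):
        # exactly uniform weights leave the power-law index undefined (all
        # strengths equal), which feature_vector propagates as an error;
        # an infinitesimally perturbed uniform graph collapses every family
        M = uniform_graph(6, 0.4)
        with pytest.raises(ValueError, match="undefined"):
            feature_vector(M)
        w = M.values.copy()
        w[0, 1] = w[1, 0] = 0.4 + 1e-9
        fv = feature_vector(ConnectivityMatrix(w, M.channel_labels))
        for fam in ("strength", "path", "closeness", "eigenvector", "clustering"):
            assert getattr(fv, f"{fam}_min") == pytest.approx(
                getattr(fv, f"{fam}_max"), abs=1e-6
            )

    def test_permutation_invariance(self, rng):
        M = random_connectivity(rng, 7)
        perm = rng.permutation(7)
        Mp = ConnectivityMatrix(
            M.values[np.ix_(perm, perm)], [M.channel_labels[i] for i in perm]
        )
        np.testing.assert_allclose(
            feature_vector(M).as_array(), feature_vector(Mp).as_array(), atol=1e-9
        )

    def test_family_ordering_enforced(self, rng):
        for _ in range(10):
            fv = feature_vector(random_connectivity(rng, 5))
            arr = fv.as_dict()
            for fam in ("strength", "path", "closeness", "eigenvector",
                        "clustering"):
                assert arr[f"{fam}_min"] <= arr[f"{fam}_mean"] <= arr[f"{fam}_max"]

    def test_min_mean_max_violation_rejected(self, rng):
        good = feature_vector(random_connectivity(rng, 4)).as_dict()
        good["strength_min"] = good["strength_max"] + 1.0
        with pytest.raises(ValueError, match="min <= mean <= max"):
            NetworkFeatureVector(**good)
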