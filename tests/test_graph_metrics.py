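"""Graph measures against hand-computed values and brute-force oracles."""

import numpy as np
import pytest

import oracles
from conftest import binary_from_matrix
from neurostage import graph_metrics as gm


class TestLocalHandExamples:
    def test_triangle(self):
        a = np.ones((3, 3), dtype=int) - np.eye(3, dtype=int)
        loc = gm.local_measures(binary_from_matrix(a))
        assert (loc["clustering_coefficient"] == 1.0).all()
        assert (loc["betweenness_centrality"] == 0.0).all()

    def test_star_center(self, star5):
        loc = gm.local_measures(binary_from_matrix(star5))
        # center routes all 6 unordered leaf pairs
        assert loc["betweenness_centrality"].iloc[0] == pytest.approx(6.0)
        assert (loc["betweenness_centrality"].iloc[1:] == 0.0).all()
        assert loc["eccentricity"].iloc[0] == 1
        assert (loc["eccentricity"].iloc[1:] == 2).all()

    def test_all_edges_within_module_zero_participation(self, two_k4):
        loc = gm.local_measures(binary_from_matrix(two_k4))
        # Louvain on two disjoint cliques finds them; all edges internal
        assert np.allclose(loc["participation_coefficient"], 0.0)


class TestGlobalHandExamples:
    def test_five_cycle(self, cycle5):
        g = gm.global_measures(binary_from_matrix(cycle5), n_null=2)
        assert g["characteristic_path_length"] == pytest.approx(1.5)
        assert g["diameter"] == 2
        assert g["radius"] == 2
        assert g["density"] == pytest.approx(0.5)
        assert g["transitivity"] == 0.0

    def test_complete_graph(self):
        a = np.ones((6, 6), dtype=int) - np.eye(6, dtype=int)
        g = gm.global_measures(binary_from_matrix(a), n_null=2)
        assert g["mean_clustering"] == pytest.approx(1.0)
        assert g["transitivity"] == pytest.approx(1.0)
        assert g["global_efficiency"] == pytest.approx(1.0)
        # regular graph: degenerate assortativity must surface as NaN
        assert np.isnan(g["assortativity"])

    def test_two_cliques_modularity_half(self, two_k4):
        labels = np.array([0] * 4 + [1] * 4)
        assert gm.modularity_q(two_k4, labels) == pytest.approx(0.5)

    def test_gce_entries_passed_through(self, cycle5):
        from neurostage.connectivity import GceCurve

        curve = GceCurve(
            densities=np.array([0.1, 0.2]), gce_values=np.array([0.3, 0.1])
        )
        g = gm.global_measures(binary_from_matrix(cycle5), gce=curve, n_null=2)
        assert g["gce_max"] == pytest.approx(0.3)
        assert g["gce_argmax_cost"] == pytest.approx(0.1)


class TestModularityContribution:
    def test_sum_equals_q_exactly(self, rng):
        for _ in range(20):
            a = oracles.random_connected_graph(7, rng)
            labels = rng.integers(0, 3, size=7)
            contrib = gm.modularity_contribution(a, labels)
            assert contrib.sum() == pytest.approx(
                oracles.modularity_oracle(a, labels), abs=1e-12
            )

    def test_two_cliques_per_node_share(self, two_k4):
        labels = np.array([0] * 4 + [1] * 4)
        contrib = gm.modularity_contribution(two_k4, labels)
        np.testing.assert_allclose(contrib, 0.0625)

    def test_singleton_partition_q_zero(self, two_k4):
        labels = np.zeros(8, dtype=int)
        assert gm.modularity_contribution(two_k4, labels).sum() == pytest.approx(
            0.0, abs=1e-12
        )

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            gm.modularity_contribution(np.zeros((4, 4)), np.zeros(4))


class TestOracleSuite:
    """Each measure vs an independent brute-force implementation."""

    @pytest.mark.parametrize("seed", range(10))
    def test_local_measures_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            n = int(rng.integers(4, 8))
            a = oracles.random_connected_graph(n, rng)
            loc = gm.local_measures(binary_from_matrix(a), seed=seed)
            np.testing.assert_allclose(
                loc["betweenness_centrality"],
                oracles.betweenness_oracle(a),
                atol=1e-8,
            )
            np.testing.assert_allclose(
                loc["clustering_coefficient"],
                oracles.clustering_oracle(a),
                atol=1e-12,
            )
            d = oracles.all_pairs_distances(a)
            npl = np.array(
                [d[i][d[i] > 0].mean() for i in range(n)]
            )
            ecc = np.array([d[i].max() for i in range(n)])
            np.testing.assert_allclose(loc["nodal_path_length"], npl, atol=1e-12)
            np.testing.assert_allclose(loc["eccentricity"], ecc, atol=1e-12)
            np.testing.assert_allclose(
                loc["eigenvector_centrality"],
                oracles.eigenvector_oracle(a),
                atol=1e-6,
            )
            np.testing.assert_allclose(
                loc["subgraph_centrality"],
                oracles.subgraph_centrality_oracle(a),
                rtol=1e-8,
            )
            deg = a.sum(axis=0)
            np.testing.assert_allclose(
                loc["rich_club_at_degree"],
                [oracles.rich_club_oracle(a, int(k)) for k in deg],
                atol=1e-12,
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_global_measures_match_bruteforce(self, seed):
        rng = np.random.default_rng(100 + seed)
        for _ in range(10):
            n = int(rng.integers(4, 8))
            a = oracles.random_connected_graph(n, rng)
            g = gm.global_measures(binary_from_matrix(a), seed=seed, n_null=2)
            d = oracles.all_pairs_distances(a)
            reach = d > 0
            assert g["characteristic_path_length"] == pytest.approx(
                d[reach].mean()
            )
            ecc = d.max(axis=1)
            assert g["radius"] == ecc.min()
            assert g["diameter"] == ecc.max()
            assert g["global_efficiency"] == pytest.approx(
                oracles.global_efficiency_oracle(a)
            )
            assert g["transitivity"] == pytest.approx(
                oracles.transitivity_oracle(a)
            )
            assert g["mean_clustering"] == pytest.approx(
                oracles.clustering_oracle(a).mean()
            )
            assert g["density"] == pytest.approx(a.sum() / (n * (n - 1)))
            oracle_assort = oracles.assortativity_oracle(a)
            if np.isnan(oracle_assort):
                assert np.isnan(g["assortativity"])
            else:
                assert g["assortativity"] == pytest.approx(oracle_assort, abs=1e-8)

    def test_participation_matches_direct_formula(self, rng):
        for _ in range(20):
            a = oracles.random_connected_graph(6, rng)
            labels = rng.integers(0, 3, size=6)
            np.testing.assert_allclose(
                gm.participation_coefficient(a, labels),
                oracles.participation_oracle(a, labels),
                atol=1e-12,
            )


class TestPartitions:
    def test_louvain_q_at_least_singleton(self, rng):
        for _ in range(10):
            a = oracles.random_connected_graph(7, rng)
            louvain = gm.louvain_partition(a, seed=0)
            q = gm.modularity_q(a, louvain)
            assert q >= 0.0 - 1e-12   # singleton partition has Q = 0

    def test_louvain_nonnegative_on_disconnected(self, two_k4):
        louvain = gm.louvain_partition(two_k4, seed=0)
        assert gm.modularity_q(two_k4, louvain) >= 0.0
        # on two disjoint cliques the optimum Q = 0.5 is found
        assert gm.modularity_q(two_k4, louvain) == pytest.approx(0.5)

    def test_newman_finds_two_cliques(self, two_k4):
        labels = gm.newman_partition(two_k4)
        assert len(set(labels[:4])) == 1
        assert len(set(labels[4:])) == 1
        assert labels[0] != labels[4]


class TestSmallWorldness:
    def test_er_graph_sigma_near_one(self):
        # ER is its own degree-preserving null in expectation
        sigmas = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = (rng.random((50, 50)) < 0.2).astype(int)
            a = np.triu(a, 1)
            a = a + a.T
            sigmas.append(gm.small_worldness(a, n_null=5, seed=seed))
        assert 0.8 < np.mean(sigmas) < 1.2

    def test_watts_strogatz_sigma_large(self):
        import networkx as nx

        hits = 0
        for seed in range(20):
            g = nx.watts_strogatz_graph(50, 6, 0.1, seed=seed)
            a = nx.to_numpy_array(g).astype(int)
            if gm.small_worldness(a, n_null=5, seed=seed) > 1.5:
                hits += 1
        assert hits >= 18

    def test_deterministic_under_seed(self, rng):
        a = oracles.random_connected_graph(10, rng, p=0.4)
        s1 = gm.small_worldness(a, n_null=3, seed=7)
        s2 = gm.small_worldness(a, n_null=3, seed=7)
        assert s1 == s2 and np.isfinite(s1)


class TestRelabelingInvariance:
    def test_permutation_invariance(self, rng):
        for _ in range(20):
            n = 7
            a = oracles.random_connected_graph(n, rng)
            perm = rng.permutation(n)
            ap = a[np.ix_(perm, perm)]
            loc = gm.local_measures(binary_from_matrix(a), seed=3)
            locp = gm.local_measures(binary_from_matrix(ap), seed=3)
            # permutation-equivariant node-level measures
            for col in (
                "betweenness_centrality",
                "clustering_coefficient",
                "nodal_path_length",
                "eccentricity",
                "eigenvector_centrality",
                "rich_club_at_degree",
                "subgraph_centrality",
            ):
                np.testing.assert_allclose(
                    locp[col].to_numpy(),
                    loc[col].to_numpy()[perm],
                    atol=1e-6,
                    err_msg=col,
                )


def test_subject_feature_vector_layout(cycle5):
    from neurostage.connectivity import GceCurve

    curve = GceCurve(densities=np.array([0.2]), gce_values=np.array([0.05]))
    vec = gm.subject_graph_features(
        binary_from_matrix(cycle5), seed=0, gce=curve, n_null=2
    )
    assert len(vec) == 10 * 5 + 13
    assert vec.index[0].startswith("betweenness_centrality__")
    assert vec.index[-1] == "global__small_worldness_sigma"
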