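"""SOM training mechanics, Ward clustering, naming and serialization."""

import itertools

import numpy as np
import pandas as pd
import pytest

from daphmove.features import FEATURE_NAMES
from daphmove.som import (
    ClusterModel,
    NormalizationStats,
    PatternNamingError,
    SOMModel,
    _lattice_sqdist,
    _present,
    bmu,
    bmu_batch,
    classify_segments,
    cluster_profiles,
    component_planes,
    load_model,
    name_patterns,
    normalize,
    quantization_error,
    save_model,
    train_som,
    ward_cluster,
    ward_newick,
)


def blob_data(rng, centers, n_per, spread=0.02):
    return np.vstack([c + rng.normal(0, spread, (n_per, len(c))) for c in centers])


class TestNormalize:
    def test_min_max_column(self):
        X, stats = normalize(np.array([[0.0], [5.0], [10.0]]))
        assert np.allclose(X[:, 0], [0, 0.5, 1])

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-5, 20, (50, 7))
        Xn, stats = normalize(X)
        assert np.allclose(stats.inverse(Xn), X, atol=1e-9)

    def test_held_out_uses_training_stats(self):
        train = np.array([[0.0], [10.0]])
        _, stats = normalize(train)
        held_out = stats.transform(np.array([[20.0]]))
        # scaled with the training range, not its own: 20 -> 2, not 1
        assert held_out[0, 0] == pytest.approx(2.0)

    def test_constant_column_names_parameter(self):
        df = pd.DataFrame({"speed": [1.0, 2.0], "meander": [3.0, 3.0]})
        with pytest.raises(ValueError, match="meander"):
            normalize(df, feature_names=("speed", "meander"))


class TestTraining:
    def test_repeated_vector_is_fixed_point(self):
        v = np.array([0.3, 0.7, 0.1])
        X = np.tile(v, (100, 1))
        model = train_som(X, rows=3, cols=3, epochs=10, seed=0)
        assert np.max(np.abs(model.weights - v)) < 1e-3

    def test_zero_learning_rate_keeps_initialization(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (80, 4))
        model = train_som(X, rows=3, cols=3, epochs=3, alpha0=0.0, alphaT=0.0, seed=2)
        # every weight is still literally a data row
        for w in model.weights:
            assert any(np.array_equal(w, x) for x in X)

    def test_single_update_step_hand_value(self):
        # one node, alpha=0.5, h=1: w moves halfway toward x
        weights = np.zeros((1, 3))
        winner = _present(weights, np.ones(3), alpha=0.5, sigma=1.0,
                          lat2=_lattice_sqdist(1, 1))
        assert winner == 0
        assert np.allclose(weights, 0.5)

    def test_neighborhood_is_gaussian_in_lattice_distance(self):
        # two nodes one lattice step apart: neighbor moves by exp(-1/(2s^2))
        weights = np.zeros((2, 1))
        sigma = 0.8
        _present(weights, np.ones(1), alpha=1.0, sigma=sigma,
                 lat2=_lattice_sqdist(1, 2))
        assert weights[0, 0] == pytest.approx(1.0)
        assert weights[1, 0] == pytest.approx(np.exp(-1 / (2 * sigma**2)))

    def test_weights_stay_in_data_bounding_box(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (200, 5))
        model = train_som(X, rows=4, cols=4, epochs=5, seed=4)
        assert np.all(model.weights >= X.min(0) - 1e-12)
        assert np.all(model.weights <= X.max(0) + 1e-12)

    def test_bitwise_determinism_for_fixed_seed(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, (120, 6))
        a = train_som(X, epochs=3, seed=7, rows=4, cols=4)
        b = train_som(X, epochs=3, seed=7, rows=4, cols=4)
        assert np.array_equal(a.weights, b.weights)
        c = train_som(X, epochs=3, seed=8, rows=4, cols=4)
        assert not np.array_equal(a.weights, c.weights)

    def test_reduces_to_online_kmeans_at_zero_radius(self):
        # with sigma -> 0 only the winner moves: online k-means, replayed
        # by an independent reference loop with the same seeded order
        rng = np.random.default_rng(6)
        X = rng.uniform(0, 1, (60, 3))
        rows = cols = 2
        alpha = 0.3
        epochs = 2
        seed = 11
        model = train_som(
            X, rows=rows, cols=cols, epochs=epochs,
            alpha0=alpha, alphaT=alpha, sigma0=1e-9, sigmaT=1e-9, seed=seed,
        )
        ref_rng = np.random.default_rng(seed)
        W = X[ref_rng.choice(len(X), size=rows * cols, replace=False)].copy()
        for _ in range(epochs):
            for i in ref_rng.permutation(len(X)):
                j = int(np.argmin(((W - X[i]) ** 2).sum(1)))
                W[j] += alpha * (X[i] - W[j])
        assert np.allclose(model.weights, W, atol=1e-12)

    def test_topology_preserved_for_blobs(self):
        rng = np.random.default_rng(8)
        centers = np.eye(4) * 0.9
        X = blob_data(rng, centers, 60, spread=0.03)
        labels = np.repeat(np.arange(4), 60)
        model = train_som(X, rows=6, cols=6, epochs=8, seed=1)
        coords = model.lattice_coords()[bmu_batch(model, X)]
        within, between = [], []
        for a, b in itertools.combinations(range(len(X)), 2):
            d = np.linalg.norm(coords[a] - coords[b])
            (within if labels[a] == labels[b] else between).append(d)
        assert np.mean(within) < np.mean(between)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            train_som(np.zeros((10, 3)), rows=4, cols=4)


class TestBMU:
    def _model(self, rng):
        X = rng.uniform(0, 1, (40, 5))
        return train_som(X, rows=3, cols=3, epochs=2, seed=0), X

    def test_exact_weight_returns_its_node(self):
        model, _ = self._model(np.random.default_rng(9))
        assert bmu(model, model.weights[7]) == 7

    def test_tie_breaks_to_lowest_index(self):
        weights = np.zeros((12, 2))
        weights[3] = [1.0, 0.0]
        weights[9] = [1.0, 0.0]
        model = SOMModel(3, 4, weights, 0.5, 0.01, 2.0, 0.5, 1, 0)
        assert bmu(model, np.array([1.0, 0.0])) == 3

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(10)
        model, _ = self._model(rng)
        for _ in range(50):
            x = rng.uniform(-0.5, 1.5, 5)
            expected = min(
                range(model.n_nodes),
                key=lambda j: ((model.weights[j] - x) ** 2).sum(),
            )
            assert bmu(model, x) == expected

    def test_wrong_length_rejected(self):
        model, _ = self._model(np.random.default_rng(11))
        with pytest.raises(ValueError):
            bmu(model, np.zeros(3))


class TestWardClustering:
    def test_k_equals_nodes_gives_singletons(self):
        rng = np.random.default_rng(12)
        X = rng.uniform(0, 1, (50, 3))
        model = train_som(X, rows=3, cols=3, epochs=2, seed=0)
        cl = ward_cluster(model, k=9)
        assert len(np.unique(cl.node_to_cluster)) == 9

    def test_k_one_single_cluster(self):
        rng = np.random.default_rng(13)
        X = rng.uniform(0, 1, (50, 3))
        model = train_som(X, rows=3, cols=3, epochs=2, seed=0)
        cl = ward_cluster(model, k=1)
        assert np.all(cl.node_to_cluster == 0)

    def test_k_beyond_nodes_rejected(self):
        rng = np.random.default_rng(14)
        X = rng.uniform(0, 1, (50, 3))
        model = train_som(X, rows=3, cols=3, epochs=2, seed=0)
        with pytest.raises(ValueError):
            ward_cluster(model, k=10)

    def test_recovers_blobs_against_exhaustive_partition_oracle(self):
        # 12 codebook vectors in 3 tight blobs; the Ward k=3 cut must
        # equal the global minimum-SSE 3-partition found by brute force
        rng = np.random.default_rng(15)
        centers = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 1.0]])
        W = blob_data(rng, centers, 4, spread=0.02)
        model = SOMModel(3, 4, W, 0.5, 0.01, 2.0, 0.5, 1, 0)
        cl = ward_cluster(model, k=3)

        # enumerate all 3^12 assignments at once; SSE decomposes as
        # total_sq - sum_c n_c * |mean_c|^2
        A = np.array(list(itertools.product(range(3), repeat=12)), dtype=np.int8)
        onehot = (A[:, :, None] == np.arange(3)).astype(np.float32)
        counts = onehot.sum(axis=1)
        valid = (counts > 0).all(axis=1)
        sums = np.einsum("aic,id->acd", onehot, W.astype(np.float32))
        with np.errstate(invalid="ignore"):
            means = sums / counts[:, :, None]
        total_sq = float((W**2).sum())
        sse = total_sq - (counts * (means**2).sum(axis=2)).sum(axis=1)
        sse[~valid] = np.inf
        best = A[int(np.argmin(sse))]
        # compare partitions up to label permutation
        found = {frozenset(np.flatnonzero(cl.node_to_cluster == c)) for c in range(3)}
        oracle = {frozenset(np.flatnonzero(best == c)) for c in range(3)}
        assert found == oracle

    def test_newick_export_parses_with_independent_reader(self):
        import dendropy

        rng = np.random.default_rng(16)
        X = rng.uniform(0, 1, (60, 4))
        model = train_som(X, rows=3, cols=3, epochs=2, seed=0)
        cl = ward_cluster(model, k=3)
        tree = dendropy.Tree.get(data=ward_newick(cl), schema="newick")
        assert len(tree.leaf_nodes()) == 9


def profile_model():
    """Hand-built codebook of 6 x 2 nodes with archetype-like profiles."""
    # columns follow FEATURE_NAMES: speed, acceleration, locomotory_rate,
    # stop_number, stop_time, turning_rate, meander
    profiles = {
        "P1": [9.0, 2.5, 9.0, 0.0, 0.0, 0.5, 0.05],
        "P2": [5.5, 2.5, 5.5, 0.0, 0.0, 3.0, 0.5],
        "P3": [5.0, 11.0, 5.2, 1.0, 0.3, 3.0, 0.6],
        "P4": [3.0, 2.5, 3.1, 1.0, 0.3, 5.5, 2.0],
        "P5": [1.5, 1.7, 1.9, 1.5, 0.8, 3.0, 1.9],
        "P6": [0.2, 0.5, 0.1, 1.0, 4.8, 0.3, 1.4],
    }
    W = np.array([profiles[p] for p in sorted(profiles) for _ in range(2)])
    stats = NormalizationStats(
        tuple(FEATURE_NAMES), np.zeros(7), np.full(7, 12.0)
    )
    model = SOMModel(3, 4, stats.transform(W), 0.5, 0.01, 2.0, 0.5, 1, 0,
                     normalization=stats)
    labels = np.repeat(np.arange(6), 2)
    clusters = ClusterModel(linkage=np.zeros((11, 4)), k=6, node_to_cluster=labels)
    return model, clusters, profiles


class TestPatternNaming:
    def test_profile_ranking_recovers_archetypes(self):
        model, clusters, _ = profile_model()
        named = name_patterns(model, clusters)
        for cid, pat in named.cluster_names.items():
            assert pat == f"P{cid + 1}"

    def test_invariant_under_cluster_relabeling(self):
        model, clusters, _ = profile_model()
        perm = np.array([3, 0, 5, 1, 4, 2])
        relabeled = ClusterModel(
            linkage=clusters.linkage,
            k=6,
            node_to_cluster=perm[clusters.node_to_cluster],
        )
        named = name_patterns(model, clusters)
        named2 = name_patterns(model, relabeled)
        for node in range(model.n_nodes):
            assert named.pattern_of_node(node) == named2.pattern_of_node(node)

    def test_k_not_six_rejected(self):
        model, clusters, _ = profile_model()
        bad = ClusterModel(clusters.linkage, 5, clusters.node_to_cluster % 5)
        with pytest.raises(ValueError, match="k=6"):
            name_patterns(model, bad)

    def test_profile_tie_raises(self):
        model, clusters, _ = profile_model()
        W = model.weights.copy()
        W[2:4] = W[0:2]  # cluster 1 duplicates cluster 0 -> speed tie
        tied = SOMModel(3, 4, W, 0.5, 0.01, 2.0, 0.5, 1, 0,
                        normalization=model.normalization)
        with pytest.raises(PatternNamingError, match="tie"):
            name_patterns(tied, clusters)


class TestClassification:
    def test_node_weight_maps_to_its_cluster(self):
        model, clusters, _ = profile_model()
        named = name_patterns(model, clusters)
        W_denorm = model.normalization.inverse(model.weights)
        df = pd.DataFrame(W_denorm, columns=list(FEATURE_NAMES))
        labels = classify_segments(model, named, df)
        for node, lab in enumerate(labels):
            assert lab == named.pattern_of_node(node)

    def test_missing_parameter_rejected(self):
        model, clusters, _ = profile_model()
        named = name_patterns(model, clusters)
        df = pd.DataFrame({"speed": [1.0]})
        with pytest.raises(ValueError, match="missing"):
            classify_segments(model, named, df)


class TestPlanesAndSerialization:
    def test_component_planes_match_weights(self):
        model, _, _ = profile_model()
        planes = component_planes(model)
        W_denorm = model.normalization.inverse(model.weights)
        for i, name in enumerate(FEATURE_NAMES):
            assert np.allclose(planes[name].ravel(), W_denorm[:, i])

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(17)
        X = rng.uniform(0, 1, (80, 7))
        model = train_som(X, rows=3, cols=3, epochs=2, seed=3,
                          normalization=NormalizationStats(
                              tuple(FEATURE_NAMES), np.zeros(7), np.ones(7)))
        clusters = ward_cluster(model, k=6)
        path = tmp_path / "model.json"
        save_model(model, path, clusters)
        model2, clusters2 = load_model(path)
        assert np.array_equal(model.weights, model2.weights)
        assert model2.normalization.feature_names == tuple(FEATURE_NAMES)
        assert np.array_equal(clusters.node_to_cluster, clusters2.node_to_cluster)
        # planes computed from the reloaded model equal the originals
        p1 = component_planes(model)
        p2 = component_planes(model2)
        for name in FEATURE_NAMES:
            assert np.array_equal(p1[name], p2[name])

    def test_quantization_error_helper_matches_history(self):
        rng = np.random.default_rng(18)
        X = rng.uniform(0, 1, (90, 4))
        model = train_som(X, rows=3, cols=3, epochs=4, seed=5)
        assert quantization_error(model, X) == pytest.approx(
            model.qe_history[-1]
        )
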