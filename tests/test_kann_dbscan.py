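import numpy as np
import pytest

from complaintlens import (
    BlobSpec,
    ConfigError,
    InputError,
    NoStableClusteringError,
    dbscan,
    eps_candidates,
    kdistance_profile,
    make_blobs,
    pairwise_distances,
    pmin_expectation,
    select_parameters,
    solve_fixed,
)

LINE = np.array([[0.0], [1.0], [3.0]])  # hand-checkable collinear points


def graph_component_partition(d, eps, pmin):
    """Independent oracle: explicit eps-graph over core points + components."""
    import networkx as nx

    n = d.shape[0]
    counts = (d <= eps).sum(axis=1)
    core = set(np.nonzero(counts >= pmin)[0].tolist())
    g = nx.Graph()
    g.add_nodes_from(core)
    for i in core:
        for j in core:
            if i < j and d[i, j] <= eps:
                g.add_edge(i, j)
    return core, [set(c) for c in nx.connected_components(g)]


class TestPairwiseDistances:
    def test_345_triangle(self):
        d = pairwise_distances(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d[0, 1] == pytest.approx(5.0)

    def test_identical_points_zero(self):
        d = pairwise_distances(np.zeros((3, 2)))
        assert d.max() == 0.0

    def test_matches_double_loop(self, rng):
        pts = rng.normal(size=(6, 3))
        d = pairwise_distances(pts)
        for i in range(6):
            for j in range(6):
                assert d[i, j] == pytest.approx(
                    np.linalg.norm(pts[i] - pts[j]), abs=1e-12
                )

    def test_invariants(self, rng):
        d = pairwise_distances(rng.normal(size=(8, 2)), metric="cosine")
        np.testing.assert_array_equal(d, d.T)
        assert np.diag(d).max() == 0.0
        assert d.min() >= 0.0

    def test_nonfinite_rejected(self):
        with pytest.raises(InputError):
            pairwise_distances(np.array([[0.0, np.inf], [1.0, 2.0]]))

    def test_unknown_metric(self):
        with pytest.raises(ConfigError):
            pairwise_distances(np.zeros((2, 2)), metric="manhattan")


class TestKDistanceProfile:
    def test_collinear_columns(self):
        profile = kdistance_profile(pairwise_distances(LINE))
        np.testing.assert_array_equal(profile[:, 0], 0.0)
        np.testing.assert_array_equal(profile[:, 1], [1.0, 1.0, 2.0])
        np.testing.assert_array_equal(profile[:, 2], [3.0, 2.0, 3.0])

    def test_matches_per_row_sort(self, rng):
        d = pairwise_distances(rng.normal(size=(10, 3)))
        profile = kdistance_profile(d)
        for i in range(10):
            np.testing.assert_array_equal(profile[i], np.sort(d[i]))
        assert (np.diff(profile, axis=1) >= 0).all()


class TestEpsCandidates:
    def test_collinear_means(self):
        cand = eps_candidates(kdistance_profile(pairwise_distances(LINE)))
        assert cand[0] == 0.0
        assert cand[1] == pytest.approx(4 / 3)
        assert cand[2] == pytest.approx(8 / 3)

    def test_monotone_on_random_instances(self, rng):
        for _ in range(100):
            d = pairwise_distances(rng.normal(size=(rng.integers(3, 15), 2)))
            cand = eps_candidates(kdistance_profile(d))
            brute = np.sort(d, axis=1).mean(axis=0)  # brute-force means
            np.testing.assert_allclose(cand, brute, atol=1e-12)
            assert (np.diff(cand) >= -1e-12).all()


class TestPminExpectation:
    def test_hand_count(self):
        d = pairwise_distances(LINE)
        assert pmin_expectation(d, 1.0) == pytest.approx(5 / 3)

    def test_eps_zero_distinct_points(self):
        assert pmin_expectation(pairwise_distances(LINE), 0.0) == 1.0

    def test_eps_above_max(self):
        d = pairwise_distances(LINE)
        assert pmin_expectation(d, d.max()) == 3.0


class TestDbscan:
    def test_hand_run(self):
        labels = dbscan(pairwise_distances(LINE), eps=1.0, pmin=2.0)
        np.testing.assert_array_equal(labels, [0, 0, -1])

    def test_identical_points_single_cluster(self):
        d = pairwise_distances(np.zeros((5, 2)))
        labels = dbscan(d, eps=0.0, pmin=5.0)
        np.testing.assert_array_equal(labels, 0)

    def test_invalid_parameters(self):
        d = pairwise_distances(LINE)
        with pytest.raises(ConfigError):
            dbscan(d, eps=-1.0, pmin=2.0)
        with pytest.raises(ConfigError):
            dbscan(d, eps=1.0, pmin=0.5)

    def test_core_partition_matches_graph_components_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 41))
            pts = rng.normal(size=(n, 2))
            d = pairwise_distances(pts)
            eps = float(rng.uniform(0.1, 2.0))
            pmin = float(rng.uniform(1.0, 6.0))
            labels = dbscan(d, eps, pmin)
            core, components = graph_component_partition(d, eps, pmin)
            got = {}
            for i in core:
                got.setdefault(labels[i], set()).add(i)
            assert sorted(map(sorted, got.values())) == sorted(
                map(sorted, components)
            )

    def test_matches_sklearn_on_core_points(self, rng):
        # independent reference implementation, integer pmin only
        from sklearn.cluster import DBSCAN as SkDBSCAN

        for _ in range(25):
            n = int(rng.integers(8, 30))
            pts = rng.normal(size=(n, 2))
            d = pairwise_distances(pts)
            eps = float(rng.uniform(0.2, 1.5))
            pmin = int(rng.integers(2, 5))
            labels = dbscan(d, eps, float(pmin))
            sk = SkDBSCAN(eps=eps, min_samples=pmin, metric="precomputed").fit(d)
            core = np.zeros(n, bool)
            core[sk.core_sample_indices_] = True
            assert ((labels != -1) & core).sum() == core.sum()  # cores clustered
            for i in range(n):
                for j in range(n):
                    if core[i] and core[j]:
                        assert (labels[i] == labels[j]) == (
                            sk.labels_[i] == sk.labels_[j]
                        )

    def test_noise_monotone_in_eps(self, rng):
        pts = rng.normal(size=(30, 2))
        d = pairwise_distances(pts)
        pmin = 3.0
        noise = [
            int((dbscan(d, eps, pmin) == -1).sum())
            for eps in np.linspace(0.05, 2.5, 12)
        ]
        assert all(a >= b for a, b in zip(noise, noise[1:]))

    def test_core_partition_order_invariant(self, rng):
        pts = rng.normal(size=(25, 2))
        d = pairwise_distances(pts)
        eps, pmin = 0.7, 3.0
        labels = dbscan(d, eps, pmin)
        perm = rng.permutation(25)
        labels_perm = dbscan(d[np.ix_(perm, perm)], eps, pmin)
        counts = (d <= eps).sum(axis=1)
        core = counts >= pmin
        # core labels must induce the same partition after permutation
        for i in range(25):
            for j in range(25):
                if core[perm[i]] and core[perm[j]]:
                    assert (labels_perm[i] == labels_perm[j]) == (
                        labels[perm[i]] == labels[perm[j]]
                    )
        # noise set is permutation-equivariant too
        np.testing.assert_array_equal(labels_perm == -1, (labels == -1)[perm])

    def test_cluster_ids_gap_free(self, rng):
        pts = rng.normal(size=(40, 2))
        labels = dbscan(pairwise_distances(pts), 0.5, 3.0)
        ids = sorted(set(labels.tolist()) - {-1})
        assert ids == list(range(len(ids)))


class TestSelectParameters:
    def test_identical_points_degenerate_stability(self):
        d = pairwise_distances(np.zeros((6, 2)))
        sol = select_parameters(d, k_range=(1, 5))
        assert sol.n_clusters == 1
        assert sol.k == 5  # maximum of the range

    def test_three_blob_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        pts, truth = make_blobs(BlobSpec(seed=7))
        sol = select_parameters(pairwise_distances(pts))
        assert sol.n_clusters == 3
        assert adjusted_rand_score(truth, sol.labels) >= 0.9

    def test_stability_rule_on_synthetic_trace(self, monkeypatch):
        # trace C = (5,3,3,3,3,2) → N = 3, k* = last k with C = 3
        import complaintlens.kann_dbscan as mod

        counts = {1: 5, 2: 3, 3: 3, 4: 3, 5: 3, 6: 2}

        def fake_dbscan(d, eps, pmin):
            k = fake_dbscan.calls.pop(0)
            return np.arange(counts[k])  # counts[k] singleton clusters

        fake_dbscan.calls = list(range(1, 7))
        monkeypatch.setattr(mod, "dbscan", fake_dbscan)
        d = pairwise_distances(np.arange(14.0).reshape(7, 2))
        sol = mod.select_parameters(d, k_range=(1, 6))
        assert sol.n_clusters == 3
        assert sol.k == 5

    def test_no_stable_run_raises_with_trace(self, monkeypatch):
        import complaintlens.kann_dbscan as mod

        def fake_dbscan(d, eps, pmin):
            fake_dbscan.i += 1
            return np.arange(fake_dbscan.i)  # strictly changing counts

        fake_dbscan.i = 0
        monkeypatch.setattr(mod, "dbscan", fake_dbscan)
        d = pairwise_distances(np.arange(12.0).reshape(6, 2))
        with pytest.raises(NoStableClusteringError) as err:
            mod.select_parameters(d, k_range=(1, 5))
        assert len(err.value.trace) == 5

    def test_invalid_ranges(self):
        d = pairwise_distances(LINE)
        with pytest.raises(ConfigError):
            select_parameters(d, k_range=(0, 2))
        with pytest.raises(ConfigError):
            select_parameters(d, k_range=(1, 5))
        with pytest.raises(ConfigError):
            select_parameters(d, stability_window=1)


class TestSolveFixed:
    def test_fixed_eps_uses_expectation_pmin(self):
        d = pairwise_distances(LINE)
        sol = solve_fixed(d, eps=1.0)
        assert sol.eps == 1.0
        assert sol.pmin == pytest.approx(5 / 3)

    def test_fixed_k_takes_candidate_eps(self):
        d = pairwise_distances(LINE)
        sol = solve_fixed(d, k=1)
        assert sol.eps == pytest.approx(4 / 3)

    def test_requires_k_or_eps(self):
        with pytest.raises(ConfigError):
            solve_fixed(pairwise_distances(LINE))
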