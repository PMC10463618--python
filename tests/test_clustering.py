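"""k-means/k-medoids partitioning, archetype labeling, silhouette diagnostics."""
import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import swaywave as sw
from swaywave.errors import ParameterError
from swaywave.synthetic_data import ARCHETYPE_TARGETS


def brute_force_wcss(X, k):
    """Global WCSS optimum by enumerating every labeling into <= k clusters."""
    best = np.inf
    for labels in itertools.product(range(k), repeat=len(X)):
        labels = np.asarray(labels)
        wcss = 0.0
        for c in set(labels):
            pts = X[labels == c]
            wcss += ((pts - pts.mean(axis=0)) ** 2).sum()
        best = min(best, wcss)
    return best


def archetype_blobs(n_per_group=15, sd=1.0, seed=0):
    """Gaussian 17-d blobs around the three archetype targets, renormalized."""
    rng = np.random.default_rng(seed)
    X, truth = [], []
    for g in ("group1", "group2", "group3"):
        target = ARCHETYPE_TARGETS[g]
        pts = np.abs(target + rng.normal(0, sd, size=(n_per_group, 17)))
        pts = 100 * pts / pts.sum(axis=1, keepdims=True)
        X.append(pts)
        truth += [g] * n_per_group
    return np.vstack(X), np.array(truth)


class TestFitClusters:
    def test_k1_wcss_is_total_scatter(self, rng):
        X = rng.standard_normal((20, 5))
        model = sw.fit_clusters(X, k=1, seed=0, n_restarts=3)
        expected = ((X - X.mean(axis=0)) ** 2).sum()
        assert abs(model.wcss - expected) < 1e-9

    def test_recovers_archetype_blobs_exactly(self):
        X, truth = archetype_blobs()
        model = sw.fit_clusters(X, k=3, seed=1)
        assert adjusted_rand_score(truth, model.labels_) == 1.0

    def test_small_instance_matches_exhaustive_enumeration(self):
        X = np.array([[0.0, 0.0], [0.1, 0.0], [0.0, 0.2],
                      [5.0, 5.0], [5.2, 4.9], [4.8, 5.1]])
        model = sw.fit_clusters(X, k=2, seed=0)
        assert abs(model.wcss - brute_force_wcss(X, 2)) < 1e-9

    @pytest.mark.parametrize("method", ["kmeans", "kmedoids"])
    def test_wcss_consistent_with_assignments(self, method, rng):
        X = rng.standard_normal((30, 4))
        model = sw.fit_clusters(X, k=3, seed=5, method=method)
        recomputed = sum(
            ((X[i] - model.centroids[c]) ** 2).sum()
            for i, c in enumerate(model.labels_)
        )
        assert abs(model.wcss - recomputed) < 1e-9
        assert len(set(model.labels_)) == 3  # no empty clusters

    def test_monotone_wcss_trace(self, rng):
        X = rng.standard_normal((40, 6))
        model = sw.fit_clusters(X, k=4, seed=2, n_restarts=1)
        trace = np.array(model.wcss_trace)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_permutation_invariant_best_wcss(self, rng):
        X, _ = archetype_blobs(n_per_group=10, seed=6)
        w0 = sw.fit_clusters(X, k=3, seed=9).wcss
        perm = rng.permutation(len(X))
        w1 = sw.fit_clusters(X[perm], k=3, seed=9).wcss
        assert abs(w0 - w1) < 1e-9

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((20, 3))
        m1 = sw.fit_clusters(X, k=3, seed=11)
        m2 = sw.fit_clusters(X, k=3, seed=11)
        assert np.array_equal(m1.labels_, m2.labels_)
        assert m1.wcss == m2.wcss

    def test_kmedoids_centers_are_observed_points(self, rng):
        X = rng.standard_normal((20, 4))
        model = sw.fit_clusters(X, k=3, seed=0, method="kmedoids")
        for c in model.centroids:
            assert np.min(((X - c) ** 2).sum(axis=1)) < 1e-12

    def test_parameter_errors(self, rng):
        X = rng.standard_normal((5, 2))
        with pytest.raises(ParameterError):
            sw.fit_clusters(X, k=6, seed=0)
        with pytest.raises(ParameterError):
            sw.fit_clusters(X, k=0, seed=0)
        with pytest.raises(ParameterError):
            sw.fit_clusters(X, k=2, seed=0, method="dbscan")


def _centroid(**named):
    e = np.zeros(17)
    names = sw.component_names(16)
    for k, v in named.items():
        e[names.index(k)] = v
    return e


class TestLabelArchetypes:
    def _model(self, centroids):
        n = len(centroids)
        return sw.ClusterModel(
            k=n, centroids=np.asarray(centroids, dtype=float),
            assignments={}, subject_ids=[], labels_=np.arange(n),
            wcss=0.0, seed=0, n_restarts=1, method="kmeans",
        )

    def test_spec_rule_examples(self):
        c1 = _centroid(D15=22, D16=25)                    # very-low dominant
        c2 = _centroid(**{f"D{j}": 15 for j in range(11, 17)})  # broadband
        c3 = _centroid(D11=24, D12=26)                    # high dominant
        labels = sw.label_archetypes(self._model([c1, c2, c3]))
        assert labels.mapping == {0: "group1", 1: "group2", 2: "group3"}

    def test_unclassified_when_no_rule_matches(self):
        flat = np.full(17, 100 / 17)
        labels = sw.label_archetypes(self._model([flat]))
        assert labels.mapping == {0: "unclassified"}

    def test_precedence_dominance_over_range(self):
        # satisfies both the group3 and group1 dominance rules
        both = _centroid(D11=22, D12=22, D15=21, D16=22)
        labels = sw.label_archetypes(self._model([both]))
        assert labels.mapping[0] == "group3"

    def test_named_label_is_unique(self):
        a = _centroid(D15=30, D16=30)
        b = _centroid(D15=21, D16=21)
        labels = sw.label_archetypes(self._model([a, b]))
        assert labels.mapping[0] == "group1"  # larger margin wins
        assert labels.mapping[1] == "unclassified"

    def test_evidence_records_band_means(self):
        c = _centroid(D15=22, D16=26)
        labels = sw.label_archetypes(self._model([c]))
        assert labels.rule_evidence[0]["d15_d16_mean"] == pytest.approx(24.0)

    def test_requires_17_components(self):
        model = self._model([np.zeros(5)])
        with pytest.raises(ParameterError, match="17"):
            sw.label_archetypes(model)


class TestSilhouette:
    def test_perfectly_separated_duplicate_pairs(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [100.0, 0.0], [100.0, 0.0]])
        model = sw.fit_clusters(X, k=2, seed=0)
        report = sw.silhouette_report(model, X)
        assert report["overall"] == pytest.approx(1.0, abs=1e-9)

    def test_identical_points_give_zero(self):
        X = np.zeros((6, 2))
        model = sw.fit_clusters(X, k=2, seed=0)
        report = sw.silhouette_report(model, X)
        assert report["overall"] == pytest.approx(0.0, abs=1e-12)

    def test_k1_is_an_error(self, rng):
        X = rng.standard_normal((10, 2))
        model = sw.fit_clusters(X, k=1, seed=0)
        with pytest.raises(ParameterError):
            sw.silhouette_report(model, X)

    def test_blobs_match_manual_silhouette(self):
        X, _ = archetype_blobs(n_per_group=10, seed=3)
        model = sw.fit_clusters(X, k=3, seed=3)
        report = sw.silhouette_report(model, X)
        assert report["overall"] > 0.3
        # oracle: silhouette from the pairwise distance matrix, by hand
        d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        lab = model.labels_
        manual = []
        for i in range(len(X)):
            own = lab[i]
            a = d[i][(lab == own) & (np.arange(len(X)) != i)].mean()
            b = min(d[i][lab == c].mean() for c in set(lab) if c != own)
            manual.append((b - a) / max(a, b))
        assert report["overall"] == pytest.approx(np.mean(manual), abs=1e-9)
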