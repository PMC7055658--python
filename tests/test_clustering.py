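"""PCA, k-means clustering, cluster-localization mapping and the replicate filter."""

import itertools

import numpy as np
import pandas as pd
import pytest

import gradloc as gl
from gradloc.errors import CalibrationError, ConfigurationError, ValidationError
from gradloc.io_formats import FRACTIONS


def profiles(values: np.ndarray, ids=None) -> gl.ProfileSet:
    ids = ids or [f"P{i}" for i in range(len(values))]
    return gl.ProfileSet(
        replicate_id="averaged",
        logfc=pd.DataFrame(values, index=pd.Index(ids, name="protein_id"), columns=list(FRACTIONS)),
    )


class TestPCA:
    def test_rank_one_data_is_one_component(self):
        t = np.linspace(-1, 1, 30)
        direction = np.arange(1, 11, dtype=float)
        pca = gl.run_pca(profiles(np.outer(t, direction)))
        assert pca.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_data_spreads_variance(self):
        rng = np.random.default_rng(1)
        pca = gl.run_pca(profiles(rng.normal(size=(1000, 10))))
        np.testing.assert_allclose(pca.variance_fractions, 0.1, atol=0.02)

    def test_scores_are_centered(self):
        rng = np.random.default_rng(2)
        pca = gl.run_pca(profiles(rng.normal(size=(50, 10))))
        np.testing.assert_allclose(pca.scores.mean(axis=0), 0.0, atol=1e-9)

    def test_incomplete_rows_dropped(self):
        vals = np.random.default_rng(0).normal(size=(10, 10))
        vals[0, 0] = np.nan
        pca = gl.run_pca(profiles(vals))
        assert pca.n_dropped == 1 and len(pca.scores) == 9


class TestChooseK:
    def test_default_is_four(self):
        pca = gl.run_pca(profiles(np.random.default_rng(0).normal(size=(20, 10))))
        assert gl.choose_k(pca) == 4
        assert gl.choose_k(pca, 3) == 3

    def test_k_below_two_rejected(self):
        pca = gl.run_pca(profiles(np.random.default_rng(0).normal(size=(20, 10))))
        with pytest.raises(ConfigurationError):
            gl.choose_k(pca, 1)


def brute_force_best_partition(X: np.ndarray, k: int) -> float:
    """Minimum within-cluster sum of squares over all assignments (tiny n only)."""
    best = np.inf
    for labels in itertools.product(range(k), repeat=len(X)):
        labels = np.asarray(labels)
        if len(set(labels.tolist())) < k:
            continue
        inertia = 0.0
        for c in range(k):
            members = X[labels == c]
            inertia += ((members - members.mean(axis=0)) ** 2).sum()
        best = min(best, inertia)
    return best


class TestKMeans:
    def test_two_separated_clouds_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.2, size=(25, 10)) + 5
        b = rng.normal(0, 0.2, size=(25, 10)) - 5
        model = gl.kmeans_cluster(profiles(np.vstack([a, b])), k=2, seed=1)
        labels = model.assignments.to_numpy()
        assert len(set(labels[:25])) == 1 and len(set(labels[25:])) == 1
        assert labels[0] != labels[-1]

    def test_matches_exhaustive_enumeration_on_four_points(self):
        X = np.zeros((4, 10))
        X[0, 0], X[1, 0], X[2, 0], X[3, 0] = 0.0, 0.1, 5.0, 5.2
        model = gl.kmeans_cluster(profiles(X), k=2, seed=0, n_init=10)
        assert model.inertia == pytest.approx(brute_force_best_partition(X, 2), abs=1e-9)

    def test_duplicate_points_inertia_zero(self):
        X = np.ones((6, 10))
        model = gl.kmeans_cluster(profiles(X), k=2, seed=0, n_init=2)
        assert model.inertia == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 10))
        m1 = gl.kmeans_cluster(profiles(X), k=4, seed=9)
        m2 = gl.kmeans_cluster(profiles(X), k=4, seed=9)
        pd.testing.assert_series_equal(m1.assignments, m2.assignments)
        assert m1.inertia == m2.inertia

    def test_centroids_are_member_means(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 10))
        p = profiles(X)
        model = gl.kmeans_cluster(p, k=3, seed=2)
        for c in range(1, 4):
            members = p.logfc.loc[model.assignments[model.assignments == c].index]
            np.testing.assert_allclose(
                model.centroids.loc[c], members.mean(axis=0), atol=1e-7
            )

    def test_too_few_profiles_rejected(self):
        with pytest.raises(ValidationError):
            gl.kmeans_cluster(profiles(np.zeros((2, 10))), k=4, seed=0)


def toy_model(assignments: dict) -> gl.ClusterModel:
    s = pd.Series(assignments, name="cluster")
    k = int(s.max())
    return gl.ClusterModel(
        k=k,
        centroids=pd.DataFrame(np.zeros((k, 10)), index=range(1, k + 1), columns=list(FRACTIONS)),
        assignments=s,
        inertia=0.0,
        seed=0,
        n_init=1,
    )


class TestClusterLocalizationMap:
    def test_dominant_group_labels_cluster(self):
        cats = {f"O{i}": "OMP" for i in range(8)} | {"S0": "cytoplasmic", "S1": "periplasmic"}
        cats |= {f"I{i}": "IM-integral" for i in range(5)}
        ann = gl.AnnotationTable(categories=pd.Series(cats, dtype=object))
        assignments = {f"O{i}": 1 for i in range(8)} | {"S0": 1, "S1": 2} | {
            f"I{i}": 2 for i in range(5)
        }
        cmap = gl.map_clusters_to_localization(toy_model(assignments), ann)
        assert cmap.mapping[1] == "OM"
        assert cmap.mapping[2] == "IM"

    def test_enrichment_beats_raw_majority_under_imbalance(self):
        # 12 soluble + 6 OM in cluster 1: soluble majority, but OM is 6/8 of
        # all OM proteins vs soluble 12/80 - OM enrichment must win
        cats = {f"S{i}": "cytoplasmic" for i in range(80)} | {f"O{i}": "OMP" for i in range(8)}
        cats |= {f"I{i}": "IM-integral" for i in range(5)}
        ann = gl.AnnotationTable(categories=pd.Series(cats, dtype=object))
        assignments = {f"S{i}": 1 if i < 12 else 2 for i in range(80)}
        assignments |= {f"O{i}": 1 if i < 6 else 2 for i in range(8)}
        assignments |= {f"I{i}": 2 for i in range(5)}
        cmap = gl.map_clusters_to_localization(toy_model(assignments), ann)
        assert cmap.mapping[1] == "OM"

    def test_benchmark_free_cluster_defaults_to_soluble(self):
        cats = {"O0": "OMP", "I0": "IM-integral", "S0": "cytoplasmic", "X0": "IM-cyto"}
        ann = gl.AnnotationTable(categories=pd.Series(cats, dtype=object))
        assignments = {"O0": 1, "I0": 2, "S0": 3, "X0": 4}
        cmap = gl.map_clusters_to_localization(toy_model(assignments), ann)
        assert cmap.mapping[4] == "soluble"

    def test_missing_benchmark_group_rejected(self):
        cats = {"I0": "IM-integral", "S0": "cytoplasmic"}
        ann = gl.AnnotationTable(categories=pd.Series(cats, dtype=object))
        with pytest.raises(CalibrationError):
            gl.map_clusters_to_localization(toy_model({"I0": 1, "S0": 2}), ann)


class TestReplicateConsistencyFilter:
    def test_localization_level_comparison(self):
        # cluster ids differ between replicates; what matters is the mapped label
        rep1 = pd.Series({"A": "IM", "B": "IM", "C": "soluble"})
        rep2 = pd.Series({"A": "IM", "B": "soluble", "C": "soluble"})
        out = gl.replicate_consistency_filter(rep1, rep2)
        assert out.loc["A", "replicate_consistent"]
        assert not out.loc["B", "replicate_consistent"]
        assert out.loc["B", "reason"] == "replicate-inconsistency"
        assert out.loc["C", "replicate_consistent"]

    def test_missing_call_is_incomplete(self):
        rep1 = pd.Series({"A": "IM"})
        rep2 = pd.Series({"B": "IM"})
        out = gl.replicate_consistency_filter(rep1, rep2)
        assert not out["replicate_consistent"].any()
        assert (out["reason"] == "incomplete").all()
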