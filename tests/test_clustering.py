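import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from diabclust import run_clustering_pipeline
from diabclust.clustering import (
    ARCHETYPES,
    DiabetesSubtypeClustering,
    kmeans_best_of_runs,
    label_archetypes,
    match_clusters_across_sexes,
    scale_features,
    silhouette,
)
from diabclust.config import CLUSTER_FEATURES
from diabclust.simulate import generate_cohort

from conftest import well_separated_config


def silhouette_bruteforce(X, labels):
    """Loop-based silhouette oracle straight from the definition."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    out = np.zeros(len(X))
    for i in range(len(X)):
        same = (labels == labels[i])
        if same.sum() == 1:
            out[i] = 0.0
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in np.where(same)[0] if j != i])
        b = min(
            np.mean([np.linalg.norm(X[i] - X[j]) for j in np.where(labels == c)[0]])
            for c in np.unique(labels) if c != labels[i]
        )
        denom = max(a, b)
        out[i] = 0.0 if denom == 0 else (b - a) / denom
    return out, float(out.mean())


class TestScaleFeatures:
    def test_hand_example_sample_sd(self):
        df = pd.DataFrame({f: [1.0, 2.0, 3.0] for f in CLUSTER_FEATURES})
        X, params = scale_features(df)
        assert np.allclose(X[:, 0], [-1.0, 0.0, 1.0])  # ddof=1: sd == 1
        assert params.loc["bmi", "mean"] == 2.0 and params.loc["bmi", "sd"] == 1.0

    def test_idempotent_on_zscores(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(40, 5)), columns=CLUSTER_FEATURES)
        df = (df - df.mean()) / df.std(ddof=1)
        X, _ = scale_features(df)
        assert np.allclose(X, df.to_numpy(), atol=1e-12)

    def test_constant_feature_named_in_error(self):
        df = pd.DataFrame({f: [1.0, 2.0, 3.0] for f in CLUSTER_FEATURES})
        df["homa2_ir"] = 5.0
        with pytest.raises(ValueError, match="homa2_ir"):
            scale_features(df)


class TestSilhouette:
    def test_two_separated_pairs(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = np.array([0, 0, 1, 1])
        s, avg = silhouette(X, labels)
        s_ref, avg_ref = silhouette_bruteforce(X, labels)
        assert np.allclose(s, s_ref, atol=1e-12)
        assert avg == pytest.approx(0.99, abs=0.001)

    def test_identical_points_zero_by_convention(self):
        X = np.zeros((4, 2))
        s, avg = silhouette(X, np.array([0, 0, 1, 1]))
        assert np.allclose(s, 0.0) and avg == 0.0

    def test_equidistant_point_scores_zero(self):
        # middle point at 1.0 equidistant (a == b)
        X = np.array([[0.0], [2.0], [1.0], [-0.1], [2.1]])
        labels = np.array([0, 1, 0, 0, 1])
        s, _ = silhouette(X, labels)
        s_ref, _ = silhouette_bruteforce(X, labels)
        assert np.allclose(s, s_ref, atol=1e-12)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette(np.zeros((3, 1)), np.array([0, 0, 0]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, 3))
        labels = rng.integers(0, 3, size=12)
        if len(np.unique(labels)) < 2:
            labels[0] = (labels[0] + 1) % 3
        s, avg = silhouette(X, labels)
        s_ref, avg_ref = silhouette_bruteforce(X, labels)
        assert np.allclose(s, s_ref, atol=1e-10)
        assert avg == pytest.approx(avg_ref, abs=1e-10)


class TestKmeansBestOfRuns:
    def test_separated_pairs_partition(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        sol = kmeans_best_of_runs(X, k=2, runs=10, seed=1)
        assert sol.assignments[0] == sol.assignments[1]
        assert sol.assignments[2] == sol.assignments[3]
        assert sol.assignments[0] != sol.assignments[2]
        assert sol.asw == pytest.approx(0.99, abs=0.001)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 5))
        a = kmeans_best_of_runs(X, k=4, runs=20, seed=42)
        b = kmeans_best_of_runs(X, k=4, runs=20, seed=42)
        assert np.array_equal(a.assignments, b.assignments)
        assert a.asw == b.asw

    def test_matches_exhaustive_sse_minimum_when_rankings_agree(self):
        """On tiny well-separated instances the ASW pick equals the SSE-optimal
        2-partition found by exhausting all assignments."""
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.3, (4, 2)), rng.normal(5, 0.3, (4, 2))])
        best_sse, best_part = np.inf, None
        for mask in range(1, 2**7):  # fix point 0 in cluster 0, non-empty others
            part = np.array([0] + [int(b) for b in f"{mask:07b}"])
            sse = sum(
                ((X[part == c] - X[part == c].mean(axis=0)) ** 2).sum()
                for c in (0, 1)
            )
            if sse < best_sse:
                best_sse, best_part = sse, part
        sol = kmeans_best_of_runs(X, k=2, runs=20, seed=0)
        assert adjusted_rand_score(best_part, sol.assignments) == 1.0

    def test_n_must_exceed_k(self):
        with pytest.raises(ValueError):
            kmeans_best_of_runs(np.zeros((3, 2)), k=4)


class TestCrossSexMatching:
    def test_identity_and_swap(self):
        c = np.arange(20.0).reshape(4, 5)
        assert match_clusters_across_sexes(c, c) == (0, 1, 2, 3)
        swapped = c[[1, 0, 2, 3]]
        assert match_clusters_across_sexes(c, swapped) == (1, 0, 2, 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_hungarian_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(4, 5)), rng.normal(size=(4, 5))
        perm = match_clusters_across_sexes(a, b)
        cost = np.array([[np.linalg.norm(a[i] - b[j]) for j in range(4)] for i in range(4)])
        rows, cols = linear_sum_assignment(cost)
        assert cost[np.arange(4), list(perm)].sum() == pytest.approx(
            cost[rows, cols].sum()
        )

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            match_clusters_across_sexes(np.zeros((4, 5)), np.zeros((4, 4)))


class TestArchetypeLabeling:
    def _centroids(self):
        # rows: hba1c, bmi, age_at_onset, homa2_b, homa2_ir in z-units
        return np.array([
            [1.5, -0.5, -0.5, -1.2, -0.5],  # SIDD-like
            [-0.5, 0.6, -0.2, 0.8, 1.5],    # SIRD-like
            [0.0, 1.5, -0.8, -0.2, 0.8],    # MOD-like
            [-0.4, -0.5, 1.2, 0.0, -0.8],   # MARD-like
        ])

    def test_separable_costs_give_per_axis_argmax(self):
        labels = label_archetypes(self._centroids(), "new_onset")
        assert labels == {0: "SIDD", 1: "SIRD", 2: "MOD", 3: "MARD"}

    def test_long_term_irod_disambiguation_by_homa2_b(self):
        z = self._centroids()
        labels = label_archetypes(z, "long_term", raw_homa2_b=[30, 65.7, 139.4, 55])
        assert labels[1] == "IROD1" and labels[2] == "IROD2"  # 65.7 < 139.4
        flipped = label_archetypes(z, "long_term", raw_homa2_b=[30, 139.4, 65.7, 55])
        assert flipped[1] == "IROD2" and flipped[2] == "IROD1"

    def test_invariant_under_cluster_index_permutation(self):
        z = self._centroids()
        base = label_archetypes(z, "new_onset")
        for perm in itertools.permutations(range(4)):
            perm = list(perm)
            labels = label_archetypes(z[perm], "new_onset")
            assert [labels[i] for i in range(4)] == [base[p] for p in perm]


class TestPipeline:
    def test_all_gada_positive_everyone_said(self, small_cohort):
        df = small_cohort.cohort.df.copy()
        df["gada"] = 10.0
        res = run_clustering_pipeline(df, "new_onset", runs=5, seed=0)
        assert (res.assignments["cluster_label"] == "SAID").all()
        assert (res.assignments["provenance"] == "gada").all()

    def test_said_iff_gada_positive(self, small_cohort):
        df = small_cohort.cohort.df
        res = run_clustering_pipeline(df[df.duration < 3], "new_onset", runs=10, seed=0)
        a = res.assignments
        gada = df.loc[df.duration < 3, "gada"].reset_index(drop=True)
        assert ((a["cluster_label"] == "SAID") == (gada >= 5.0)).all()

    def test_label_sets_per_stratum(self, small_cohort):
        df = small_cohort.cohort.df
        r_new = run_clustering_pipeline(df[df.duration < 3], "new_onset", runs=10, seed=0)
        r_long = run_clustering_pipeline(df[df.duration >= 3], "long_term", runs=10, seed=0)
        assert set(r_new.assignments["cluster_label"]) <= {"SAID", "SIDD", "SIRD", "MOD", "MARD"}
        assert set(r_long.assignments["cluster_label"]) <= {"SAID", "SIDD", "IROD1", "IROD2", "MARD"}

    def test_scaling_equivariance_affine_transform(self, small_cohort):
        """Affine rescaling of a raw feature leaves labels unchanged."""
        df = small_cohort.cohort.df[small_cohort.cohort.df.duration >= 3].copy()
        res1 = run_clustering_pipeline(df, "long_term", runs=10, seed=3)
        df2 = df.copy()
        df2["homa2_b"] = df2["homa2_b"] * 18.0 - 5.0
        res2 = run_clustering_pipeline(df2, "long_term", runs=10, seed=3)
        lab1 = res1.assignments["cluster_label"].to_numpy()
        lab2 = res2.assignments["cluster_label"].to_numpy()
        # archetype naming may shift (raw HOMA2-B scale changed); partition may not
        assert adjusted_rand_score(lab1, lab2) == 1.0

    def test_recovery_on_well_separated_config(self):
        """ARI vs ground truth stays high when centroids are well separated."""
        aris = []
        for seed in (0, 1, 2):
            cfg = well_separated_config(seed, n_new=500, n_long=1)
            syn = generate_cohort(cfg)
            df = syn.cohort.df.merge(syn.truth, on="patient_id")
            part = df[df.stratum == "new_onset"]
            res = run_clustering_pipeline(part, "new_onset", runs=25, seed=seed)
            aris.append(adjusted_rand_score(
                part["truth_cluster"], res.assignments["cluster_label"]
            ))
        assert np.mean(aris) >= 0.8

    def test_estimator_sklearn_contract(self, small_cohort):
        df = small_cohort.cohort.df[small_cohort.cohort.df.duration >= 3]
        est = DiabetesSubtypeClustering(stratum="long_term", runs=5, random_state=1)
        params = est.get_params()
        assert params["runs"] == 5 and params["stratum"] == "long_term"
        est.set_params(runs=8)
        labels = est.fit_predict(df)
        assert len(labels) == len(df)
        assert hasattr(est, "labels_") and hasattr(est, "result_")
        again = DiabetesSubtypeClustering(stratum="long_term", runs=8, random_state=1).fit_predict(df)
        assert np.array_equal(labels, again)
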