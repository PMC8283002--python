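"""GADA-gated, sex-stratified k-means subtype clustering with archetype labels.

The procedure reproduces the published reclassification of adult diabetes:

1. GADA-positive patients (>= 5 U/ml) form the SAID cluster outright.
2. The remainder are z-scored (five features: HbA1c, BMI, age at onset,
   HOMA2-B, HOMA2-IR) and clustered with k-means (k=4, Lloyd, Euclidean),
   separately for men and women, restarting 100 times (k-means++ seeding)
   and keeping the run with the highest average silhouette width (ASW).
3. The two sex-specific solutions are merged by the minimum-cost bijection
   between their scaled centroids (exhaustive over the 4! pairings).
4. Merged clusters are named after the four non-autoimmune archetypes (SIDD,
   SIRD, MOD, MARD) by a cost-minimizing bijection against fixed signature
   directions in z-space; in long-term disease the two insulin-resistant
   obese clusters are renamed IROD1 (lower HOMA2-B) and IROD2 (higher).

The scikit-learn estimator :class:`DiabetesSubtypeClustering` wraps the whole
procedure; the module-level functions implement the individual steps.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances, silhouette_samples

from .config import CLUSTER_FEATURES
from .phenotyping import classify_gada

ARCHETYPES = ("SIDD", "SIRD", "MOD", "MARD")

#: Signature directions in z-space, ordered as CLUSTER_FEATURES
#: (hba1c, bmi, age_at_onset, homa2_b, homa2_ir).
SIGNATURES: Dict[str, np.ndarray] = {
    "SIDD": np.array([1.0, 0.0, 0.0, -1.0, 0.0]),
    "SIRD": np.array([0.0, 0.5, 0.0, 0.0, 1.0]),
    "MOD": np.array([0.0, 1.0, 0.0, 0.0, 0.0]),
    "MARD": np.array([-0.5, 0.0, 1.0, 0.0, 0.0]),
}


def scale_features(
    df: pd.DataFrame, features: Sequence[str] = CLUSTER_FEATURES
) -> Tuple[np.ndarray, pd.DataFrame]:
    """Center and scale features to z-scores (sample SD, ddof=1).

    Returns the scaled matrix and a frame of per-feature mean/SD for
    back-transformation.  A zero-variance feature is an error naming it.
    """
    means = df[list(features)].mean()
    sds = df[list(features)].std(ddof=1)
    zero = sds[~(sds > 0)].index.tolist()
    if zero:
        raise ValueError(f"zero-variance feature(s): {zero}")
    X = ((df[list(features)] - means) / sds).to_numpy(dtype=float)
    params = pd.DataFrame({"mean": means, "sd": sds})
    return X, params


def silhouette(
    X: np.ndarray, labels: np.ndarray, precomputed: bool = False
) -> Tuple[np.ndarray, float]:
    """Per-point silhouette values and their average (Euclidean distance).

    s_i = (b_i - a_i)/max(a_i, b_i); singleton clusters and degenerate 0/0
    cases score 0.  Requires >= 2 non-empty clusters.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    metric = "precomputed" if precomputed else "euclidean"
    with np.errstate(divide="ignore", invalid="ignore"):
        s = silhouette_samples(X, labels, metric=metric)
    s = np.nan_to_num(s, nan=0.0)
    return s, float(s.mean())


@dataclass
class ClusterSolution:
    """One sex stratum's best-of-runs k-means partition."""

    assignments: np.ndarray  # 0..k-1 per point
    centers: np.ndarray  # k x p, scaled space
    asw: float
    scaling: pd.DataFrame  # per-feature mean/sd used for this stratum
    n_runs: int
    seed: int


def kmeans_best_of_runs(
    X: np.ndarray,
    k: int = 4,
    runs: int = 100,
    max_iter: int = 100,
    seed: int = 0,
    scaling: Optional[pd.DataFrame] = None,
) -> ClusterSolution:
    """Lloyd k-means restarted ``runs`` times from k-means++ seedings; the
    partition with the highest average silhouette width wins.

    Runs that collapse below ``k`` non-empty clusters are discarded and
    redrawn (up to 10x ``runs`` attempts); ties in ASW keep the earliest run.
    Deterministic under ``seed``.
    """
    n = X.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} points, got {n}")
    # one pairwise-distance matrix shared by all silhouette evaluations
    D = pairwise_distances(X) if n <= 5000 else None
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(10 * runs)]
    best: Tuple[float, int, Optional[np.ndarray], Optional[np.ndarray]] = (-2.0, -1, None, None)
    done = attempt = 0
    while done < runs:
        if attempt >= len(child_seeds):
            raise RuntimeError("all k-means runs degenerate")
        km = KMeans(
            n_clusters=k, init="k-means++", n_init=1, max_iter=max_iter,
            algorithm="lloyd", random_state=child_seeds[attempt],
        )
        attempt += 1
        labels = km.fit_predict(X)
        if len(np.unique(labels)) < k:
            continue  # degenerate run: redraw
        if D is not None:
            _, asw = silhouette(D, labels, precomputed=True)
        else:
            _, asw = silhouette(X, labels)
        if asw > best[0]:
            best = (asw, done, labels, km.cluster_centers_)
        done += 1
    asw, _, labels, centers = best
    return ClusterSolution(
        assignments=labels, centers=centers, asw=asw,
        scaling=scaling if scaling is not None else pd.DataFrame(),
        n_runs=runs, seed=seed,
    )


def match_clusters_across_sexes(
    centers_a: np.ndarray, centers_b: np.ndarray
) -> Tuple[int, ...]:
    """Pair the clusters of two solutions by their scaled centroids.

    Returns the permutation ``p`` (exhaustive over k!) minimizing
    ``sum_i ||centers_a[i] - centers_b[p[i]]||``, i.e. cluster ``p[i]`` of
    solution b corresponds to cluster ``i`` of solution a.
    """
    a, b = np.asarray(centers_a, float), np.asarray(centers_b, float)
    if a.shape != b.shape:
        raise ValueError(f"centroid shape mismatch: {a.shape} vs {b.shape}")
    k = a.shape[0]
    best_perm, best_cost = None, np.inf
    for perm in itertools.permutations(range(k)):
        cost = sum(np.linalg.norm(a[i] - b[perm[i]]) for i in range(k))
        if cost < best_cost - 1e-12:
            best_cost, best_perm = cost, perm
    return best_perm


def label_archetypes(
    z_centroids: np.ndarray,
    stratum: str,
    raw_homa2_b: Optional[Sequence[float]] = None,
) -> Dict[int, str]:
    """Name k=4 clusters after the non-autoimmune archetypes.

    ``z_centroids`` is 4 x 5 in CLUSTER_FEATURES order, in z-space of the
    clustered pool.  Cost of assigning cluster c to archetype a is the negative
    dot product of the centroid with the archetype signature; the
    cost-minimizing bijection (exhaustive, ties broken by lexicographic
    archetype order) is returned.  In the long-term stratum the SIRD- and
    MOD-slot clusters are renamed IROD1/IROD2 by ascending raw HOMA2-B.
    """
    Z = np.asarray(z_centroids, float)
    if Z.shape != (4, len(CLUSTER_FEATURES)):
        raise ValueError(f"expected 4x{len(CLUSTER_FEATURES)} centroids, got {Z.shape}")
    cost = {(c, a): -float(Z[c] @ SIGNATURES[a]) for c in range(4) for a in ARCHETYPES}
    best_perm, best_cost = None, np.inf
    for names in itertools.permutations(sorted(ARCHETYPES)):
        total = sum(cost[c, names[c]] for c in range(4))
        if total < best_cost - 1e-12:
            best_cost, best_perm = total, names
    labels = {c: best_perm[c] for c in range(4)}
    if stratum == "long_term":
        if raw_homa2_b is None:
            raise ValueError("long-term labeling needs raw HOMA2-B centroids")
        sird = next(c for c, a in labels.items() if a == "SIRD")
        mod = next(c for c, a in labels.items() if a == "MOD")
        if raw_homa2_b[sird] <= raw_homa2_b[mod]:
            labels[sird], labels[mod] = "IROD1", "IROD2"
        else:
            labels[sird], labels[mod] = "IROD2", "IROD1"
    return labels


@dataclass
class LabeledClustering:
    """Final per-patient subtype labels plus solution metadata."""

    assignments: pd.DataFrame  # patient_id, sex, stratum, cluster_label, provenance, silhouette
    centroids: pd.DataFrame  # per final label x feature: raw mean/sd and z of centroid
    solutions: Dict[str, ClusterSolution] = field(default_factory=dict)
    correspondence: Optional[Tuple[int, ...]] = None
    label_map: Dict[int, str] = field(default_factory=dict)


class DiabetesSubtypeClustering(ClusterMixin, BaseEstimator):
    """Sex-stratified k-means reclassification of adult diabetes.

    Parameters
    ----------
    stratum : "new_onset" or "long_term"
        Controls the archetype label set (MARD/MOD/SIRD vs IROD1/IROD2).
    k, runs, max_iter : int
        k-means size and the best-of-runs restart schedule (ASW criterion).
    scale_within_sex : bool
        z-score within sex stratum (default) or on the pooled GADA-negative
        stratum.
    include_gada_unknown : bool
        Whether patients without a GADA measurement enter k-means.
    random_state : int
        Seed for every stochastic step.

    Attributes
    ----------
    labels_ : ndarray of final subtype labels per input row.
    result_ : :class:`LabeledClustering` with centroids and solution metadata.
    """

    def __init__(
        self,
        stratum: str = "new_onset",
        k: int = 4,
        runs: int = 100,
        max_iter: int = 100,
        scale_within_sex: bool = True,
        include_gada_unknown: bool = True,
        random_state: int = 0,
    ):
        self.stratum = stratum
        self.k = k
        self.runs = runs
        self.max_iter = max_iter
        self.scale_within_sex = scale_within_sex
        self.include_gada_unknown = include_gada_unknown
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "DiabetesSubtypeClustering":
        """Cluster a phenotyped cohort frame.

        ``X`` needs the five clustering features plus ``sex`` and either a
        ``gada`` concentration or a ``gada_status`` column.
        """
        df = X.reset_index(drop=True)
        missing = [c for c in (*CLUSTER_FEATURES, "sex") if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if "gada_status" in df.columns:
            status = df["gada_status"].astype(str)
        elif "gada" in df.columns:
            status = classify_gada(df["gada"])
        else:
            status = pd.Series("unknown", index=df.index)

        out = pd.DataFrame({
            "patient_id": df.get("patient_id", pd.Series(np.arange(len(df)).astype(str))),
            "sex": df["sex"],
            "stratum": self.stratum,
            "cluster_label": "",
            "provenance": "",
            "silhouette": np.nan,
        })
        said = status == "positive"
        out.loc[said, "cluster_label"] = "SAID"
        out.loc[said, "provenance"] = "gada"
        eligible = ~said if self.include_gada_unknown else (status == "negative")
        out.loc[~said & ~eligible, "cluster_label"] = "UNCLASSIFIED"
        pool = df[eligible]

        solutions: Dict[str, ClusterSolution] = {}
        if len(pool) == 0:  # degenerate gate: everyone SAID
            self.result_ = LabeledClustering(assignments=out, centroids=pd.DataFrame())
            self.labels_ = out["cluster_label"].to_numpy()
            return self

        ss = np.random.SeedSequence(self.random_state)
        sex_seeds = {s: int(c.generate_state(1)[0] % (2**31 - 1))
                     for s, c in zip(("male", "female"), ss.spawn(2))}
        pooled_X, pooled_params = scale_features(pool)
        idx_by_sex: Dict[str, pd.Index] = {}
        for sex in ("male", "female"):
            sub = pool[pool["sex"] == sex]
            if len(sub) == 0:
                continue
            if self.scale_within_sex:
                Xs, params = scale_features(sub)
            else:
                Xs = pooled_X[(pool["sex"] == sex).to_numpy()]
                params = pooled_params
            sol = kmeans_best_of_runs(
                Xs, k=self.k, runs=self.runs, max_iter=self.max_iter,
                seed=sex_seeds[sex], scaling=params,
            )
            solutions[sex] = sol
            idx_by_sex[sex] = sub.index

        # merge the two sex solutions: reference = male indices
        merged = pd.Series(-1, index=pool.index, dtype=int)
        corr: Optional[Tuple[int, ...]] = None
        if len(solutions) == 2:
            corr = match_clusters_across_sexes(
                solutions["male"].centers, solutions["female"].centers
            )
            inv = {corr[i]: i for i in range(self.k)}
            merged.loc[idx_by_sex["male"]] = solutions["male"].assignments
            merged.loc[idx_by_sex["female"]] = [
                inv[a] for a in solutions["female"].assignments
            ]
        else:
            only = next(iter(solutions))
            merged.loc[idx_by_sex[only]] = solutions[only].assignments

        # merged centroids: raw means per cluster, z relative to the pooled stratum
        raw_means = pool.groupby(merged)[list(CLUSTER_FEATURES)].mean()
        z_cent = (
            (raw_means - pooled_params["mean"]) / pooled_params["sd"]
        ).to_numpy()
        label_map = label_archetypes(
            z_cent, self.stratum, raw_homa2_b=raw_means["homa2_b"].to_numpy()
        )
        out.loc[pool.index, "cluster_label"] = merged.map(label_map)
        out.loc[pool.index, "provenance"] = "kmeans"
        for sex, sol in solutions.items():
            sil, _ = (
                silhouette(
                    sol.scaling.pipe(lambda p: ((pool.loc[idx_by_sex[sex], list(CLUSTER_FEATURES)] - p["mean"]) / p["sd"]).to_numpy(float)),
                    sol.assignments,
                )
            )
            out.loc[idx_by_sex[sex], "silhouette"] = sil

        cent = raw_means.copy()
        cent.index = [label_map[i] for i in cent.index]
        cent.index.name = "cluster_label"
        for j, f in enumerate(CLUSTER_FEATURES):
            cent[f"z_{f}"] = z_cent[:, j]
        cent["n"] = pool.groupby(merged).size().to_numpy()

        self.result_ = LabeledClustering(
            assignments=out, centroids=cent, solutions=solutions,
            correspondence=corr, label_map=label_map,
        )
        self.labels_ = out["cluster_label"].to_numpy()
        self.asw_ = {s: sol.asw for s, sol in solutions.items()}
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).labels_


def run_clustering_pipeline(
    df: pd.DataFrame,
    stratum: str,
    k: int = 4,
    runs: int = 100,
    max_iter: int = 100,
    seed: int = 0,
    scale_within_sex: bool = True,
    include_gada_unknown: bool = True,
) -> LabeledClustering:
    """Functional wrapper over :class:`DiabetesSubtypeClustering`."""
    est = DiabetesSubtypeClustering(
        stratum=stratum, k=k, runs=runs, max_iter=max_iter,
        scale_within_sex=scale_within_sex,
        include_gada_unknown=include_gada_unknown, random_state=seed,
    )
    est.fit(df)
    return est.result_
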