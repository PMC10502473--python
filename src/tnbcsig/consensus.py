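"""Consensus clustering over forest dissimilarities with CDF-based k selection.

Each repetition subsamples a fraction of the features (all samples are always
included), computes the unsupervised conditional-forest dissimilarity, and
partitions the samples by deterministic PAM (k-medoids) at every candidate k.
The per-k consensus matrix holds the fraction of repetitions in which two
samples co-cluster. The number of clusters is chosen from the change in area
under the consensus CDF: the largest k whose relative area increase exceeds a
threshold (the published analyses chose k by examination of these curves, so
the full curve is always returned for manual override).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .forest import forest_dissimilarity

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusClusteringResult",
    "ForestConsensusCluster",
    "consensus_cluster",
    "cdf_area",
    "select_k",
    "assign_clusters",
]

MIN_CLUSTER_SIZE_WARN = 5


@dataclass
class ConsensusClusteringResult:
    """Per-k consensus matrices, CDF areas, the selected k and final labels."""

    k_range: list[int]
    consensus: dict[int, np.ndarray]
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    selected_k: int
    labels: np.ndarray
    sample_ids: list
    seed: int
    per_rep_labels: dict[int, np.ndarray] | None = field(default=None, repr=False)

    def labels_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.sample_ids, name="cluster")


def _cut_distance(dist: np.ndarray, k: int) -> np.ndarray:
    """Average-linkage partition of a square distance matrix into k clusters."""
    condensed = squareform(dist, checks=False)
    z = linkage(condensed, method="average")
    return fcluster(z, t=k, criterion="maxclust")


def _pam_partition(dist: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Deterministic PAM (k-medoids) partition of a square distance matrix.

    Greedy BUILD initialisation followed by best-improvement SWAP steps;
    fully determined by the distance matrix (argmin ties go to the lowest
    index), hence reproducible without a random state. Medoid-based
    partitioning is robust to the stray borderline samples that make
    agglomerative cuts shave off singletons.
    """
    n = dist.shape[0]
    if k >= n:
        return np.arange(1, n + 1)
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        dmin = dist[:, medoids].min(axis=1)
        gains = np.maximum(dmin[:, None] - dist, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = np.array(medoids)
    for _ in range(max_iter):
        cost = dist[:, medoids].min(axis=1).sum()
        best_delta, best_swap = -1e-12, None
        for mi in range(k):
            others = np.delete(medoids, mi)
            dmin_o = dist[:, others].min(axis=1)
            cand_cost = np.minimum(dmin_o[:, None], dist).sum(axis=0)
            cand_cost[medoids] = np.inf
            ci = int(np.argmin(cand_cost))
            delta = cost - cand_cost[ci]
            if delta > best_delta:
                best_delta, best_swap = delta, (mi, ci)
        if best_swap is None or best_delta <= 1e-12:
            break
        medoids[best_swap[0]] = best_swap[1]
    return dist[:, medoids].argmin(axis=1) + 1


def cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus entries.

    Trapezoid rule over the consensus values in [0, 1]; larger areas mean the
    entries sit nearer 0/1, i.e. a cleaner partition.
    """
    iu = np.triu_indices(consensus.shape[0], k=1)
    vals = np.sort(consensus[iu])
    grid = np.concatenate([[0.0], vals, [1.0]])
    n = vals.size
    cdf = np.concatenate([[0.0], (np.arange(n) + 1) / n, [1.0]])
    return float(np.trapezoid(cdf, grid))


def select_k(areas: dict[int, float], threshold: float = 0.1) -> tuple[int, dict[int, float]]:
    """Choose k from per-k CDF areas by the relative-increase rule.

    delta_area(k) is the relative increase of the area over k-1, clamped at 0
    (the first candidate k's delta is its own area). The selected k is the
    largest candidate whose delta exceeds ``threshold``.
    """
    ks = sorted(areas)
    if len(ks) < 2:
        raise ValueError("need at least 2 candidate k values")
    delta: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            delta[k] = max(0.0, (areas[k] - prev) / prev) if prev > 0 else 0.0
    above = [k for k in ks if delta[k] > threshold]
    selected = max(above) if above else ks[0]
    return selected, delta


def assign_clusters(consensus: np.ndarray, k: int) -> np.ndarray:
    """Final labels: average-linkage cut of 1 - consensus at k clusters.

    Label ids are 1..k ordered by descending cluster size (ties by first
    occurrence); deterministic in the consensus matrix alone.
    """
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    raw = _cut_distance(dist, k)
    order = sorted(
        np.unique(raw),
        key=lambda lab: (-np.sum(raw == lab), np.argmax(raw == lab)),
    )
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    labels = np.array([remap[lab] for lab in raw])
    sizes = np.bincount(labels)[1:]
    for lab, size in enumerate(sizes, start=1):
        if size < MIN_CLUSTER_SIZE_WARN:
            logger.warning("cluster %d has only %d samples (kept, not merged)", lab, size)
    return labels


class ForestConsensusCluster(ClusterMixin, BaseEstimator):
    """Consensus conditional-inference-forest clustering of mixed features.

    Parameters
    ----------
    k_range : sequence of int, default (2, 3, 4, 5, 6)
        Candidate numbers of clusters.
    n_reps : int, default 100
        Consensus repetitions; each draws a feature subsample.
    feature_frac : float, default 0.8
        Fraction of features (continuous or categorical, each one unit) drawn
        without replacement per repetition, rounded up.
    n_trees : int, default 50
        Trees per repetition's forest. The consensus already averages
        ``n_reps`` forests, so a moderate per-repetition ensemble suffices;
        use :func:`~tnbcsig.forest.forest_dissimilarity` directly (500-tree
        default) for a single-forest dissimilarity.
    alpha : float, default 0.05
        Stopping level of the split-selection association test.
    delta_area_threshold : float, default 0.1
        Relative CDF-area increase required to accept a larger k.
    random_state : int, default 0
        Seed for feature subsampling and (when ``vary_forest_seed``) the
        per-repetition forests.
    vary_forest_seed : bool, default True
        Draw a fresh forest seed per repetition, so forest randomness adds to
        the feature-subsample perturbation (needed when few distinct feature
        subsets exist). With ``False`` the forest seed is fixed: the feature
        subsample is the only perturbation, and ``feature_frac=1`` yields a
        consensus matrix of exact 0/1 entries.
    store_rep_labels : bool, default False
        Keep the per-repetition labels for audit.

    Attributes
    ----------
    labels_ : ndarray
        Final cluster labels (1..selected_k, ordered by descending size).
    selected_k_ : int
        Number of clusters chosen by the delta-area rule.
    consensus_ : dict of int -> ndarray
        Per-k consensus matrices (symmetric, unit diagonal, entries in [0,1]).
    cdf_area_, delta_area_ : dict of int -> float
        Consensus CDF areas and their relative increases.
    result_ : ConsensusClusteringResult
        The full result object.
    """

    def __init__(self, k_range=(2, 3, 4, 5, 6), n_reps: int = 100,
                 feature_frac: float = 0.8, n_trees: int = 50, alpha: float = 0.05,
                 delta_area_threshold: float = 0.1, random_state: int = 0,
                 vary_forest_seed: bool = True, store_rep_labels: bool = False):
        self.k_range = k_range
        self.n_reps = n_reps
        self.feature_frac = feature_frac
        self.n_trees = n_trees
        self.alpha = alpha
        self.delta_area_threshold = delta_area_threshold
        self.random_state = random_state
        self.vary_forest_seed = vary_forest_seed
        self.store_rep_labels = store_rep_labels

    def fit(self, X: pd.DataFrame, y=None) -> "ForestConsensusCluster":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X)
        n, p = X.shape
        k_range = sorted(int(k) for k in self.k_range)
        if not k_range or k_range[0] < 2 or k_range[-1] > n - 1:
            raise ValueError(f"k_range must lie within [2, {n - 1}]")
        if not 0 < self.feature_frac <= 1:
            raise ValueError("feature_frac must be in (0, 1]")
        rng = np.random.default_rng(self.random_state)
        n_draw = int(np.ceil(self.feature_frac * p))
        counts = {k: np.zeros((n, n)) for k in k_range}
        rep_labels: dict[int, list] = {k: [] for k in k_range} if self.store_rep_labels else None
        for rep in range(self.n_reps):
            cols = np.sort(rng.choice(p, size=n_draw, replace=False))
            sub = X.iloc[:, cols]
            entropy = [int(self.random_state) % (2**31)]
            if self.vary_forest_seed:
                entropy.append(rep)
            dist = forest_dissimilarity(
                sub, n_trees=self.n_trees,
                seed=np.random.default_rng(np.random.SeedSequence(entropy)),
                alpha=self.alpha,
            )
            for k in k_range:
                labels = _pam_partition(dist, k)
                same = labels[:, None] == labels[None, :]
                counts[k] += same
                if rep_labels is not None:
                    rep_labels[k].append(labels)
        consensus = {}
        for k in k_range:
            mat = counts[k] / self.n_reps
            np.fill_diagonal(mat, 1.0)
            consensus[k] = mat
        areas = {k: cdf_area(consensus[k]) for k in k_range}
        selected, delta = select_k(areas, self.delta_area_threshold)
        labels = assign_clusters(consensus[selected], selected)
        self.consensus_ = consensus
        self.cdf_area_ = areas
        self.delta_area_ = delta
        self.selected_k_ = selected
        self.labels_ = labels
        self.result_ = ConsensusClusteringResult(
            k_range=k_range,
            consensus=consensus,
            cdf_area=areas,
            delta_area=delta,
            selected_k=selected,
            labels=labels,
            sample_ids=list(X.index),
            seed=self.random_state,
            per_rep_labels=(
                {k: np.array(v) for k, v in rep_labels.items()} if rep_labels else None
            ),
        )
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def consensus_cluster(
    features: pd.DataFrame,
    k_range=(2, 3, 4, 5, 6),
    n_reps: int = 100,
    feature_frac: float = 0.8,
    seed: int = 0,
    **kwargs,
) -> ConsensusClusteringResult:
    """Functional wrapper over :class:`ForestConsensusCluster`."""
    est = ForestConsensusCluster(
        k_range=k_range, n_reps=n_reps, feature_frac=feature_frac,
        random_state=seed, **kwargs,
    )
    return est.fit(features).result_
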