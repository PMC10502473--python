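"""Unsupervised conditional-inference-forest dissimilarity for mixed data.

The forest discriminates the real samples from a synthetic contrast set built
by independently permuting each feature column, which destroys the joint
dependence structure while preserving the marginals. Trees choose splits by
an association-test criterion: at each node the candidate feature with the
smallest Bonferroni-adjusted permutation-test p value (asymptotic linear
statistic for continuous features, chi-square for categoricals) is selected,
and growth stops when no adjusted p value falls below the stopping alpha.

The proximity between two real samples is the fraction of trees in which they
share a terminal node; the returned dissimilarity is 1 - proximity. Mixed
continuous/categorical features are handled natively (categoricals are split
by level subsets, ordered by class rate).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["forest_dissimilarity", "prepare_features"]

_MIN_SPLIT = 10  # smallest node that may be split further
_MIN_LEAF = 3  # smallest admissible child node


def prepare_features(features: pd.DataFrame):
    """Encode a mixed-type feature table as a float matrix plus type flags.

    Categorical/object/bool columns are encoded as level codes; the boolean
    flag array marks them so tree splits treat codes as unordered levels.
    """
    if features.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if features.shape[1] < 1:
        raise ValueError("need at least 1 feature")
    cols, is_cat = [], []
    for name in features.columns:
        col = features[name]
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            values = col.to_numpy(dtype=float)
            if not np.isfinite(values).all():
                raise ValueError(f"feature {name!r} contains non-finite values")
            cols.append(values)
            is_cat.append(False)
        else:
            codes = pd.Categorical(col).codes.astype(float)
            if (codes < 0).any():
                raise ValueError(f"feature {name!r} contains missing values")
            cols.append(codes)
            is_cat.append(True)
    x = np.column_stack(cols)
    if all(np.all(c == c[0]) for c in cols):
        raise ValueError("all features are constant: no splits possible")
    return x, np.asarray(is_cat)


def _split_pvalue_continuous(x: np.ndarray, y: np.ndarray) -> float:
    """Asymptotic permutation-test p for association of x with binary y.

    The standardized linear statistic of the conditional-inference framework
    reduces to z = r * sqrt(n - 1) for a single continuous transformation.
    """
    n = x.size
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return 1.0
    r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    z = abs(r) * np.sqrt(n - 1)
    return float(2.0 * sps.norm.sf(z))


def _split_pvalue_categorical(x: np.ndarray, y: np.ndarray) -> float:
    """Chi-square independence p for a coded categorical feature vs binary y."""
    levels, inv = np.unique(x, return_inverse=True)
    if levels.size < 2:
        return 1.0
    counts = np.zeros((levels.size, 2))
    np.add.at(counts, (inv, y.astype(int)), 1.0)
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    expected = row @ col / counts.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0).sum()
    return float(sps.chi2.sf(chi2, df=levels.size - 1))


def _best_cutpoint(x: np.ndarray, y: np.ndarray):
    """Cutpoint maximizing the standardized two-sample statistic on y.

    Works on a continuous feature or on categorical codes re-ordered by class
    rate. Returns (threshold, left_mask) or None when no admissible split
    leaves both children with at least ``_MIN_LEAF`` samples.
    """
    n = x.size
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    csum = np.cumsum(ys)
    total = csum[-1]
    var_y = y.var()
    if var_y == 0:
        return None
    sizes = np.arange(1, n)  # left-child sizes for split after position i
    valid = (xs[:-1] < xs[1:]) & (sizes >= _MIN_LEAF) & (n - sizes >= _MIN_LEAF)
    if not valid.any():
        return None
    mean_y = total / n
    expect = sizes * mean_y
    var = sizes * (n - sizes) / (n - 1) * var_y
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(valid, np.abs(csum[:-1] - expect) / np.sqrt(var), -np.inf)
    i = int(np.argmax(z))
    if not np.isfinite(z[i]):
        return None
    threshold = 0.5 * (xs[i] + xs[i + 1])
    return threshold, x <= threshold


class _Tree:
    """One conditional-inference tree; arrays of node descriptions."""

    __slots__ = ("feature", "threshold", "left_levels", "children", "n_nodes")

    def __init__(self):
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.left_levels: list[frozenset | None] = []
        self.children: list[tuple[int, int] | None] = []
        self.n_nodes = 0

    def _new_node(self) -> int:
        self.feature.append(-1)
        self.threshold.append(np.nan)
        self.left_levels.append(None)
        self.children.append(None)
        self.n_nodes += 1
        return self.n_nodes - 1

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Terminal-node id for each row of x."""
        leaves = np.zeros(x.shape[0], dtype=np.intp)
        stack = [(0, np.arange(x.shape[0]))]
        while stack:
            node, rows = stack.pop()
            if self.children[node] is None:
                leaves[rows] = node
                continue
            f = self.feature[node]
            if self.left_levels[node] is not None:
                go_left = np.isin(x[rows, f], list(self.left_levels[node]))
            else:
                go_left = x[rows, f] <= self.threshold[node]
            left, right = self.children[node]
            stack.append((left, rows[go_left]))
            stack.append((right, rows[~go_left]))
        return leaves


def _grow_tree(x, y, is_cat, mtry, alpha, rng, force_depth=3) -> _Tree:
    tree = _Tree()
    root = tree._new_node()
    n_feat = x.shape[1]
    stack = [(root, np.arange(x.shape[0]), 0)]
    while stack:
        node, rows, depth = stack.pop()
        yn = y[rows]
        if rows.size < _MIN_SPLIT or yn.min() == yn.max():
            continue
        candidates = rng.choice(n_feat, size=min(mtry, n_feat), replace=False)
        best_p, best_f = np.inf, -1
        tested = 0
        for f in candidates:
            xf = x[rows, f]
            if xf.min() == xf.max():
                continue
            tested += 1
            p = (_split_pvalue_categorical(xf, yn) if is_cat[f]
                 else _split_pvalue_continuous(xf, yn))
            if p < best_p:
                best_p, best_f = p, f
        if best_f < 0:
            continue
        # The permuted contrast matches every feature's marginal, so a node
        # whose real samples still mix clusters can show no single-feature
        # association; the signal is conditional and only emerges once the
        # node is stratified. Splits (on the min-p candidate) are therefore
        # forced down to force_depth; the alpha stop governs below that.
        if depth >= force_depth and best_p > alpha:
            continue
        xf = x[rows, best_f]
        if is_cat[best_f]:
            # order levels by class rate, then scan as if ordinal
            levels = np.unique(xf)
            rates = np.array([yn[xf == lv].mean() for lv in levels])
            rank_of = {lv: r for r, lv in zip(np.argsort(np.argsort(rates)), levels)}
            ordinal = np.array([rank_of[v] for v in xf], dtype=float)
            cut = _best_cutpoint(ordinal, yn)
            if cut is None:
                continue
            threshold, left_mask = cut
            left_levels = frozenset(lv for lv in levels if rank_of[lv] <= threshold)
            tree.left_levels[node] = left_levels
        else:
            cut = _best_cutpoint(xf, yn)
            if cut is None:
                continue
            threshold, left_mask = cut
            tree.threshold[node] = threshold
        tree.feature[node] = int(best_f)
        left = tree._new_node()
        right = tree._new_node()
        tree.children[node] = (left, right)
        stack.append((left, rows[left_mask], depth + 1))
        stack.append((right, rows[~left_mask], depth + 1))
    return tree


def forest_dissimilarity(
    features: pd.DataFrame,
    n_trees: int = 500,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    mtry: int | None = None,
    subsample: float = 0.632,
    force_depth: int = 3,
) -> np.ndarray:
    """Sample-by-sample dissimilarity from an unsupervised conditional forest.

    Parameters
    ----------
    features : DataFrame
        Samples in rows; mixed continuous/categorical columns.
    n_trees : int
        Number of trees.
    seed : int or Generator
        Randomness source for the synthetic contrast set, per-tree row
        subsampling and feature subsets.
    alpha : float
        Stopping level for the split-selection association test: a node is
        not split when the smallest candidate p value exceeds it.
    mtry : int, optional
        Candidate features per node; default ``ceil(sqrt(n_features))``.
    subsample : float
        Fraction of rows (real + synthetic) grown on per tree, without
        replacement.
    force_depth : int
        Depth down to which splits are made unconditionally (still on the
        min-p candidate feature); the alpha stop applies below. Needed
        because the permuted contrast carries no marginal signal: the
        real-vs-synthetic dependence is only visible conditionally.

    Returns
    -------
    ndarray
        Symmetric matrix ``1 - proximity`` with zero diagonal, entries in
        [0, 1].
    """
    x_real, is_cat = prepare_features(features)
    n, p = x_real.shape
    rng = np.random.default_rng(seed)
    if mtry is None:
        mtry = max(1, int(np.ceil(np.sqrt(p))))
    y_all = np.concatenate([np.ones(n), np.zeros(n)])
    n_all = 2 * n
    n_sub = max(_MIN_SPLIT, int(round(subsample * n_all)))
    prox = np.zeros((n, n))
    for _ in range(n_trees):
        # fresh synthetic contrast per tree: each feature permuted
        # independently, destroying the joint structure but not the marginals
        x_syn = np.column_stack([rng.permutation(x_real[:, j]) for j in range(p)])
        x_all = np.vstack([x_real, x_syn])
        rows = rng.choice(n_all, size=min(n_sub, n_all), replace=False)
        tree = _grow_tree(x_all[rows], y_all[rows], is_cat, mtry, alpha, rng,
                          force_depth=force_depth)
        leaves = tree.apply(x_real)
        for leaf in np.unique(leaves):
            idx = np.flatnonzero(leaves == leaf)
            prox[np.ix_(idx, idx)] += 1.0
    prox /= n_trees
    dist = 1.0 - prox
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 1.0)
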