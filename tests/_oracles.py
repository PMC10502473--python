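"""Independent brute-force recomputations of every scoring scheme.

These deliberately avoid the package's vectorised implementations: plain
loops, direct formula transcription, scipy primitives only. They exist so the
scoring module can be checked against a second, independently written path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps


def mean_centered(log2_expr: pd.DataFrame, genes) -> np.ndarray:
    present = [g for g in genes if g in log2_expr.index]
    out = []
    for sample in log2_expr.columns:
        vals = []
        for g in present:
            row = log2_expr.loc[g]
            vals.append(log2_expr.loc[g, sample] - row.mean())
        out.append(np.mean(vals))
    return np.array(out)


def weighted_normalized(expr, genes, weights, norm_genes, boundaries, bias, pseudocount=1.0):
    shifted = expr + pseudocount
    log_ratios = {}
    for g in genes:
        vals = []
        for sample in expr.columns:
            gm = np.exp(np.mean([np.log(shifted.loc[ng, sample]) for ng in norm_genes]))
            vals.append(np.log2(shifted.loc[g, sample] / gm))
        log_ratios[g] = np.array(vals)
    out = np.zeros(expr.shape[1])
    for g, w in zip(genes, weights):
        centred = log_ratios[g] - np.median(log_ratios[g])
        if boundaries is not None:
            centred = np.clip(centred, boundaries[0], boundaries[1])
        out = out + w * centred
    return out + bias


def nearest_centroid(log2_expr, genes, centroids):
    labels, corrs = [], []
    shared = [g for g in genes if g in log2_expr.index]
    for sample in log2_expr.columns:
        profile = [log2_expr.loc[g, sample] for g in shared]
        rhos = {}
        for lab, cent in centroids.items():
            rho, _ = sps.spearmanr(profile, [cent[g] for g in shared])
            rhos[lab] = rho
        best = max(centroids, key=lambda lab: rhos[lab])
        labels.append(best)
        corrs.append(rhos)
    return labels, corrs


def negated_sum(log2_expr, genes):
    out = np.zeros(log2_expr.shape[1])
    for g in genes:
        centred = log2_expr.loc[g] - log2_expr.loc[g].median()
        out = out - centred.to_numpy()
    return out


def median_log2(log2_expr, genes):
    present = [g for g in genes if g in log2_expr.index]
    return np.array([
        np.median([log2_expr.loc[g, s] for g in present]) for s in log2_expr.columns
    ])


def first_pc(log2_expr, genes):
    sub = log2_expr.loc[[g for g in genes if g in log2_expr.index]].to_numpy()
    centred = sub - sub.mean(axis=1, keepdims=True)
    cov = np.cov(centred, rowvar=True, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    loading = eigvecs[:, -1]
    scores = centred.T @ loading
    if np.corrcoef(scores, sub.mean(axis=0))[0, 1] < 0:
        scores = -scores
    return scores


def enrichment_raw(expr, genes, alpha):
    """Running-sum statistic written as an explicit per-position loop."""
    out = []
    gene_ids = list(expr.index)
    n = len(gene_ids)
    in_set = {g for g in genes if g in expr.index}
    n_out = n - len(in_set)
    for sample in expr.columns:
        col = expr[sample]
        ranks = sps.rankdata(col.to_numpy())
        order = sorted(range(n), key=lambda i: (-col.iloc[i], i))
        total_w = sum(ranks[i] ** alpha for i in order if gene_ids[i] in in_set)
        es, cum_in, cum_out = 0.0, 0.0, 0.0
        for i in order:
            if gene_ids[i] in in_set:
                cum_in += ranks[i] ** alpha / total_w
            else:
                cum_out += 1.0 / n_out if n_out else 0.0
            es += cum_in - cum_out
        out.append(es)
    return np.array(out)


def linear_weighted(expr, genes, weights, bias):
    out = np.full(expr.shape[1], bias, dtype=float)
    for g, w in zip(genes, weights):
        if g in expr.index:
            out = out + w * expr.loc[g].to_numpy()
    return out


def select_top(de, cell_type, lfc_min, fdr_max, n_top):
    rows = [r for _, r in de.iterrows()
            if r["cell_type"] == cell_type and r["log_fold_change"] > lfc_min
            and r["fdr"] < fdr_max]
    rows.sort(key=lambda r: (-r["log_fold_change"], r["fdr"], r["gene_id"]))
    return [r["gene_id"] for r in rows[:n_top]]


def random_expression(rng, n_genes=10, n_samples=8) -> pd.DataFrame:
    values = rng.uniform(0.0, 200.0, size=(n_genes, n_samples))
    return pd.DataFrame(
        values,
        index=[f"G{i:03d}" for i in range(n_genes)],
        columns=[f"S{j:02d}" for j in range(n_samples)],
    )
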