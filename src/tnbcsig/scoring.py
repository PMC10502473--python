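"""Transcriptional signature scoring from an FPKM-scale expression matrix.

Expression matrices are pandas DataFrames with genes in rows (index = gene
identifiers) and samples in columns. Eight scoring schemes are supported,
dispatched by the ``scheme`` tag of each :class:`~tnbcsig.registry.SignatureDefinition`:

``mean_centered``
    log2 values mean-centred per gene across the cohort; score = mean of
    centred values over the signature genes (CIN70-style).
``weighted_normalized``
    signature genes divided by the geometric mean of normalization genes,
    log2-transformed, median-centred per gene, optionally clipped to
    boundaries, then combined as a weighted sum plus bias (PARPi7-style).
``nearest_centroid``
    per-sample Spearman correlation against each centroid profile; the label
    of the most correlated centroid is assigned (TP53-classifier-style).
``negated_sum``
    log2 values median-centred per gene; score = minus the sum over the
    signature genes (RPS-style).
``median_log2``
    median log2 expression of the signature genes (module-score-style).
``single_gene``
    the log2 value of one gene (checkpoint markers).
``first_pc``
    first principal component of the gene-centred signature submatrix,
    oriented to correlate positively with the mean signature expression.
``enrichment``
    single-sample rank-based running-sum enrichment (ssGSEA-type) with
    rank-weight exponent alpha, min-max normalized across samples per set.
``linear_weighted``
    weighted sum plus bias on the configured input scale, linear FPKM by
    default (DDIR-style).

Several schemes are cohort-dependent (mean/median centring, PC loadings,
enrichment normalization): scores are a function of the full sample set, and
adding a sample may change all scores. :class:`SignatureScorer` makes this
explicit — ``fit`` learns the cohort statistics, ``transform`` applies them
frozen, and the module-level functions are the per-cohort (fit-and-apply)
versions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .registry import SignatureDefinition

logger = logging.getLogger(__name__)

__all__ = [
    "log2_transform",
    "validate_expression",
    "score_mean_centered",
    "score_weighted_normalized",
    "classify_nearest_centroid",
    "score_negated_sum",
    "score_median_log2",
    "score_single_gene",
    "select_top_genes",
    "score_first_pc",
    "score_enrichment",
    "score_linear_weighted",
    "score_all",
    "zscore_columns",
    "SignatureScorer",
]


# ---------------------------------------------------------------------------
# validation and transforms
# ---------------------------------------------------------------------------


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check an expression matrix: unique ids, finite non-negative values."""
    if expr.index.duplicated().any():
        dupes = sorted(expr.index[expr.index.duplicated()].unique().tolist())
        raise ValueError(f"duplicate gene identifiers: {dupes[:10]}")
    if expr.columns.duplicated().any():
        dupes = sorted(expr.columns[expr.columns.duplicated()].unique().tolist())
        raise ValueError(f"duplicate sample identifiers: {dupes[:10]}")
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    if (values < 0).any():
        raise ValueError("expression matrix contains negative values")
    return expr


def log2_transform(expr: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise ``log2(x + pseudocount)``.

    A pseudocount of 0 is rejected when any value is 0 (log of zero).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    values = expr.to_numpy(dtype=float)
    if pseudocount == 0 and (values == 0).any():
        raise ValueError("pseudocount 0 with zero expression values: log2(0) undefined")
    return pd.DataFrame(
        np.log2(values + pseudocount), index=expr.index, columns=expr.columns
    )


def _present(sig_name: str, genes: list[str], index: pd.Index, *, required: bool = False,
             what: str = "signature gene") -> list[str]:
    """Genes present in the matrix; warn on (or reject) missing ones."""
    index_set = set(index)
    present = [g for g in genes if g in index_set]
    missing = [g for g in genes if g not in index_set]
    if missing:
        if required:
            raise KeyError(
                f"signature {sig_name!r}: missing required {what}(s): {missing}"
            )
        logger.warning(
            "signature %r: %d/%d %ss missing from matrix (skipped): %s",
            sig_name, len(missing), len(genes), what, missing[:10],
        )
    if not present:
        raise KeyError(f"signature {sig_name!r}: no {what} present in the matrix")
    return present


# ---------------------------------------------------------------------------
# scheme internals: _fit learns cohort statistics, _apply uses them frozen
# ---------------------------------------------------------------------------


def _fit_mean_centered(log2_expr, sig):
    genes = _present(sig.name, sig.genes, log2_expr.index)
    return {"genes": genes, "center": log2_expr.loc[genes].mean(axis=1)}


def _apply_mean_centered(log2_expr, sig, state):
    sub = log2_expr.loc[state["genes"]]
    return sub.sub(state["center"], axis=0).mean(axis=0)


def _weighted_normalized_log_ratios(expr, sig, pseudocount):
    norm_genes = _present(sig.name, sig.normalization_genes, expr.index,
                          required=True, what="normalization gene")
    shifted = expr + pseudocount
    norm_vals = shifted.loc[norm_genes].to_numpy(dtype=float)
    if (norm_vals <= 0).any():
        raise ValueError(
            f"signature {sig.name!r}: non-positive normalization-gene value after pseudocount"
        )
    geo_mean = np.exp(np.mean(np.log(norm_vals), axis=0))  # per sample
    genes = _present(sig.name, sig.genes, expr.index)
    ratios = shifted.loc[genes].to_numpy(dtype=float) / geo_mean[None, :]
    if (ratios <= 0).any():
        raise ValueError(f"signature {sig.name!r}: non-positive ratio after normalization")
    log_ratios = pd.DataFrame(np.log2(ratios), index=genes, columns=expr.columns)
    return genes, log_ratios


def _fit_weighted_normalized(expr, sig, pseudocount):
    genes, log_ratios = _weighted_normalized_log_ratios(expr, sig, pseudocount)
    return {"genes": genes, "center": log_ratios.median(axis=1)}


def _apply_weighted_normalized(expr, sig, state, pseudocount):
    genes, log_ratios = _weighted_normalized_log_ratios(expr, sig, pseudocount)
    if genes != state["genes"]:
        raise KeyError(f"signature {sig.name!r}: gene coverage changed between fit and apply")
    centred = log_ratios.sub(state["center"], axis=0)
    if sig.boundaries is not None:
        centred = centred.clip(lower=sig.boundaries[0], upper=sig.boundaries[1])
    weights = pd.Series(sig.weights, index=sig.genes).loc[genes]
    return centred.mul(weights, axis=0).sum(axis=0) + sig.bias


def classify_nearest_centroid(log2_expr: pd.DataFrame, sig: SignatureDefinition):
    """Assign each sample to the centroid with the highest Spearman correlation.

    Returns ``(labels, correlations)``: a Series of centroid labels per sample
    (``"unclassifiable"`` where the sample profile is constant over the shared
    genes) and a samples-by-centroids DataFrame of Spearman correlations.
    Ties go to the first centroid in declared order.
    """
    labels_order = list(sig.centroids)
    shared = [g for g in sig.genes if g in log2_expr.index
              and all(g in prof for prof in sig.centroids.values())]
    if len(shared) < 3:
        raise ValueError(
            f"signature {sig.name!r}: only {len(shared)} genes shared between "
            "matrix and centroids; >=3 required for Spearman"
        )
    sub = log2_expr.loc[shared].to_numpy(dtype=float)  # genes x samples
    # ranks within each column; Spearman = Pearson on ranks
    sample_ranks = sps.rankdata(sub, axis=0)
    cent_ranks = {
        lab: sps.rankdata([sig.centroids[lab][g] for g in shared]) for lab in labels_order
    }
    corr = np.full((sub.shape[1], len(labels_order)), np.nan)
    for j, lab in enumerate(labels_order):
        cr = cent_ranks[lab]
        cr_c = cr - cr.mean()
        sr_c = sample_ranks - sample_ranks.mean(axis=0, keepdims=True)
        denom = np.sqrt((sr_c ** 2).sum(axis=0) * (cr_c ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            corr[:, j] = np.where(denom > 0, (sr_c * cr_c[:, None]).sum(axis=0) / denom, np.nan)
    corr_df = pd.DataFrame(corr, index=log2_expr.columns, columns=labels_order)
    labels = []
    for i, sample in enumerate(log2_expr.columns):
        row = corr[i]
        if np.isnan(row).all():
            logger.warning("signature %r: sample %r constant over shared genes; unclassifiable",
                           sig.name, sample)
            labels.append("unclassifiable")
        else:
            labels.append(labels_order[int(np.nanargmax(row))])
    return pd.Series(labels, index=log2_expr.columns, name=sig.name), corr_df


def _fit_negated_sum(log2_expr, sig):
    genes = _present(sig.name, sig.genes, log2_expr.index)
    if len(genes) < len(sig.genes):
        logger.warning("signature %r: score computed over %d of %d genes",
                       sig.name, len(genes), len(sig.genes))
    return {"genes": genes, "center": log2_expr.loc[genes].median(axis=1)}


def _apply_negated_sum(log2_expr, sig, state):
    centred = log2_expr.loc[state["genes"]].sub(state["center"], axis=0)
    return -centred.sum(axis=0)


def score_median_log2(log2_expr: pd.DataFrame, sig: SignatureDefinition) -> pd.Series:
    """Median log2 expression over the signature genes, per sample."""
    genes = _present(sig.name, sig.genes, log2_expr.index)
    return log2_expr.loc[genes].median(axis=0).rename(sig.name)


def score_single_gene(log2_expr: pd.DataFrame, gene: str) -> pd.Series:
    """The log2 expression of one gene, per sample."""
    if gene not in log2_expr.index:
        raise KeyError(f"gene {gene!r} absent from the expression matrix")
    return log2_expr.loc[gene].copy()


def _fit_first_pc(log2_expr, sig):
    genes = _present(sig.name, sig.genes, log2_expr.index)
    if len(genes) < 2:
        raise ValueError(f"signature {sig.name!r}: first_pc needs >=2 present genes")
    if log2_expr.shape[1] < 3:
        raise ValueError(f"signature {sig.name!r}: first_pc needs >=3 samples")
    sub = log2_expr.loc[genes].to_numpy(dtype=float)
    center = sub.mean(axis=1)
    centred = sub - center[:, None]
    # samples as observations in gene space
    u, s, vt = np.linalg.svd(centred.T, full_matrices=False)
    if s[0] <= 0 or not np.isfinite(s[0]):
        raise ValueError(f"signature {sig.name!r}: zero-variance submatrix; PC1 undefined")
    loading = vt[0]  # unit-norm gene loadings
    scores = centred.T @ loading
    # orient PC1 so high score means high signature expression
    mean_expr = sub.mean(axis=0)
    orient = np.corrcoef(scores, mean_expr)[0, 1] if np.std(mean_expr) > 0 else 1.0
    sign = -1.0 if orient < 0 else 1.0
    return {"genes": genes, "center": center, "loading": sign * loading}


def _apply_first_pc(log2_expr, sig, state):
    sub = log2_expr.loc[state["genes"]].to_numpy(dtype=float)
    scores = (sub - state["center"][:, None]).T @ state["loading"]
    return pd.Series(scores, index=log2_expr.columns, name=sig.name)


# --- enrichment ------------------------------------------------------------


def _enrichment_raw(expr: pd.DataFrame, genes: list[str], alpha: float) -> np.ndarray:
    """ssGSEA-type running-sum enrichment statistic, one value per sample.

    Genes are ranked per sample (descending expression, average-tied ranks as
    weights); the statistic is the summed gap between the weighted in-set and
    the uniform out-of-set cumulative distributions along the ranking.
    """
    values = expr.to_numpy(dtype=float)
    n_genes, n_samples = values.shape
    in_set = np.asarray(expr.index.isin(genes))
    n_in = int(in_set.sum())
    n_out = n_genes - n_in
    es = np.empty(n_samples)
    gene_pos = np.arange(n_genes)
    for j in range(n_samples):
        col = values[:, j]
        ranks = sps.rankdata(col)  # ascending: top expression gets rank n_genes
        # descending order, ties broken by gene position for determinism
        order = np.lexsort((gene_pos, -col))
        in_ord = in_set[order]
        w = np.where(in_ord, ranks[order] ** alpha, 0.0)
        p_in = np.cumsum(w)
        p_in /= p_in[-1]
        if n_out > 0:
            p_out = np.cumsum(~in_ord) / n_out
        else:
            p_out = np.zeros(n_genes)
        es[j] = float(np.sum(p_in - p_out))
    return es


def _fit_enrichment(expr, sig, alpha):
    genes = _present(sig.name, sig.genes, expr.index, what="gene set gene")
    es = _enrichment_raw(expr, genes, alpha)
    lo, hi = float(es.min()), float(es.max())
    return {"genes": genes, "lo": lo, "range": hi - lo}


def _apply_enrichment(expr, sig, state, alpha):
    es = _enrichment_raw(expr, state["genes"], alpha)
    if state["range"] > 0:
        es = (es - state["lo"]) / state["range"]
    return pd.Series(es, index=expr.columns, name=sig.name)


def score_enrichment(
    expr: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    alpha: float = 0.25,
    exclude_from_average: tuple[str, ...] = (),
):
    """Per-set single-sample enrichment scores plus their average.

    Returns ``(scores, average)``: a samples-by-sets DataFrame of min-max
    normalized enrichment scores and a Series averaging the sets not listed
    in ``exclude_from_average`` (fibroblast sets are conventionally excluded
    from the average immune score).
    """
    if not gene_sets:
        raise ValueError("no gene sets supplied")
    cols = {}
    for name, genes in gene_sets.items():
        present = [g for g in genes if g in expr.index]
        if not present:
            raise KeyError(f"gene set {name!r}: empty intersection with the matrix")
        es = _enrichment_raw(expr, present, alpha)
        rng = es.max() - es.min()
        cols[name] = (es - es.min()) / rng if rng > 0 else es
    scores = pd.DataFrame(cols, index=expr.columns)
    included = [c for c in scores.columns if c not in set(exclude_from_average)]
    if not included:
        raise ValueError("all gene sets excluded from the average")
    average = scores[included].mean(axis=1).rename("enrichment_average")
    return scores, average


def score_linear_weighted(expr: pd.DataFrame, sig: SignatureDefinition) -> pd.Series:
    """Weighted sum of expression values plus bias, per sample (DDIR-style)."""
    weights = pd.Series(sig.weights, index=sig.genes)
    genes = _present(sig.name, sig.genes, expr.index)
    sub = expr.loc[genes]
    return sub.mul(weights.loc[genes], axis=0).sum(axis=0) + sig.bias


# ---------------------------------------------------------------------------
# public per-cohort wrappers
# ---------------------------------------------------------------------------


def score_mean_centered(log2_expr: pd.DataFrame, sig: SignatureDefinition) -> pd.Series:
    """Mean of per-gene mean-centred log2 values over the signature genes."""
    state = _fit_mean_centered(log2_expr, sig)
    return _apply_mean_centered(log2_expr, sig, state).rename(sig.name)


def score_weighted_normalized(
    expr: pd.DataFrame, sig: SignatureDefinition, pseudocount: float = 1.0
) -> pd.Series:
    """Geometric-mean-normalized, median-centred weighted score (PARPi7-style).

    Operates on the linear FPKM scale: signature genes are divided by the
    per-sample geometric mean of the normalization genes, log2-transformed,
    median-centred per gene across the cohort, clipped to the configured
    boundaries if any, and combined as a weighted sum plus bias. The score is
    kept continuous.
    """
    state = _fit_weighted_normalized(expr, sig, pseudocount)
    return _apply_weighted_normalized(expr, sig, state, pseudocount).rename(sig.name)


def score_negated_sum(log2_expr: pd.DataFrame, sig: SignatureDefinition) -> pd.Series:
    """Minus the sum of per-gene median-centred log2 values (RPS-style)."""
    state = _fit_negated_sum(log2_expr, sig)
    return _apply_negated_sum(log2_expr, sig, state).rename(sig.name)


def score_first_pc(log2_expr: pd.DataFrame, sig: SignatureDefinition) -> pd.Series:
    """First principal component of the gene-centred signature submatrix.

    The sign is oriented so the score correlates positively with the
    per-sample mean of the signature genes; gene loadings are unit-norm.
    """
    state = _fit_first_pc(log2_expr, sig)
    return _apply_first_pc(log2_expr, sig, state).rename(sig.name)


def select_top_genes(
    de: pd.DataFrame,
    cell_type: str,
    lfc_min: float = 1.0,
    fdr_max: float = 0.01,
    n_top: int = 50,
) -> list[str]:
    """Top differentially expressed genes for one cell type.

    Filters to rows of ``cell_type`` with log-fold change strictly above
    ``lfc_min`` and FDR strictly below ``fdr_max``, then takes the ``n_top``
    genes by descending log-fold change (ties broken by ascending FDR, then
    lexicographic gene id). Returns all survivors when fewer than ``n_top``.
    """
    if de.empty:
        raise ValueError("empty differential expression table")
    sub = de[(de["cell_type"] == cell_type)
             & (de["log_fold_change"] > lfc_min)
             & (de["fdr"] < fdr_max)]
    if sub.empty:
        logger.warning("select_top_genes: no genes survive the filter for %r", cell_type)
        return []
    ordered = sub.sort_values(
        ["log_fold_change", "fdr", "gene_id"], ascending=[False, True, True]
    )
    return ordered["gene_id"].head(n_top).tolist()


def zscore_columns(scores: pd.DataFrame) -> pd.DataFrame:
    """Z-score each continuous column (mean 0, sample SD 1); calls untouched.

    Uses the sample standard deviation (ddof=1) over non-missing values.
    Raises on zero-SD columns.
    """
    out = scores.copy()
    for col in scores.columns:
        if not pd.api.types.is_numeric_dtype(scores[col]):
            continue
        x = scores[col].astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {col!r} has zero or undefined standard deviation")
        out[col] = (x - x.mean()) / sd
    return out


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class SignatureScorer(TransformerMixin, BaseEstimator):
    """Score a registry of transcriptional signatures on an expression cohort.

    ``fit`` learns the cohort-dependent statistics (per-gene centring values,
    PC loadings, enrichment normalization ranges) on a genes-by-samples FPKM
    matrix; ``transform`` applies them frozen, returning a samples-by-
    signatures score table. ``fit_transform`` on one cohort gives the
    per-cohort scores the module-level functions compute.

    Parameters
    ----------
    registry : list of SignatureDefinition
        Signatures to score.
    pseudocount : float, default 1.0
        Added before log2 transformation of FPKM values.
    enrichment_alpha : float, default 0.25
        Rank-weight exponent of the enrichment running-sum statistic.
    """

    def __init__(self, registry=None, pseudocount: float = 1.0,
                 enrichment_alpha: float = 0.25):
        self.registry = registry
        self.pseudocount = pseudocount
        self.enrichment_alpha = enrichment_alpha

    def fit(self, X: pd.DataFrame, y=None) -> "SignatureScorer":
        if not self.registry:
            raise ValueError("empty signature registry")
        names = [s.name for s in self.registry]
        if len(set(names)) != len(names):
            raise ValueError("duplicate signature names in registry")
        validate_expression(X)
        log2x = log2_transform(X, self.pseudocount)
        self.states_ = {}
        for sig in self.registry:
            if sig.scheme == "mean_centered":
                st = _fit_mean_centered(log2x, sig)
            elif sig.scheme == "weighted_normalized":
                st = _fit_weighted_normalized(X, sig, self.pseudocount)
            elif sig.scheme == "negated_sum":
                st = _fit_negated_sum(log2x, sig)
            elif sig.scheme == "first_pc":
                st = _fit_first_pc(log2x, sig)
            elif sig.scheme == "enrichment":
                st = _fit_enrichment(X, sig, self.enrichment_alpha)
            else:
                st = None  # stateless schemes
            self.states_[sig.name] = st
        self.n_features_in_ = X.shape[0]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "states_"):
            raise RuntimeError("SignatureScorer is not fitted")
        validate_expression(X)
        log2x = log2_transform(X, self.pseudocount)
        columns: dict[str, pd.Series] = {}
        enrichment_cols: list[str] = []
        enrichment_included: list[str] = []
        for sig in self.registry:
            st = self.states_[sig.name]
            if sig.scheme == "mean_centered":
                col = _apply_mean_centered(log2x, sig, st)
            elif sig.scheme == "weighted_normalized":
                col = _apply_weighted_normalized(X, sig, st, self.pseudocount)
            elif sig.scheme == "nearest_centroid":
                col, _ = classify_nearest_centroid(log2x, sig)
            elif sig.scheme == "negated_sum":
                col = _apply_negated_sum(log2x, sig, st)
            elif sig.scheme == "median_log2":
                col = score_median_log2(log2x, sig)
            elif sig.scheme == "single_gene":
                col = score_single_gene(log2x, sig.genes[0])
            elif sig.scheme == "first_pc":
                col = _apply_first_pc(log2x, sig, st)
            elif sig.scheme == "enrichment":
                col = _apply_enrichment(X, sig, st, self.enrichment_alpha)
                enrichment_cols.append(sig.name)
                if not sig.exclude_from_average:
                    enrichment_included.append(sig.name)
            elif sig.scheme == "linear_weighted":
                source = X if sig.input_scale == "fpkm" else log2x
                col = score_linear_weighted(source, sig)
            else:  # pragma: no cover - registry validation forbids this
                raise ValueError(f"unknown scheme {sig.scheme!r}")
            columns[sig.name] = col
        table = pd.DataFrame(columns, index=X.columns)
        if enrichment_included:
            table["enrichment_average"] = table[enrichment_included].mean(axis=1)
        return table


def score_all(
    expr: pd.DataFrame,
    registry: list[SignatureDefinition],
    pseudocount: float = 1.0,
    enrichment_alpha: float = 0.25,
) -> pd.DataFrame:
    """Score every signature in the registry on one cohort.

    Returns a samples-by-signatures table with one column per signature
    (continuous scores, or centroid labels for nearest_centroid schemes) plus
    an ``enrichment_average`` column when enrichment signatures are present.
    """
    scorer = SignatureScorer(
        registry=registry, pseudocount=pseudocount, enrichment_alpha=enrichment_alpha
    )
    return scorer.fit(expr).transform(expr)
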