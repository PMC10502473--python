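"""Association statistics for trial biomarkers: response, survival, and the
descriptive tests used alongside them.

Continuous biomarkers are Z-scored once on the full analysis cohort before
arm subsetting, so per-arm models share a scale. Objective response is
modelled by univariable logistic regression (per arm) with a Wald
treatment-by-biomarker interaction test; progression-free survival by linear
regression of restricted-mean-survival pseudo-observations, which turns a
censored outcome into an ordinary regression with effects in months per
Z-unit. All p values and confidence intervals are two-sided, and no
multiplicity adjustment is applied by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "AssociationResult",
    "fit_logistic_orr",
    "test_interaction",
    "km_rmst",
    "rmst_pseudo_observations",
    "rmst_regression",
    "wilcoxon_rank_sum",
    "kruskal_dunn",
    "fisher_exact_2x2",
    "spearman_matrix",
    "paired_change_test",
    "random_intercept_timepoint_model",
    "response_rate_table",
]


@dataclass
class AssociationResult:
    """One biomarker-outcome association estimate with its uncertainty."""

    biomarker: str
    subgroup: str
    arm: str
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "biomarker": self.biomarker, "subgroup": self.subgroup, "arm": self.arm,
            "estimate": self.estimate, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p": self.p, "n": self.n, "note": self.note,
        }


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def _logit_fit(X: np.ndarray, y: np.ndarray):
    """Logit MLE with separation detection; returns (result_or_None, note)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:
            return None, "separation"
    if not np.isfinite(res.bse).all() or np.abs(res.params).max() > 15 or res.bse.max() > 50:
        return None, "separation"
    return res, ""


def fit_logistic_orr(
    z, response, subset=None, biomarker: str = "biomarker",
    subgroup: str = "all", arm: str = "all",
) -> AssociationResult:
    """Univariable logistic regression of objective response on a biomarker.

    ``z`` should already be Z-scored on the full analysis cohort; ``subset``
    is an optional boolean mask (e.g. one treatment arm). Complete or
    quasi-complete separation is flagged in ``note`` with no finite estimate
    rather than reported silently.
    """
    z = _as_float_array(z)
    y = _as_float_array(response)
    if subset is not None:
        mask = np.asarray(subset, dtype=bool)
        z, y = z[mask], y[mask]
    n = z.size
    if y.min() == y.max():
        raise ValueError("subset has no variation in response (all 0 or all 1)")
    X = sm.add_constant(z)
    res, note = _logit_fit(X, y)
    if res is None:
        return AssociationResult(biomarker, subgroup, arm,
                                 np.nan, np.nan, np.nan, np.nan, n, note)
    est = float(res.params[1])
    ci = res.conf_int()[1]
    return AssociationResult(biomarker, subgroup, arm, est,
                             float(ci[0]), float(ci[1]), float(res.pvalues[1]), n)


def test_interaction(
    z, response, arm, biomarker: str = "biomarker", subgroup: str = "all",
) -> AssociationResult:
    """Wald test of the treatment-by-biomarker product term for response.

    Fits ``response ~ z + arm + z:arm`` and reports the interaction
    coefficient (difference in log-odds per Z-unit between arms).
    """
    z = _as_float_array(z)
    y = _as_float_array(response)
    arm = np.asarray(arm)
    levels = np.unique(arm)
    if levels.size != 2:
        raise ValueError(f"interaction test needs exactly 2 arms, got {levels.tolist()}")
    a = (arm == levels[1]).astype(float)
    for lev in levels:
        ya = y[arm == lev]
        if ya.min() == ya.max():
            raise ValueError(f"arm {lev!r} has no variation in response")
    X = sm.add_constant(np.column_stack([z, a, z * a]))
    res, note = _logit_fit(X, y)
    if res is None:
        return AssociationResult(biomarker, subgroup, "interaction",
                                 np.nan, np.nan, np.nan, np.nan, z.size, note)
    ci = res.conf_int()[3]
    return AssociationResult(biomarker, subgroup, "interaction", float(res.params[3]),
                             float(ci[0]), float(ci[1]), float(res.pvalues[3]), z.size)


# ---------------------------------------------------------------------------
# restricted mean survival time
# ---------------------------------------------------------------------------


def km_rmst(time, event, tau: float) -> float:
    """Restricted mean survival time: area under Kaplan-Meier up to tau."""
    t = _as_float_array(time)
    e = np.asarray(event, dtype=bool)
    ut = np.unique(t[e & (t <= tau)])
    if ut.size == 0:
        return float(tau)
    n_at = (t[:, None] >= ut[None, :]).sum(axis=0)
    d = ((t[:, None] == ut[None, :]) & e[:, None]).sum(axis=0)
    surv = np.cumprod(1.0 - d / n_at)
    bounds = np.concatenate([[0.0], np.minimum(ut, tau), [tau]])
    steps = np.concatenate([[1.0], surv])
    return float(np.sum(steps * np.diff(bounds)))


def rmst_pseudo_observations(time, event, tau: float) -> np.ndarray:
    """Jackknife pseudo-observations of the restricted mean at horizon tau.

    ``po_i = n * rmst(all) - (n - 1) * rmst(all but i)``; with no censoring
    these reduce to ``min(T_i, tau)`` exactly. The leave-one-out curves are
    computed in one vectorized pass over the shared event-time grid.
    """
    t = _as_float_array(time)
    e = np.asarray(event, dtype=bool)
    n = t.size
    if not (e & (t <= tau)).any():
        raise ValueError("no events at or before tau: restricted mean unidentified")
    theta = km_rmst(t, e, tau)
    ut = np.unique(t[e & (t <= tau)])
    n_at = (t[:, None] >= ut[None, :]).sum(axis=0)
    d = ((t[:, None] == ut[None, :]) & e[:, None]).sum(axis=0)
    # leave-one-out risk sets and event counts, one row per removed sample
    n_loo = n_at[None, :] - (t[:, None] >= ut[None, :])
    d_loo = d[None, :] - ((t[:, None] == ut[None, :]) & e[:, None])
    with np.errstate(invalid="ignore", divide="ignore"):
        factor = np.where(n_loo > 0, 1.0 - d_loo / n_loo, 1.0)
    surv = np.cumprod(factor, axis=1)
    widths = np.diff(np.concatenate([[0.0], np.minimum(ut, tau), [tau]]))
    theta_loo = widths[0] + surv @ widths[1:]
    return n * theta - (n - 1) * theta_loo


def rmst_regression(
    pfs_time, pfs_event, z=None, tau: float | None = None, subset=None,
    interaction_arm=None, biomarker: str = "biomarker",
    subgroup: str = "all", arm: str = "all",
) -> AssociationResult:
    """Linear regression of restricted-mean-survival pseudo-observations.

    With ``z=None`` the intercept (the restricted mean itself) is reported.
    With ``interaction_arm`` given, the model ``po ~ z + arm + z:arm`` is
    fitted and the interaction coefficient reported. Coefficients are in
    months per Z-unit with HC1 robust confidence intervals.
    """
    t = _as_float_array(pfs_time)
    e = np.asarray(pfs_event, dtype=bool)
    zv = None if z is None else _as_float_array(z)
    av = None if interaction_arm is None else np.asarray(interaction_arm)
    if subset is not None:
        mask = np.asarray(subset, dtype=bool)
        t, e = t[mask], e[mask]
        zv = zv[mask] if zv is not None else None
        av = av[mask] if av is not None else None
    if tau is None:
        tau = float(t.max())
    if tau > t.max():
        raise ValueError(f"tau={tau} exceeds maximum follow-up {t.max():.3g}")
    po = rmst_pseudo_observations(t, e, tau)
    n = t.size
    if zv is None:
        X = np.ones((n, 1))
        term = 0
    elif av is not None:
        levels = np.unique(av)
        if levels.size != 2:
            raise ValueError("interaction needs exactly 2 arms")
        ai = (av == levels[1]).astype(float)
        X = sm.add_constant(np.column_stack([zv, ai, zv * ai]))
        term = 3
        arm = "interaction"
    else:
        X = sm.add_constant(zv)
        term = 1
    res = sm.OLS(po, X).fit(cov_type="HC1")
    ci = np.atleast_2d(res.conf_int())[term]
    return AssociationResult(biomarker, subgroup, arm, float(res.params[term]),
                             float(ci[0]), float(ci[1]), float(res.pvalues[term]), n)


# ---------------------------------------------------------------------------
# descriptive tests
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Exact enumeration of the permutation distribution (with midranks, so ties
    are handled) for combined n <= 10; otherwise the tie-corrected normal
    approximation. Returns (rank-sum of x, two-sided p).
    """
    x = _as_float_array(x)
    y = _as_float_array(y)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    nx, n = x.size, x.size + y.size
    ranks = sps.rankdata(np.concatenate([x, y]))
    w_obs = float(ranks[:nx].sum())
    if n <= 10:
        sums = np.array([sum(c) for c in combinations(ranks, nx)])
        eps = 1e-9
        p_lo = np.mean(sums <= w_obs + eps)
        p_hi = np.mean(sums >= w_obs - eps)
        p = min(1.0, 2.0 * min(p_lo, p_hi))
        return w_obs, float(p)
    _, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return w_obs, float(p)


def kruskal_dunn(values, groups, adjust: str | None = None):
    """Kruskal-Wallis omnibus test with Dunn post hoc pairwise z tests.

    Pairwise p values are unadjusted by default (``adjust`` may be "holm" or
    "bh"). Returns ``(H, p, pairwise)`` where ``pairwise`` is a DataFrame with
    one row per group pair.
    """
    values = _as_float_array(values)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(s.size == 0 for s in samples):
        raise ValueError("empty group")
    h, p_global = sps.kruskal(*samples)
    # Dunn z from pooled midranks with tie correction
    n = values.size
    ranks = sps.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n - 1))
    var_unit = n * (n + 1) / 12.0 - tie_term
    rows = []
    for g1, g2 in combinations(labels, 2):
        m1, m2 = groups == g1, groups == g2
        n1, n2 = int(m1.sum()), int(m2.sum())
        se = np.sqrt(var_unit * (1.0 / n1 + 1.0 / n2))
        z = (ranks[m1].mean() - ranks[m2].mean()) / se if se > 0 else np.nan
        rows.append({"group1": g1, "group2": g2, "z": z,
                     "p": 2 * sps.norm.sf(abs(z)) if np.isfinite(z) else np.nan})
    pairwise = pd.DataFrame(rows)
    if adjust is not None:
        from statsmodels.stats.multitest import multipletests

        method = {"holm": "holm", "bh": "fdr_bh"}[adjust]
        pairwise["p_adjusted"] = multipletests(pairwise["p"], method=method)[1]
    return float(h), float(p_global), pairwise


def fisher_exact_2x2(table) -> tuple[float, float, str]:
    """Fisher exact test on a 2x2 table.

    Returns ``(odds_ratio, p, note)``: the sample cross-product odds ratio
    (Haldane 0.5 correction, flagged, when any cell is zero) and the
    conditional hypergeometric two-sided p value.
    """
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2) or (tab < 0).any() or not np.allclose(tab, np.round(tab)):
        raise ValueError("table must be 2x2 with non-negative integer cells")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("zero margin: odds ratio undefined")
    _, p = sps.fisher_exact(tab.astype(int), alternative="two-sided")
    note = ""
    work = tab
    if (tab == 0).any():
        work = tab + 0.5
        note = "haldane_correction"
    odds = (work[0, 0] * work[1, 1]) / (work[0, 1] * work[1, 0])
    return float(odds), float(p), note


def spearman_matrix(scores: pd.DataFrame, min_periods: int = 3) -> pd.DataFrame:
    """Pairwise-complete tie-corrected Spearman correlation matrix.

    Constant columns yield undefined (NaN) off-diagonal cells; diagonals are 1
    where defined.
    """
    numeric = scores.select_dtypes(include=[np.number])
    rho = numeric.corr(method="spearman", min_periods=min_periods)
    for col in numeric.columns:
        x = numeric[col].dropna()
        if x.size >= 2 and x.nunique() > 1:
            rho.loc[col, col] = 1.0
        else:
            rho.loc[col, :] = np.nan
            rho.loc[:, col] = np.nan
    return rho


def paired_change_test(primary_scores, recurrence_scores, pairing=None):
    """Paired t test of recurrence minus primary scores.

    ``pairing`` optionally maps positions: a sequence of (primary_idx,
    recurrence_idx); by default scores are aligned positionally (or by index
    for Series). Returns ``(mean_change, p, note)``; a zero-variance set of
    differences yields the mean change with p flagged undefined (NaN).
    """
    if isinstance(primary_scores, pd.Series) and isinstance(recurrence_scores, pd.Series):
        common = primary_scores.index.intersection(recurrence_scores.index)
        prim = primary_scores.loc[common].to_numpy(dtype=float)
        rec = recurrence_scores.loc[common].to_numpy(dtype=float)
    else:
        prim = _as_float_array(primary_scores)
        rec = _as_float_array(recurrence_scores)
    if pairing is not None:
        pairing = np.asarray(pairing)
        prim = prim[pairing[:, 0]]
        rec = rec[pairing[:, 1]]
    if prim.size < 2:
        raise ValueError("need at least 2 complete pairs")
    diffs = rec - prim
    mean_change = float(diffs.mean())
    if np.ptp(diffs) == 0:
        return mean_change, float("nan"), "zero_variance"
    _, p = sps.ttest_1samp(diffs, 0.0)
    return mean_change, float(p), ""


def random_intercept_timepoint_model(scores, patient_ids, timepoint):
    """Gaussian random-intercept model with a fixed timepoint effect.

    Fits ``score ~ timepoint + (1 | patient)`` by REML: patients with several
    samples share a random intercept; the reported fixed effect is the
    recurrence-vs-primary shift with its Wald p. Returns a dict with
    ``estimate``, ``p``, ``var_patient`` and a ``note`` flagging the
    degenerate case where the patient variance collapses to ~0 (the model
    then coincides with ordinary regression).
    """
    y = _as_float_array(scores)
    pid = np.asarray(patient_ids)
    tp = np.asarray(timepoint)
    levels = np.unique(tp)
    if levels.size < 2:
        raise ValueError("timepoint is constant")
    if np.unique(pid).size < 2:
        raise ValueError("need at least 2 patients")
    both = [p for p in np.unique(pid) if np.unique(tp[pid == p]).size == 2]
    if not both:
        raise ValueError("no patient observed at both timepoints")
    ind = (tp == ("recurrence" if "recurrence" in levels else levels[1])).astype(float)
    X = sm.add_constant(ind)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=pid)
        try:
            res = model.fit(reml=True)
        except np.linalg.LinAlgError:
            res = model.fit(reml=True, method="powell")
    var_patient = float(np.asarray(res.cov_re).ravel()[0])
    note = ""
    if var_patient < 1e-2 * float(res.scale):
        note = "degenerate_patient_variance"  # collapses to ordinary regression
    ci = np.asarray(res.conf_int())
    return {
        "estimate": float(np.asarray(res.fe_params)[1]),
        "p": float(np.asarray(res.pvalues)[1]),
        "ci_low": float(ci[1, 0]),
        "ci_high": float(ci[1, 1]),
        "var_patient": var_patient,
        "var_residual": float(res.scale),
        "note": note,
    }


def response_rate_table(labels, arm, response, min_size: int = 5) -> pd.DataFrame:
    """Per-cluster per-arm response rates with a Fisher comparison of arms.

    One row per cluster: arm-wise responders/treated and rates, the Fisher
    exact p comparing arms (NaN when an arm is empty within the cluster), and
    a ``too_small`` flag for clusters below ``min_size``.
    """
    df = pd.DataFrame({"cluster": np.asarray(labels), "arm": np.asarray(arm),
                       "response": np.asarray(response, dtype=int)})
    arms = sorted(df["arm"].unique())
    if len(arms) != 2:
        raise ValueError(f"expected 2 arms, got {arms}")
    rows = []
    for cluster, grp in df.groupby("cluster", sort=True):
        row: dict = {"cluster": cluster, "n": len(grp)}
        cells = []
        for a in arms:
            sub = grp[grp["arm"] == a]
            resp, tot = int(sub["response"].sum()), len(sub)
            row[f"n_{a}"] = tot
            row[f"responders_{a}"] = resp
            row[f"rate_{a}"] = resp / tot if tot else np.nan
            cells.append((resp, tot - resp))
        tab = np.array([list(cells[0]), list(cells[1])])
        if tab.sum(axis=1).min() > 0 and tab.sum(axis=0).min() > 0:
            _, p, _ = fisher_exact_2x2(tab)
            row["fisher_p"] = p
        else:
            row["fisher_p"] = np.nan
        row["too_small"] = len(grp) < min_size
        rows.append(row)
    return pd.DataFrame(rows)
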