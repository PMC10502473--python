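"""End-to-end orchestration: files in, scored/clustered/tested artifacts out.

The full run mirrors the analysis plan of a randomized biomarker substudy:
score all registry signatures on the primary-tumor expression matrix, Z-score
the continuous columns, estimate per-arm response and restricted-mean-PFS
associations (overall and within prior-chemotherapy strata), carry every
biomarker with a significant univariable association (plus TILs and the BRCA
genotype categories) into consensus forest clustering, and characterize the
resulting clusters with module scores and per-arm response tables. Every
stage writes CSV artifacts and the run ends with a manifest of content
hashes, so reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from . import io as tio
from .consensus import ForestConsensusCluster
from .registry import SignatureDefinition, load_registry
from .scoring import score_all, score_median_log2, log2_transform, zscore_columns
from .stats import (
    AssociationResult,
    fit_logistic_orr,
    response_rate_table,
    rmst_regression,
    test_interaction,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "CharacterizationReport",
    "run_associations",
    "select_clustering_features",
    "characterize_clusters",
    "run_pipeline",
]

SUBGROUPS = ("all", "prior_chemo", "chemo_naive")


@dataclass
class PipelineConfig:
    """Paths and options of one pipeline run; the seed must be explicit."""

    expression_path: str
    clinical_path: str
    registry_path: str
    output_dir: str
    modules_gmt_path: str | None = None
    pseudocount: float = 1.0
    enrichment_alpha: float = 0.25
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    n_reps: int = 100
    feature_frac: float = 0.8
    n_trees: int = 50
    forest_alpha: float = 0.05
    delta_area_threshold: float = 0.1
    tau: float | None = None
    alpha: float = 0.05
    adjustment: str | None = None
    min_subgroup_n: int = 15
    min_cluster_size: int = 5
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "seed" not in doc:
            raise ValueError(f"{path}: config must set 'seed' explicitly")
        cfg = cls(**{k: tuple(v) if k == "k_range" else v for k, v in doc.items()})
        for attr in ("expression_path", "clinical_path", "registry_path"):
            p = getattr(cfg, attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"{attr} does not resolve: {p}")
        return cfg


@dataclass
class CharacterizationReport:
    """Cluster sizes, per-arm response rates and a supervised module matrix."""

    cluster_sizes: pd.Series
    response_table: pd.DataFrame
    module_matrix: pd.DataFrame  # modules (row-ordered) x samples (cluster-grouped)
    module_order: list[str]
    sample_order: list[str]
    flags: dict


def _safe(call, biomarker, subgroup, arm, n) -> AssociationResult:
    try:
        return call()
    except ValueError as exc:
        return AssociationResult(biomarker, subgroup, arm, np.nan, np.nan,
                                 np.nan, np.nan, n, note=f"not_estimable: {exc}")


def run_associations(
    scores_z: pd.DataFrame,
    clinical: pd.DataFrame,
    tau: float | None = None,
    min_subgroup_n: int = 15,
) -> pd.DataFrame:
    """Per-biomarker per-arm associations with response and restricted-mean PFS.

    ``scores_z`` is the Z-scored score table indexed by sample id; clinical
    rows are matched on ``sample_id``. For each continuous biomarker and each
    subgroup (all, prior chemotherapy, chemotherapy-naive, the latter two
    skipped below ``min_subgroup_n``) the output holds one logistic ORR fit
    per arm, the treatment interaction, one RMST fit per arm, and the RMST
    interaction. Returns a tidy DataFrame.
    """
    clin = clinical.set_index("sample_id").loc[scores_z.index]
    numeric_cols = [c for c in scores_z.columns
                    if pd.api.types.is_numeric_dtype(scores_z[c])]
    if tau is None:
        # smallest per-arm maximum follow-up keeps the horizon identifiable in
        # both arms
        tau = float(clin.groupby("arm")["pfs_time"].max().min())
    results: list[AssociationResult] = []
    subgroup_masks = {
        "all": np.ones(len(clin), dtype=bool),
        "prior_chemo": clin["prior_chemo"].to_numpy() == 1,
        "chemo_naive": clin["prior_chemo"].to_numpy() == 0,
    }
    for biomarker in numeric_cols:
        z = scores_z[biomarker].to_numpy(dtype=float)
        for subgroup in SUBGROUPS:
            mask = subgroup_masks[subgroup]
            if subgroup != "all" and mask.sum() < min_subgroup_n:
                logger.warning("subgroup %r has n=%d < %d: analyses skipped",
                               subgroup, int(mask.sum()), min_subgroup_n)
                continue
            for arm_name in sorted(clin["arm"].unique()):
                sel = mask & (clin["arm"].to_numpy() == arm_name)
                results.append(_safe(
                    lambda s=sel, a=arm_name, sg=subgroup: fit_logistic_orr(
                        z, clin["response"].to_numpy(), subset=s,
                        biomarker=biomarker, subgroup=sg, arm=a),
                    biomarker, subgroup, arm_name, int(sel.sum())))
                results.append(_safe(
                    lambda s=sel, a=arm_name, sg=subgroup: rmst_regression(
                        clin["pfs_time"].to_numpy(), clin["pfs_event"].to_numpy(),
                        z, tau=min(tau, float(clin.loc[s, "pfs_time"].max())),
                        subset=s, biomarker=biomarker, subgroup=sg,
                        arm=f"{a}_rmst"),
                    biomarker, subgroup, f"{arm_name}_rmst", int(sel.sum())))
            results.append(_safe(
                lambda m=mask, sg=subgroup: test_interaction(
                    z[m], clin["response"].to_numpy()[m], clin["arm"].to_numpy()[m],
                    biomarker=biomarker, subgroup=sg),
                biomarker, subgroup, "interaction", int(mask.sum())))
            results.append(_safe(
                lambda m=mask, sg=subgroup: rmst_regression(
                    clin["pfs_time"].to_numpy(), clin["pfs_event"].to_numpy(), z,
                    tau=min(tau, float(clin.loc[m, "pfs_time"].max())), subset=m,
                    interaction_arm=clin["arm"].to_numpy(),
                    biomarker=biomarker, subgroup=sg),
                biomarker, subgroup, "interaction_rmst", int(mask.sum())))
    return pd.DataFrame([r.to_dict() for r in results])


def select_clustering_features(
    associations: pd.DataFrame,
    scores_z: pd.DataFrame,
    clinical: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Feature table for clustering: significant biomarkers + TILs + BRCA.

    A biomarker enters when any of its univariable response or PFS
    associations (either arm, any subgroup) has p < alpha. TILs and the BRCA
    genotype category are always included (TILs continuous, BRCA
    categorical). Raises when the selection is empty.
    """
    per_arm = associations[~associations["arm"].str.startswith("interaction")]
    hits = per_arm[per_arm["p"] < alpha]["biomarker"].unique().tolist()
    selected = [b for b in scores_z.columns if b in set(hits)
                and pd.api.types.is_numeric_dtype(scores_z[b])]
    if not selected:
        raise ValueError(
            f"no biomarker has a univariable association with p < {alpha}; "
            "consider relaxing alpha"
        )
    logger.info("clustering features selected at alpha=%s: %s", alpha, selected)
    clin = clinical.set_index("sample_id").loc[scores_z.index]
    features = scores_z[selected].copy()
    features["tils"] = clin["tils"].astype(float)
    features["brca_status"] = pd.Categorical(clin["brca_status"])
    return features


def characterize_clusters(
    labels: pd.Series,
    module_scores: pd.DataFrame,
    clinical: pd.DataFrame,
    min_cluster_size: int = 5,
) -> CharacterizationReport:
    """Supervised characterization of the novel clusters.

    Module rows are ordered by average-linkage hierarchical clustering of
    their score profiles; sample columns are grouped by cluster label
    (samples are never reordered across cluster boundaries). The per-cluster
    per-arm response table comes from :func:`tnbcsig.stats.response_rate_table`.
    ``module_scores`` is samples x modules, indexed like ``labels``.
    """
    labels = labels.loc[module_scores.index]
    mat = module_scores.T  # modules x samples
    if mat.shape[0] > 2:
        order_idx = leaves_list(linkage(pdist(mat.to_numpy()), method="average"))
        module_order = [mat.index[i] for i in order_idx]
    else:
        module_order = list(mat.index)
    sample_order = [s for lab in sorted(labels.unique())
                    for s in labels.index[labels == lab]]
    ordered = mat.loc[module_order, sample_order]
    clin = clinical.set_index("sample_id").loc[module_scores.index]
    response = response_rate_table(
        labels.to_numpy(), clin["arm"].to_numpy(), clin["response"].to_numpy(),
        min_size=min_cluster_size,
    )
    sizes = labels.value_counts().sort_index()
    flags = {"undersized_clusters": sizes.index[sizes < min_cluster_size].tolist()}
    return CharacterizationReport(
        cluster_sizes=sizes,
        response_table=response,
        module_matrix=ordered,
        module_order=module_order,
        sample_order=sample_order,
        flags=flags,
    )


def _write_csv(df: pd.DataFrame, path: Path, **kwargs) -> str:
    df.to_csv(path, **kwargs)
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write all stage artifacts.

    Returns the manifest dict (also written as ``manifest.json``), which maps
    each artifact to its SHA-256 content hash along with the configuration
    and per-stage row counts.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                                 for k, v in vars(config).items()},
                      "stages": {}, "hashes": {}}

    expr = tio.read_expression_tsv(config.expression_path)
    clinical = tio.read_clinical_csv(config.clinical_path)
    registry = load_registry(config.registry_path)
    known = set(expr.columns)
    dropped = clinical.loc[~clinical["sample_id"].isin(known), "sample_id"].tolist()
    if dropped:
        logger.warning("samples in clinical without expression (dropped): %s", dropped)
    clinical = clinical[clinical["sample_id"].isin(known)].reset_index(drop=True)
    primary = clinical[clinical["timepoint"] == "primary"]
    expr_primary = expr[primary["sample_id"].tolist()]
    manifest["stages"]["input"] = {
        "n_genes": int(expr.shape[0]), "n_samples": int(expr.shape[1]),
        "n_primary": int(primary.shape[0]), "n_dropped_clinical": len(dropped),
        "n_signatures": len(registry),
    }

    scores = score_all(expr_primary, registry, pseudocount=config.pseudocount,
                       enrichment_alpha=config.enrichment_alpha)
    manifest["hashes"]["scores.csv"] = _write_csv(scores, out / "scores.csv",
                                                  index_label="sample_id")
    scores_z = zscore_columns(scores)
    manifest["hashes"]["scores_z.csv"] = _write_csv(scores_z, out / "scores_z.csv",
                                                    index_label="sample_id")

    associations = run_associations(scores_z, primary, tau=config.tau,
                                    min_subgroup_n=config.min_subgroup_n)
    manifest["hashes"]["associations.csv"] = _write_csv(
        associations, out / "associations.csv", index=False)
    manifest["stages"]["associations"] = {"n_rows": int(associations.shape[0])}

    features = select_clustering_features(associations, scores_z, primary,
                                          alpha=config.alpha)
    manifest["hashes"]["features.csv"] = _write_csv(features, out / "features.csv",
                                                    index_label="sample_id")

    est = ForestConsensusCluster(
        k_range=config.k_range, n_reps=config.n_reps,
        feature_frac=config.feature_frac, n_trees=config.n_trees,
        alpha=config.forest_alpha,
        delta_area_threshold=config.delta_area_threshold,
        random_state=config.seed,
    ).fit(features)
    labels = pd.Series(est.labels_, index=features.index, name="cluster")
    manifest["hashes"]["clusters.csv"] = _write_csv(
        labels.to_frame(), out / "clusters.csv", index_label="sample_id")
    cdf = pd.DataFrame({"k": est.result_.k_range,
                        "cdf_area": [est.cdf_area_[k] for k in est.result_.k_range],
                        "delta_area": [est.delta_area_[k] for k in est.result_.k_range]})
    manifest["hashes"]["cdf_areas.csv"] = _write_csv(cdf, out / "cdf_areas.csv", index=False)
    for k, mat in est.consensus_.items():
        df = pd.DataFrame(mat, index=features.index, columns=features.index)
        manifest["hashes"][f"consensus_k{k}.csv"] = _write_csv(
            df, out / f"consensus_k{k}.csv", index_label="sample_id")
    manifest["stages"]["clustering"] = {
        "selected_k": int(est.selected_k_),
        "cluster_sizes": np.bincount(est.labels_)[1:].tolist(),
    }

    if config.modules_gmt_path:
        modules = tio.read_gmt(config.modules_gmt_path)
    else:  # fall back to the registry's plain gene sets as modules
        modules = {s.name: s.genes for s in registry
                   if s.scheme in ("median_log2", "mean_centered")}
    log2x = log2_transform(expr_primary, config.pseudocount)
    module_scores = pd.DataFrame({
        name: score_median_log2(log2x, SignatureDefinition(name, "median_log2", genes))
        for name, genes in modules.items()
        if any(g in log2x.index for g in genes)
    }, index=expr_primary.columns)
    report = characterize_clusters(labels, module_scores, primary,
                                   min_cluster_size=config.min_cluster_size)
    manifest["hashes"]["module_matrix.csv"] = _write_csv(
        report.module_matrix, out / "module_matrix.csv", index_label="module")
    manifest["hashes"]["response_by_cluster.csv"] = _write_csv(
        report.response_table, out / "response_by_cluster.csv", index=False)
    manifest["stages"]["characterization"] = {
        "cluster_sizes": report.cluster_sizes.to_dict(),
        "flags": report.flags,
    }

    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest["hashes"], sort_keys=True).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
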