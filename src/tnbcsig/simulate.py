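"""Synthetic TNBC-like trial cohorts with planted structure.

The generator emulates the statistical shape of a randomized two-arm
advanced-TNBC biomarker cohort: a non-negative FPKM-scale expression matrix
with correlated immune and DDR signature gene blocks, planted sample
clusters, a 1:1 randomized treatment arm, objective response drawn from a
per-arm logistic model on block-level biomarkers (including arm-specific
effects), exponential progression-free survival with independent uniform
censoring, pathologist-style TILs percentages correlated with the immune
block, BRCA genotype categories, and optional paired recurrence samples with
configurable per-block shifts on the log2 scale.

Expression is generated as ``2**(base + cluster_shift + noise) - 1`` floored
at zero, i.e. Gaussian on the log2(x+1) scale, which keeps FPKM values
non-negative. Everything is reproducible from ``CohortConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .registry import SignatureDefinition

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "block_gene_map",
    "generate_cohort",
    "generate_signature_registry",
    "generate_paired_recurrence",
]

_PSEUDOCOUNT = 1.0

# gene counts of the named signature blocks, carved from the front of the
# gene list; remaining genes are unstructured background
DEFAULT_BLOCK_SIZES: dict[str, int] = {
    "ddr": 70,          # CIN70-style chromosomal-instability block
    "parpi7_sig": 7,
    "parpi7_norm": 7,   # housekeeping-style normalization genes (never shifted)
    "tp53": 20,
    "rps": 4,
    "immune": 40,
    "cxcl13": 10,
    "caf": 30,
    "checkpoint": 6,
    "ddir": 10,
}

# per-cluster mean shifts (log2 units) for the named blocks; the sign
# structure plants a negative CIN70-vs-RPS-score correlation and a positive
# TILs-vs-immune-score correlation at the sample level
DEFAULT_BLOCK_STRUCTURE: dict[str, dict[str, float]] = {
    "immune_high": {"immune": 1.5, "checkpoint": 1.5, "cxcl13": 0.75},
    "immune_low_cxcl13_high": {"cxcl13": 1.5, "immune": -0.75},
    "fibroblast_rps_high": {"caf": 1.5, "rps": -1.5, "ddr": -1.0},
    "ddr_deficient": {"ddr": 1.5, "rps": 0.75, "ddir": 1.5, "immune": -0.75},
}

# Table-1-style marginal frequencies
BRCA_CATEGORIES = ["BRCA1_mutated", "BRCA2_mutated", "BRCA1_methylated", "wildtype", "uncertain"]
BRCA_PROBS = [0.118, 0.027, 0.124, 0.591, 0.140]
PRIOR_CHEMO_RATE = 0.387
ARMS = ("carboplatin", "docetaxel")


def _default_response_model() -> dict:
    logit_orr = float(np.log(0.3 / 0.7))
    return {
        "intercepts": {"carboplatin": logit_orr, "docetaxel": logit_orr},
        "effects": {
            "immune": {"carboplatin": 0.6, "docetaxel": 0.6},
            "ddr": {"carboplatin": 0.8, "docetaxel": 0.0},
        },
    }


def _default_pfs_model() -> dict:
    return {
        "baseline_median": 4.0,  # months
        "effects": {"immune": {"carboplatin": -0.25, "docetaxel": -0.25}},
        "censoring_rate": 0.2,
    }


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort.

    Defaults describe the study conditions the package is exercised under: a
    186-sample cohort (the size of the trial's RNA subset) over 2,000 genes
    with four planted clusters whose block shifts are 3x the per-gene noise
    SD, a 13/186 paired-recurrence fraction, and a +0.36 log2 recurrence
    shift of the CIN70-style block.
    """

    n_samples: int = 186
    n_genes: int = 2000
    cluster_sizes: tuple[int, ...] | None = None
    block_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_BLOCK_SIZES))
    block_structure: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_BLOCK_STRUCTURE.items()}
    )
    noise_sd: float = 0.5
    response_model: dict = field(default_factory=_default_response_model)
    pfs_model: dict = field(default_factory=_default_pfs_model)
    paired_fraction: float = 13 / 186
    recurrence_shift: dict[str, float] = field(default_factory=lambda: {"ddr": 0.36})
    tils_slope: float = 0.8
    tils_noise_sd: float = 0.7
    seed: int = 0

    @property
    def n_clusters(self) -> int:
        return len(self.block_structure)

    def resolved_cluster_sizes(self) -> list[int]:
        if self.cluster_sizes is not None:
            return [int(s) for s in self.cluster_sizes]
        k = self.n_clusters
        base = self.n_samples // k
        sizes = [base] * k
        for i in range(self.n_samples - base * k):
            sizes[i] += 1
        return sizes

    def validate(self) -> None:
        if self.n_samples < 2 or self.n_genes < 1:
            raise ValueError("n_samples and n_genes must be positive (n_samples >= 2)")
        sizes = self.resolved_cluster_sizes()
        if len(sizes) != self.n_clusters:
            raise ValueError("cluster_sizes length must equal the number of planted clusters")
        if any(s <= 0 for s in sizes):
            raise ValueError("all cluster sizes must be positive")
        if sum(sizes) != self.n_samples:
            raise ValueError(f"cluster_sizes sum {sum(sizes)} != n_samples {self.n_samples}")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if sum(self.block_sizes.values()) > self.n_genes:
            raise ValueError("block gene lists exceed n_genes")
        rate = self.pfs_model.get("censoring_rate", 0.0)
        if not 0 <= rate < 1:
            raise ValueError("censoring rate must be in [0, 1)")
        for shifts in self.block_structure.values():
            unknown = set(shifts) - set(self.block_sizes)
            if unknown:
                raise ValueError(f"block_structure references unknown blocks {sorted(unknown)}")


@dataclass
class SyntheticTruth:
    """What the generator planted: labels, model coefficients, shifts."""

    true_cluster: pd.Series
    true_effects: dict
    true_recurrence_shifts: dict[str, float]
    cluster_names: list[str]
    biomarkers: pd.DataFrame  # z-scored block-mean biomarkers used by the models


def block_gene_map(config: CohortConfig) -> dict[str, list[str]]:
    """Deterministic assignment of gene identifiers to named blocks."""
    width = max(4, len(str(config.n_genes)))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]
    blocks: dict[str, list[str]] = {}
    start = 0
    for name, size in config.block_sizes.items():
        blocks[name] = gene_ids[start:start + size]
        start += size
    blocks["_background"] = gene_ids[start:]
    blocks["_all"] = gene_ids
    return blocks


def _log2_means(config: CohortConfig, blocks: dict, labels: np.ndarray,
                rng_base: np.random.Generator) -> pd.DataFrame:
    """Per-gene per-sample log2 mean: baseline plus planted cluster shifts."""
    gene_ids = blocks["_all"]
    base = rng_base.uniform(2.0, 8.0, size=config.n_genes)
    means = np.tile(base[:, None], (1, config.n_samples))
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    cluster_names = list(config.block_structure)
    for ci, cname in enumerate(cluster_names):
        cols = np.flatnonzero(labels == ci + 1)
        for block, shift in config.block_structure[cname].items():
            rows = [gene_pos[g] for g in blocks[block]]
            means[np.ix_(rows, cols)] += shift
    return pd.DataFrame(means, index=gene_ids)


def _censoring_bound(rates: np.ndarray, target: float) -> float:
    """Upper bound b of U(0, b) censoring hitting the target censoring rate."""

    def frac_censored(b):
        return float(np.mean((1.0 - np.exp(-rates * b)) / (rates * b))) - target

    # frac decreases from 1 (b->0) to 0 (b->inf)
    lo, hi = 1e-6, 1e6
    return brentq(frac_censored, lo, hi)


def generate_cohort(config: CohortConfig):
    """Generate ``(expression, clinical, truth)`` for one primary-tumor cohort.

    Returns a non-negative FPKM-scale genes-by-samples DataFrame, a clinical
    table (sample/patient ids, arm, response, PFS, TILs, BRCA category,
    prior-chemo flag, timepoint) and the :class:`SyntheticTruth` record.
    """
    config.validate()
    seq = np.random.SeedSequence(config.seed)
    rng_base, rng_noise, rng_clin = (np.random.default_rng(s) for s in seq.spawn(3))
    n = config.n_samples
    blocks = block_gene_map(config)
    sizes = config.resolved_cluster_sizes()
    labels = np.repeat(np.arange(1, len(sizes) + 1), sizes)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    patient_ids = [f"P{i + 1:04d}" for i in range(n)]

    means = _log2_means(config, blocks, labels, rng_base)
    log2_vals = means.to_numpy() + rng_noise.normal(0.0, config.noise_sd, size=means.shape)
    fpkm = np.maximum(np.exp2(log2_vals) - _PSEUDOCOUNT, 0.0)
    expr = pd.DataFrame(fpkm, index=means.index, columns=sample_ids)

    # block-level biomarkers actually driving outcome models: z-scored mean
    # log2 expression of each shifted block
    log2_df = pd.DataFrame(np.log2(fpkm + _PSEUDOCOUNT), index=means.index,
                           columns=sample_ids)
    biomarker_names = sorted(
        set(config.response_model.get("effects", {}))
        | set(config.pfs_model.get("effects", {}))
        | {"immune", "ddr", "rps"}
    )
    biom = {}
    for name in biomarker_names:
        if name not in blocks or not blocks[name]:
            raise ValueError(f"outcome model references unknown block {name!r}")
        raw = log2_df.loc[blocks[name]].mean(axis=0)
        biom[name] = (raw - raw.mean()) / raw.std(ddof=1)
    biomarkers = pd.DataFrame(biom, index=sample_ids)

    # 1:1 complete randomization
    arm_idx = rng_clin.permutation(n)
    arm = np.empty(n, dtype=object)
    arm[arm_idx[: n // 2]] = ARMS[0]
    arm[arm_idx[n // 2:]] = ARMS[1]

    # objective response from the per-arm logistic model
    eta = np.array([config.response_model["intercepts"][a] for a in arm])
    for name, per_arm in config.response_model.get("effects", {}).items():
        zb = biomarkers[name].to_numpy()
        eta += zb * np.array([per_arm.get(a, 0.0) for a in arm])
    response = (rng_clin.uniform(size=n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)

    # exponential PFS with independent uniform censoring
    log_rate = np.log(np.log(2.0) / config.pfs_model["baseline_median"]) * np.ones(n)
    for name, per_arm in config.pfs_model.get("effects", {}).items():
        zb = biomarkers[name].to_numpy()
        log_rate += zb * np.array([per_arm.get(a, 0.0) for a in arm])
    rates = np.exp(log_rate)
    t_event = rng_clin.exponential(1.0 / rates)
    cens_rate = config.pfs_model.get("censoring_rate", 0.0)
    if cens_rate > 0:
        bound = _censoring_bound(rates, cens_rate)
        t_cens = rng_clin.uniform(0.0, bound, size=n)
    else:
        t_cens = np.full(n, np.inf)
    pfs_time = np.minimum(t_event, t_cens)
    pfs_event = (t_event <= t_cens).astype(int)
    pfs_time = np.maximum(pfs_time, 1e-6)

    # TILs: logit-normal percentage coupled to the immune block
    logit_tils = (-1.5 + config.tils_slope * biomarkers["immune"].to_numpy()
                  + rng_clin.normal(0.0, config.tils_noise_sd, size=n))
    tils = 100.0 / (1.0 + np.exp(-logit_tils))

    brca = rng_clin.choice(BRCA_CATEGORIES, size=n, p=BRCA_PROBS)
    prior_chemo = (rng_clin.uniform(size=n) < PRIOR_CHEMO_RATE).astype(int)

    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "patient_id": patient_ids,
            "arm": arm,
            "response": response,
            "pfs_time": pfs_time,
            "pfs_event": pfs_event,
            "tils": tils,
            "brca_status": brca,
            "prior_chemo": prior_chemo,
            "timepoint": "primary",
        }
    )
    truth = SyntheticTruth(
        true_cluster=pd.Series(labels, index=sample_ids, name="true_cluster"),
        true_effects={"response": config.response_model, "pfs": config.pfs_model},
        true_recurrence_shifts=dict(config.recurrence_shift),
        cluster_names=list(config.block_structure),
        biomarkers=biomarkers,
    )
    return expr, clinical, truth


def generate_signature_registry(config: CohortConfig) -> list[SignatureDefinition]:
    """A registry over the planted blocks covering all eight scoring schemes.

    Weighted, centroid and enrichment content is drawn deterministically from
    the config seed; gene lists are subsets of the generated identifiers.
    """
    blocks = block_gene_map(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    tp53_genes = blocks["tp53"]
    mut_profile = rng.uniform(2.0, 8.0, size=len(tp53_genes))
    wt_profile = rng.uniform(2.0, 8.0, size=len(tp53_genes))
    parpi7_weights = np.round(rng.uniform(-1.0, 1.0, size=len(blocks["parpi7_sig"])), 3)
    ddir_weights = np.round(rng.uniform(-0.2, 0.2, size=len(blocks["ddir"])), 3)
    immune = blocks["immune"]
    return [
        SignatureDefinition("CIN70_like", "mean_centered", list(blocks["ddr"])),
        SignatureDefinition(
            "PARPi7_like", "weighted_normalized", list(blocks["parpi7_sig"]),
            weights=parpi7_weights.tolist(),
            normalization_genes=list(blocks["parpi7_norm"]),
            boundaries=(-3.0, 3.0),
        ),
        SignatureDefinition(
            "TP53_like", "nearest_centroid", list(tp53_genes),
            centroids={
                "mutant": dict(zip(tp53_genes, mut_profile.tolist())),
                "wildtype": dict(zip(tp53_genes, wt_profile.tolist())),
            },
        ),
        SignatureDefinition("RPS_like", "negated_sum", list(blocks["rps"])),
        SignatureDefinition("IGG_like", "median_log2", list(immune[:25])),
        SignatureDefinition("CXCL13_like", "median_log2", list(blocks["cxcl13"])),
        SignatureDefinition("PDL1_like", "single_gene", [blocks["checkpoint"][0]]),
        SignatureDefinition("CAF_S1_like", "first_pc", list(blocks["caf"])),
        SignatureDefinition("TME_T_cells", "enrichment", list(immune[:20])),
        SignatureDefinition("TME_B_cells", "enrichment", list(immune[20:])),
        SignatureDefinition(
            "TME_Fibroblasts", "enrichment", list(blocks["caf"][:20]),
            exclude_from_average=True,
        ),
        SignatureDefinition(
            "DDIR_like", "linear_weighted", list(blocks["ddir"]),
            weights=ddir_weights.tolist(), bias=0.5, input_scale="fpkm",
        ),
    ]


def generate_paired_recurrence(cohort, config: CohortConfig):
    """Add one recurrence sample per selected patient.

    ``cohort`` is the ``(expression, clinical, truth)`` triple of
    :func:`generate_cohort`. Recurrence expression is the patient's planted
    log2 mean plus the configured per-block recurrence shifts and fresh
    noise; clinical covariates are carried over with timepoint "recurrence".
    Returns the extended ``(expression, clinical)``.
    """
    expr, clinical, truth = cohort
    config.validate()
    n_pairs = int(round(config.paired_fraction * config.n_samples))
    if n_pairs < 2:
        raise ValueError("paired_fraction * n_samples must be >= 2")
    seq = np.random.SeedSequence(config.seed)
    rng_base = np.random.default_rng(seq.spawn(3)[0])
    rng_rec = np.random.default_rng(seq.spawn(5)[4])
    blocks = block_gene_map(config)
    labels = truth.true_cluster.to_numpy()
    means = _log2_means(config, blocks, labels, rng_base)  # replays the base draw

    chosen = np.sort(rng_rec.choice(config.n_samples, size=n_pairs, replace=False))
    gene_pos = {g: i for i, g in enumerate(means.index)}
    shift_vec = np.zeros(config.n_genes)
    for block, shift in config.recurrence_shift.items():
        if block not in blocks:
            raise ValueError(f"recurrence_shift references unknown block {block!r}")
        for g in blocks[block]:
            shift_vec[gene_pos[g]] = shift
    rec_means = means.to_numpy()[:, chosen] + shift_vec[:, None]
    rec_log2 = rec_means + rng_rec.normal(0.0, config.noise_sd, size=rec_means.shape)
    rec_fpkm = np.maximum(np.exp2(rec_log2) - _PSEUDOCOUNT, 0.0)
    rec_ids = [f"{expr.columns[i]}R" for i in chosen]
    rec_expr = pd.DataFrame(rec_fpkm, index=expr.index, columns=rec_ids)

    rec_clin = clinical.iloc[chosen].copy()
    rec_clin["sample_id"] = rec_ids
    rec_clin["timepoint"] = "recurrence"
    expr_ext = pd.concat([expr, rec_expr], axis=1)
    clin_ext = pd.concat([clinical, rec_clin], ignore_index=True)
    return expr_ext, clin_ext
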