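# tnbcsig

Transcriptional biomarker analysis for two-arm trials in advanced
triple-negative breast cancer (TNBC): signature scoring, consensus
conditional-inference-forest clustering, and per-arm predictive statistics —
plus a synthetic cohort generator so the whole pipeline is testable without
controlled-access trial data.

## Who this is for

Translational statisticians and bioinformaticians analysing randomized
trial cohorts with bulk RNA-seq: the question is whether DNA-damage-response
(DDR) markers such as CIN70, PARPi7, the TP53-mutation classifier and RPS, or
immune markers (checkpoint genes, cell-type signatures, TILs), predict
objective response and progression-free survival (PFS) differently between a
platinum arm and a taxane arm, and whether those features define novel
patient subgroups.

## What it computes

**Signature scores.** From a genes-by-samples FPKM matrix and a declarative
signature registry, nine scoring schemes: mean-centred mean
(score_s = mean_g(x_gs − x̄_g)), geometric-mean-normalized weighted sums with
clipping (PARPi7-style, Σ_g w_g·clip(log2(x_gs/GM_s) − med_g)), Spearman
nearest-centroid classification, negated median-centred sums (RPS),
median-log2 module scores, single-gene log2 markers, oriented first
principal components, ssGSEA-type rank-weighted enrichment (weight rank^α,
α = 0.25), and linear weight+bias scores on the FPKM scale (DDIR).

**Novel subgroups.** Z-scored signatures, TILs and BRCA1/2 genotype
categories feed a consensus clustering: 100 repetitions each sampling 80% of
the features, an unsupervised conditional-inference forest per repetition
(trees discriminate real samples from a marginal-preserving permuted
contrast; dissimilarity = 1 − terminal-node co-membership), deterministic
k-medoids partitions, and cluster-number selection from the change in area
under the consensus CDF.

**Treatment-specific effects.** Per arm: univariable logistic regression of
response per biomarker Z-unit and linear regression of restricted mean PFS
via jackknife pseudo-observations (months per Z-unit, HC1 robust CIs), with
Wald treatment-interaction tests for both endpoints; descriptive Wilcoxon /
Kruskal–Wallis + Dunn / Fisher / Spearman tests; paired primary-vs-recurrence
t tests and a random-intercept model with a fixed timepoint effect for
patients with multiple samples. Everything two-sided, unadjusted by default.

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

```python
import pandas as pd
from scipy.stats import spearmanr
import tnbcsig as t

cfg = t.CohortConfig(seed=7)                      # 186 samples x 2,000 genes
expr, clinical, truth = t.generate_cohort(cfg)
registry = t.generate_signature_registry(cfg)

scores = t.score_all(expr, registry)              # samples x signatures
scores_z = t.zscore_columns(scores)

rho, p = spearmanr(scores["CIN70_like"], scores["RPS_like"])
print(f"CIN70 vs RPS: Spearman rho = {rho:.2f} (p = {p:.2g})")

assoc = t.run_associations(scores_z.select_dtypes("number"), clinical)
row = assoc.query("biomarker == 'IGG_like' and arm == 'docetaxel'"
                  " and subgroup == 'all'").iloc[0]
print(f"IGG-cluster score, docetaxel arm: OR/Z = {2.718281828**row.estimate:.2f},"
      f" p = {row.p:.3g}")

features = t.select_clustering_features(assoc, scores_z.select_dtypes("number"),
                                        clinical)
est = t.ForestConsensusCluster(random_state=7).fit(features)
print(f"selected k = {est.selected_k_}, cluster sizes = "
      f"{pd.Series(est.labels_).value_counts().sort_index().tolist()}")
```

prints

```
CIN70 vs RPS: Spearman rho = -0.84 (p = 1.1e-50)
IGG-cluster score, docetaxel arm: OR/Z = 1.61, p = 0.0319
selected k = 4, cluster sizes = [48, 47, 46, 45]
```

The generated cohort plants four clusters and a negative CIN70–RPS score
correlation; scoring, feature selection (any univariable p < 0.05, plus TILs
and BRCA status) and consensus clustering recover exactly that structure:
an odds ratio of 1.61 per Z-unit of the immune score for response on
docetaxel, and four clusters of roughly equal size matching the planted
labels.

The same flow is available from the shell:

```bash
tnbcsig simulate --n-samples 186 --n-genes 2000 --seed 7 --out-dir cohort/
tnbcsig score --expression cohort/expression.tsv --registry cohort/registry.yaml \
        --out scores.csv
tnbcsig run --config pipeline.yaml     # full pipeline with manifest
```

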