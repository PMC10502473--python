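import numpy as np
import pandas as pd
import pytest

from tnbcsig import (
    SignatureDefinition,
    SignatureScorer,
    classify_nearest_centroid,
    log2_transform,
    score_all,
    score_enrichment,
    score_first_pc,
    score_linear_weighted,
    score_mean_centered,
    score_median_log2,
    score_negated_sum,
    score_single_gene,
    score_weighted_normalized,
    select_top_genes,
    zscore_columns,
)

from tests import _oracles


def _frame(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestLog2Transform:
    def test_known_values(self):
        expr = _frame([[0.0, 7.0]])
        out = log2_transform(expr, pseudocount=1.0)
        assert out.iloc[0, 0] == 0.0
        assert out.iloc[0, 1] == 3.0

    def test_elementwise_oracle(self, rng):
        expr = _oracles.random_expression(rng, 5, 4)
        out = log2_transform(expr, 1.0)
        np.testing.assert_allclose(out.to_numpy(), np.log2(expr.to_numpy() + 1),
                                   atol=1e-12)

    def test_zero_pseudocount_with_zero_rejected(self):
        with pytest.raises(ValueError, match="log2"):
            log2_transform(_frame([[0.0]]), pseudocount=0.0)

    def test_monotone(self, rng):
        expr = _oracles.random_expression(rng, 6, 3)
        out = log2_transform(expr, 1.0)
        order_in = np.argsort(expr.to_numpy().ravel())
        order_out = np.argsort(out.to_numpy().ravel())
        np.testing.assert_array_equal(order_in, order_out)


class TestMeanCentered:
    def test_hand_example(self):
        log2x = _frame([[1.0, 3.0], [3.0, 3.0]])
        sig = SignatureDefinition("cin", "mean_centered", ["g0", "g1"])
        np.testing.assert_allclose(score_mean_centered(log2x, sig).to_numpy(),
                                   [-0.5, 0.5])

    def test_scores_sum_to_zero(self, rng):
        log2x = _frame(rng.normal(size=(6, 9)))
        sig = SignatureDefinition("cin", "mean_centered", [f"g{i}" for i in range(6)])
        assert abs(score_mean_centered(log2x, sig).sum()) < 1e-9

    def test_sample_permutation_equivariance(self, rng):
        log2x = _frame(rng.normal(size=(5, 7)))
        sig = SignatureDefinition("cin", "mean_centered", [f"g{i}" for i in range(5)])
        base = score_mean_centered(log2x, sig)
        perm = list(reversed(log2x.columns))
        permuted = score_mean_centered(log2x[perm], sig)
        np.testing.assert_allclose(permuted.loc[base.index].to_numpy(),
                                   base.to_numpy(), atol=1e-12)

    def test_no_gene_present_errors(self, rng):
        log2x = _frame(rng.normal(size=(3, 3)))
        sig = SignatureDefinition("cin", "mean_centered", ["absent1", "absent2"])
        with pytest.raises(KeyError, match="cin"):
            score_mean_centered(log2x, sig)


class TestWeightedNormalized:
    def test_identical_genes_give_zero_log_ratios(self):
        # all genes share one value per sample: ratios are 1, log2 ratios 0,
        # median-centring keeps them 0, so the score is exactly the bias
        expr = _frame(np.tile([[3.0, 9.0, 17.0]], (4, 1)))
        sig = SignatureDefinition(
            "parpi", "weighted_normalized", ["g0", "g1"],
            weights=[2.0, -1.0], normalization_genes=["g0", "g1", "g2", "g3"],
            bias=0.25,
        )
        np.testing.assert_allclose(score_weighted_normalized(expr, sig).to_numpy(),
                                   [0.25, 0.25, 0.25], atol=1e-12)

    def test_zero_weights_give_bias(self, rng):
        expr = _oracles.random_expression(rng, 6, 5)
        sig = SignatureDefinition(
            "parpi", "weighted_normalized", ["G000", "G001"], weights=[0.0, 0.0],
            normalization_genes=["G002", "G003"], bias=1.5,
        )
        np.testing.assert_allclose(score_weighted_normalized(expr, sig).to_numpy(),
                                   1.5, atol=1e-12)

    def test_brute_force_oracle(self, rng):
        expr = _oracles.random_expression(rng, 10, 6)
        genes = [f"G{i:03d}" for i in range(5)]
        norm = [f"G{i:03d}" for i in range(5, 10)]
        weights = rng.normal(size=5).tolist()
        sig = SignatureDefinition("parpi", "weighted_normalized", genes,
                                  weights=weights, normalization_genes=norm,
                                  boundaries=(-1.0, 1.0), bias=0.3)
        expected = _oracles.weighted_normalized(expr, genes, weights, norm,
                                                (-1.0, 1.0), 0.3)
        np.testing.assert_allclose(score_weighted_normalized(expr, sig).to_numpy(),
                                   expected, atol=1e-9)

    def test_missing_normalization_gene_errors(self, rng):
        expr = _oracles.random_expression(rng, 4, 3)
        sig = SignatureDefinition("parpi", "weighted_normalized", ["G000"],
                                  weights=[1.0], normalization_genes=["missing"])
        with pytest.raises(KeyError, match="normalization"):
            score_weighted_normalized(expr, sig)


class TestNearestCentroid:
    def _sig(self, centroids, genes):
        return SignatureDefinition("tp53", "nearest_centroid", genes,
                                   centroids=centroids)

    def test_exact_match_wins_with_correlation_one(self):
        genes = [f"g{i}" for i in range(5)]
        profile = [1.0, 2.0, 3.0, 4.0, 5.0]
        cents = {"A": dict(zip(genes, profile)),
                 "B": dict(zip(genes, reversed(profile)))}
        log2x = _frame(np.array(profile)[:, None], genes=genes, samples=["s0"])
        labels, corr = classify_nearest_centroid(log2x, self._sig(cents, genes))
        assert labels.iloc[0] == "A"
        assert corr.loc["s0", "A"] == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_transform(self):
        genes = [f"g{i}" for i in range(5)]
        cents = {"A": dict(zip(genes, [1, 2, 3, 4, 5])),
                 "B": dict(zip(genes, [5, 4, 3, 2, 1]))}
        decreasing = np.array([10.0, 8.0, 5.0, 3.0, 1.0])  # strictly decreasing of A
        log2x = _frame(decreasing[::-1][:, None], genes=genes, samples=["s0"])
        labels, _ = classify_nearest_centroid(log2x, self._sig(cents, genes))
        assert labels.iloc[0] == "A"

    def test_hand_computed_spearman(self):
        genes = [f"g{i}" for i in range(5)]
        cents = {"A": dict(zip(genes, [1.0, 2.0, 3.0, 5.0, 4.0])),
                 "B": dict(zip(genes, [5.0, 4.0, 3.0, 2.0, 1.0]))}
        log2x = _frame(np.array([1.0, 2.0, 3.0, 4.0, 5.0])[:, None],
                       genes=genes, samples=["s0"])
        labels, corr = classify_nearest_centroid(log2x, self._sig(cents, genes))
        assert labels.iloc[0] == "A"
        assert corr.loc["s0", "A"] == pytest.approx(0.9)
        assert corr.loc["s0", "B"] == pytest.approx(-1.0)

    def test_constant_profile_unclassifiable(self):
        genes = [f"g{i}" for i in range(5)]
        cents = {"A": dict(zip(genes, [1, 2, 3, 4, 5])),
                 "B": dict(zip(genes, [2, 1, 4, 3, 5]))}
        log2x = _frame(np.full((5, 1), 2.0), genes=genes, samples=["s0"])
        labels, _ = classify_nearest_centroid(log2x, self._sig(cents, genes))
        assert labels.iloc[0] == "unclassifiable"

    def test_too_few_shared_genes_errors(self):
        genes = ["g0", "g1"]
        cents = {"A": {"g0": 1.0, "g1": 2.0}, "B": {"g0": 2.0, "g1": 1.0}}
        log2x = _frame(np.ones((2, 2)), genes=genes)
        with pytest.raises(ValueError, match=">=3"):
            classify_nearest_centroid(log2x, self._sig(cents, genes))

    def test_oracle_agreement(self, rng):
        genes = [f"g{i}" for i in range(8)]
        cents = {lab: dict(zip(genes, rng.normal(size=8))) for lab in ("A", "B", "C")}
        log2x = _frame(rng.normal(size=(8, 6)), genes=genes)
        sig = self._sig(cents, genes)
        labels, corr = classify_nearest_centroid(log2x, sig)
        exp_labels, exp_corrs = _oracles.nearest_centroid(log2x, genes, cents)
        assert labels.tolist() == exp_labels
        for i, sample in enumerate(log2x.columns):
            for lab in cents:
                assert corr.loc[sample, lab] == pytest.approx(exp_corrs[i][lab], abs=1e-9)


class TestNegatedSum:
    def test_sample_at_median_scores_zero(self):
        log2x = _frame([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        sig = SignatureDefinition("rps", "negated_sum", ["g0", "g1"])
        scores = score_negated_sum(log2x, sig)
        assert scores.iloc[1] == pytest.approx(0.0)

    def test_one_unit_above_median_scores_minus_one(self):
        log2x = _frame([[0.0, 0.0, 1.0], [0.0, 0.0, 0.0]])
        sig = SignatureDefinition("rps", "negated_sum", ["g0", "g1"])
        scores = score_negated_sum(log2x, sig)
        assert scores.iloc[2] == pytest.approx(-1.0)

    def test_oracle(self, rng):
        log2x = _frame(rng.normal(size=(4, 7)))
        sig = SignatureDefinition("rps", "negated_sum", [f"g{i}" for i in range(4)])
        np.testing.assert_allclose(score_negated_sum(log2x, sig).to_numpy(),
                                   _oracles.negated_sum(log2x, sig.genes), atol=1e-12)


class TestMedianLog2:
    def test_single_gene_signature(self, rng):
        log2x = _frame(rng.normal(size=(3, 4)))
        sig = SignatureDefinition("m", "median_log2", ["g1"])
        np.testing.assert_allclose(score_median_log2(log2x, sig).to_numpy(),
                                   log2x.loc["g1"].to_numpy())

    def test_median_robust_to_outlier(self):
        log2x = _frame(np.array([[1.0], [5.0], [100.0]]))
        sig = SignatureDefinition("m", "median_log2", ["g0", "g1", "g2"])
        assert score_median_log2(log2x, sig).iloc[0] == 5.0

    def test_oracle(self, rng):
        log2x = _frame(rng.normal(size=(9, 5)))
        genes = [f"g{i}" for i in range(0, 9, 2)]
        sig = SignatureDefinition("m", "median_log2", genes)
        np.testing.assert_allclose(score_median_log2(log2x, sig).to_numpy(),
                                   _oracles.median_log2(log2x, genes), atol=1e-12)


class TestSingleGene:
    def test_matches_log2_transform_row(self, rng):
        expr = _oracles.random_expression(rng, 5, 4)
        log2x = log2_transform(expr, 1.0)
        np.testing.assert_array_equal(score_single_gene(log2x, "G002").to_numpy(),
                                      log2x.loc["G002"].to_numpy())

    def test_absent_gene_errors(self, rng):
        log2x = _frame(np.ones((2, 2)))
        with pytest.raises(KeyError, match="nope"):
            score_single_gene(log2x, "nope")


class TestSelectTopGenes:
    @staticmethod
    def _table(rng, n=120):
        return pd.DataFrame({
            "gene_id": [f"g{i:03d}" for i in range(n)],
            "log_fold_change": rng.uniform(-1, 4, size=n),
            "fdr": rng.uniform(0, 0.05, size=n),
            "cell_type": rng.choice(["cd8_trm", "cd4_trm"], size=n),
        })

    def test_cap_at_n_top(self):
        de = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(60)],
            "log_fold_change": 2.0,
            "fdr": 0.001,
            "cell_type": "cd8_trm",
        })
        assert len(select_top_genes(de, "cd8_trm")) == 50

    def test_strict_lfc_boundary(self):
        de = pd.DataFrame({
            "gene_id": ["edge", "in"],
            "log_fold_change": [1.0, 1.01],
            "fdr": [0.001, 0.001],
            "cell_type": "cd8_trm",
        })
        assert select_top_genes(de, "cd8_trm") == ["in"]

    def test_brute_force_oracle(self, rng):
        de = self._table(rng)
        got = select_top_genes(de, "cd8_trm", lfc_min=0.5, fdr_max=0.02, n_top=10)
        assert got == _oracles.select_top(de, "cd8_trm", 0.5, 0.02, 10)

    def test_empty_filter_returns_empty(self):
        de = pd.DataFrame({"gene_id": ["a"], "log_fold_change": [0.1],
                           "fdr": [0.5], "cell_type": ["cd8_trm"]})
        assert select_top_genes(de, "cd8_trm") == []


class TestFirstPC:
    def test_rank_one_recovery(self, rng):
        pattern = rng.normal(size=12)
        loadings = rng.uniform(0.5, 2.0, size=6)
        log2x = _frame(np.outer(loadings, pattern))
        sig = SignatureDefinition("pc", "first_pc", [f"g{i}" for i in range(6)])
        scores = score_first_pc(log2x, sig)
        centred = pattern - pattern.mean()
        rho = np.corrcoef(scores, centred)[0, 1]
        assert abs(rho) == pytest.approx(1.0, abs=1e-10)

    def test_eigen_oracle(self, rng):
        log2x = _frame(rng.normal(size=(7, 10)))
        sig = SignatureDefinition("pc", "first_pc", [f"g{i}" for i in range(7)])
        scores = score_first_pc(log2x, sig).to_numpy()
        expected = _oracles.first_pc(log2x, sig.genes)
        agreement = min(np.max(np.abs(scores - expected)),
                        np.max(np.abs(scores + expected)))
        assert agreement < 1e-8

    def test_orientation_contract(self, rng):
        for _ in range(5):
            log2x = _frame(rng.normal(size=(5, 8)))
            sig = SignatureDefinition("pc", "first_pc", [f"g{i}" for i in range(5)])
            scores = score_first_pc(log2x, sig)
            mean_expr = log2x.mean(axis=0)
            assert np.corrcoef(scores, mean_expr)[0, 1] >= 0

    def test_zero_variance_errors(self):
        log2x = _frame(np.ones((4, 5)))
        sig = SignatureDefinition("pc", "first_pc", [f"g{i}" for i in range(4)])
        with pytest.raises(ValueError, match="variance"):
            score_first_pc(log2x, sig)


class TestEnrichment:
    def test_whole_matrix_set_is_degenerate(self, rng):
        expr = _oracles.random_expression(rng, 12, 5)
        scores, _ = score_enrichment(expr, {"all": list(expr.index)})
        assert np.ptp(scores["all"].to_numpy()) < 1e-9

    def test_brute_force_oracle(self, rng):
        from tnbcsig.scoring import _enrichment_raw

        expr = _oracles.random_expression(rng, 20, 3)
        genes = list(expr.index[rng.choice(20, size=5, replace=False)])
        got = _enrichment_raw(expr, genes, alpha=0.25)
        expected = _oracles.enrichment_raw(expr, genes, alpha=0.25)
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_top_ranked_sample_scores_higher(self):
        genes = [f"G{i:03d}" for i in range(20)]
        set_genes = genes[:5]
        # sample "hi": set genes have the largest values; "lo": the smallest
        hi = np.concatenate([np.arange(100, 105), np.arange(5, 20)]).astype(float)
        lo = np.concatenate([np.arange(1, 6), np.arange(100, 115)]).astype(float)
        expr = pd.DataFrame({"hi": hi, "lo": lo}, index=genes)
        scores, _ = score_enrichment(expr, {"s": set_genes})
        assert scores.loc["hi", "s"] > scores.loc["lo", "s"]

    def test_empty_intersection_errors(self, rng):
        expr = _oracles.random_expression(rng, 5, 3)
        with pytest.raises(KeyError, match="missing_set"):
            score_enrichment(expr, {"missing_set": ["nope"]})

    def test_average_excludes_flagged_sets(self, rng):
        expr = _oracles.random_expression(rng, 15, 4)
        sets = {"t": list(expr.index[:5]), "b": list(expr.index[5:10]),
                "fibro": list(expr.index[10:])}
        scores, avg = score_enrichment(expr, sets, exclude_from_average=("fibro",))
        np.testing.assert_allclose(avg.to_numpy(),
                                   scores[["t", "b"]].mean(axis=1).to_numpy())


class TestLinearWeighted:
    def test_zero_weights_give_bias(self, rng):
        expr = _oracles.random_expression(rng, 3, 4)
        sig = SignatureDefinition("ddir", "linear_weighted", ["G000", "G001"],
                                  weights=[0.0, 0.0], bias=2.5, input_scale="fpkm")
        np.testing.assert_allclose(score_linear_weighted(expr, sig).to_numpy(), 2.5)

    def test_hand_arithmetic(self):
        expr = _frame(np.array([[2.0], [3.0], [1.0]]))
        sig = SignatureDefinition("ddir", "linear_weighted", ["g0", "g1", "g2"],
                                  weights=[1.0, -1.0, 2.0], bias=0.5,
                                  input_scale="fpkm")
        assert score_linear_weighted(expr, sig).iloc[0] == pytest.approx(1.5)

    def test_linearity_in_expression(self, rng):
        expr = _oracles.random_expression(rng, 5, 4)
        sig = SignatureDefinition("ddir", "linear_weighted", list(expr.index),
                                  weights=rng.normal(size=5).tolist(), bias=0.7,
                                  input_scale="fpkm")
        s1 = score_linear_weighted(expr, sig)
        s3 = score_linear_weighted(3.0 * expr, sig)
        np.testing.assert_allclose(s3.to_numpy(), 3.0 * (s1 - 0.7) + 0.7, atol=1e-9)


class TestScoreAll:
    def test_registry_columns_finite_and_complete(self, small_cohort, small_registry):
        expr, _, _ = small_cohort
        table = score_all(expr, small_registry)
        numeric = table.select_dtypes(include=[np.number])
        assert np.isfinite(numeric.to_numpy()).all()
        for sig in small_registry:
            assert sig.name in table.columns

    def test_dispatch_matches_standalone_operations(self, small_cohort, small_registry):
        expr, _, _ = small_cohort
        table = score_all(expr, small_registry)
        log2x = log2_transform(expr, 1.0)
        by_scheme = {s.scheme: s for s in small_registry}
        sig = by_scheme["mean_centered"]
        np.testing.assert_allclose(table[sig.name].to_numpy(),
                                   score_mean_centered(log2x, sig).to_numpy())
        sig = by_scheme["negated_sum"]
        np.testing.assert_allclose(table[sig.name].to_numpy(),
                                   score_negated_sum(log2x, sig).to_numpy())
        sig = by_scheme["median_log2"]
        np.testing.assert_allclose(table[sig.name].to_numpy(),
                                   score_median_log2(log2x, sig).to_numpy())
        sig = by_scheme["first_pc"]
        np.testing.assert_allclose(table[sig.name].to_numpy(),
                                   score_first_pc(log2x, sig).to_numpy())
        sig = by_scheme["linear_weighted"]
        np.testing.assert_allclose(table[sig.name].to_numpy(),
                                   score_linear_weighted(expr, sig).to_numpy())

    def test_empty_registry_errors(self, small_cohort):
        expr, _, _ = small_cohort
        with pytest.raises(ValueError, match="registry"):
            score_all(expr, [])

    def test_cohort_dependence_is_real(self, small_cohort, small_registry):
        # mean-centred scores depend on the full sample set: dropping a sample
        # changes the scores of the others
        expr, _, _ = small_cohort
        sig = next(s for s in small_registry if s.scheme == "mean_centered")
        log2x = log2_transform(expr, 1.0)
        full = score_mean_centered(log2x, sig)
        reduced = score_mean_centered(log2x.iloc[:, :-5], sig)
        assert not np.allclose(full.iloc[:-5].to_numpy(), reduced.to_numpy())


class TestSignatureScorer:
    def test_fit_transform_equals_score_all(self, small_cohort, small_registry):
        expr, _, _ = small_cohort
        est = SignatureScorer(registry=small_registry)
        table = est.fit(expr).transform(expr)
        ref = score_all(expr, small_registry)
        pd.testing.assert_frame_equal(table, ref)

    def test_frozen_statistics_differ_from_refit(self, small_cohort, small_registry):
        expr, _, _ = small_cohort
        train, test = expr.iloc[:, :40], expr.iloc[:, 40:]
        sig_name = next(s.name for s in small_registry if s.scheme == "mean_centered")
        frozen = SignatureScorer(registry=small_registry).fit(train).transform(test)
        refit = score_all(test, small_registry)
        assert not np.allclose(frozen[sig_name].to_numpy(), refit[sig_name].to_numpy())

    def test_sklearn_params_roundtrip(self, small_registry):
        est = SignatureScorer(registry=small_registry, pseudocount=2.0)
        params = est.get_params()
        assert params["pseudocount"] == 2.0
        est.set_params(pseudocount=0.5)
        assert est.pseudocount == 0.5


class TestZscoreColumns:
    def test_known_column(self):
        scores = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        np.testing.assert_allclose(zscore_columns(scores)["a"].to_numpy(), [-1, 0, 1])

    def test_mean_zero_sd_one(self, rng):
        scores = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        z = zscore_columns(scores)
        np.testing.assert_allclose(z.mean().to_numpy(), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(ddof=1).to_numpy(), 1.0, atol=1e-9)

    def test_affine_invariance(self, rng):
        x = pd.DataFrame({"a": rng.normal(size=20)})
        np.testing.assert_allclose(zscore_columns(3.0 * x + 7.0)["a"].to_numpy(),
                                   zscore_columns(x)["a"].to_numpy(), atol=1e-9)

    def test_categorical_columns_untouched(self, rng):
        scores = pd.DataFrame({"a": rng.normal(size=4), "call": list("xyzx")})
        z = zscore_columns(scores)
        assert z["call"].tolist() == list("xyzx")

    def test_zero_sd_errors(self):
        with pytest.raises(ValueError, match="flat"):
            zscore_columns(pd.DataFrame({"flat": [1.0, 1.0, 1.0]}))
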