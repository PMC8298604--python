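import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import txage
from txage.datamodel import ValidationError
from txage.de import NBWaldDE, _irls_nb
from conftest import make_group_metadata, nb_counts


# ---------------------------------------------------------------------------
# size factors


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame([[5, 5], [7, 7]], index=["a", "b"], columns=["x", "y"])
        np.testing.assert_allclose(txage.size_factors(counts), [1.0, 1.0])

    def test_hand_computed_two_gene_example(self):
        # geometric means (2.828, 4.243); per-sample ratio medians 1/sqrt2, sqrt2
        counts = pd.DataFrame([[2, 4], [3, 6]], index=["a", "b"], columns=["x", "y"])
        np.testing.assert_allclose(
            txage.size_factors(counts), [0.7071, 1.4142], atol=5e-5
        )

    def test_scale_equivariance_of_factor_ratios(self):
        """Scaling one sample's column by 3 multiplies its size factor by 3
        relative to every other sample (the per-gene geometric means shift by
        3^(1/n), so only ratios are exactly equivariant)."""
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(1, 100, size=(50, 6)))
        scaled = counts.copy()
        scaled[3] = counts[3] * 3
        base = txage.size_factors(counts)
        new = txage.size_factors(scaled)
        np.testing.assert_allclose(
            (new[3] / new[0]), 3 * base[3] / base[0], rtol=1e-12
        )

    def test_proportional_columns_scaled_identically_give_ones(self):
        rng = np.random.default_rng(1)
        col = rng.integers(1, 50, size=30)
        counts = pd.DataFrame({f"s{j}": col for j in range(4)})
        np.testing.assert_allclose(txage.size_factors(counts), np.ones(4))

    def test_no_all_positive_gene_is_an_error(self):
        counts = pd.DataFrame([[0, 1], [1, 0]], index=["a", "b"], columns=["x", "y"])
        with pytest.raises(ValidationError, match="positive counts"):
            txage.size_factors(counts)


# ---------------------------------------------------------------------------
# expression filter


class TestFilter:
    @pytest.fixture()
    def annotated(self):
        counts = txage.CountMatrix(
            pd.DataFrame(
                {"s1": [5, 5, 1, 2], "s2": [5, 5, 1, 1]},
                index=["coding_hi", "linc", "coding_mean1", "coding_mean1p5"],
            )
        )
        annotation = txage.GeneAnnotation(
            pd.DataFrame(
                {"biotype": ["protein_coding", "lincRNA",
                             "protein_coding", "protein_coding"]},
                index=counts.counts.index,
            )
        )
        return counts, annotation

    def test_noncoding_removed_and_mean_rule_strict(self, annotated):
        kept = txage.filter_genes_for_de(*annotated)
        assert kept.gene_ids == ["coding_hi", "coding_mean1p5"]

    def test_empty_result_errors(self):
        counts = txage.CountMatrix(pd.DataFrame({"s": [1]}, index=["g"]))
        annotation = txage.GeneAnnotation(
            pd.DataFrame({"biotype": ["lincRNA"]}, index=["g"])
        )
        with pytest.raises(ValidationError):
            txage.filter_genes_for_de(counts, annotation)


# ---------------------------------------------------------------------------
# BH adjustment


def bh_bruteforce(p):
    """Independent step-up implementation straight from the definition."""
    p = list(p)
    m = len(p)
    ranks = {}
    for i, val in enumerate(sorted(range(m), key=lambda j: p[j])):
        ranks[val] = i + 1
    out = []
    for i in range(m):
        candidates = [
            m * p[j] / ranks[j] for j in range(m) if p[j] >= p[i] - 1e-15
        ]
        out.append(min(1.0, min(candidates)))
    return out


class TestBH:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
            ((0.3,), (0.3,)),
            ((0.005, 0.5), (0.01, 0.5)),
        ],
    )
    def test_hand_computed_examples(self, p, expected):
        np.testing.assert_allclose(txage.bh_adjust(p), expected)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(st.sampled_from([0.0, 0.001, 0.01, 0.04, 0.05, 0.2, 0.5, 0.9, 1.0]),
                    min_size=1, max_size=6))
    def test_matches_bruteforce_definition(self, p):
        np.testing.assert_allclose(txage.bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=40)
        perm = rng.permutation(40)
        np.testing.assert_allclose(txage.bh_adjust(p)[perm], txage.bh_adjust(p[perm]))

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(size=100)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(txage.bh_adjust(p), expected)

    def test_nan_passthrough_shrinks_m(self):
        out = txage.bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0.02, 0.02])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            txage.bh_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# quartile groups


class TestQuartiles:
    def test_hand_computed_interpolated_quantiles(self):
        md = make_group_metadata([f"s{i}" for i in range(8)], 4)
        md.table["age"] = np.arange(1.0, 9.0)
        low, high = txage.quartile_groups(md, "age")
        assert set(low) == {"s0", "s1"}   # Q1 = 2.75
        assert set(high) == {"s6", "s7"}  # Q3 = 6.25

    def test_distinct_values_give_quarter_sized_groups(self):
        md = make_group_metadata([f"s{i}" for i in range(100)], 50)
        rng = np.random.default_rng(0)
        md.table["age"] = rng.permutation(100).astype(float)
        low, high = txage.quartile_groups(md, "age")
        assert len(low) == 25 and len(high) == 25
        assert not set(low) & set(high)

    def test_ties_straddling_q1_all_included(self):
        md = make_group_metadata([f"s{i}" for i in range(8)], 4)
        md.table["age"] = [1.0, 2, 2, 2, 5, 6, 7, 8]
        low, _ = txage.quartile_groups(md, "age")
        # Q1 = 2.0; every sample valued exactly 2 joins the low set
        assert set(low) == {"s0", "s1", "s2", "s3"}

    def test_degenerate_spread_errors(self):
        md = make_group_metadata([f"s{i}" for i in range(10)], 5)
        md.table["age"] = 30.0
        with pytest.raises(ValidationError, match="Q1 == Q3"):
            txage.quartile_groups(md, "age")


# ---------------------------------------------------------------------------
# dispersion estimation


class TestDispersions:
    def test_constant_normalised_counts_hit_floor(self):
        counts = pd.DataFrame(np.full((30, 10), 7))
        disp = txage.estimate_dispersions(counts, trend_weight=0.0)
        assert (disp <= 1e-6).all()

    def test_poisson_genes_estimated_near_zero(self):
        rng = np.random.default_rng(3)
        mu = rng.uniform(50, 500, size=100)
        counts = pd.DataFrame(rng.poisson(np.tile(mu[:, None], (1, 1000))))
        disp = txage.estimate_dispersions(counts)
        assert disp.median() <= 0.05
        assert (disp >= 1e-8).all()

    def test_alpha_half_recovered_within_20pct(self):
        rng = np.random.default_rng(4)
        mu = rng.uniform(50, 500, size=100)
        counts = pd.DataFrame(
            nb_counts(rng, np.tile(mu[:, None], (1, 1000)), 0.5, (100, 1000))
        )
        disp = txage.estimate_dispersions(counts)
        assert 0.4 <= disp.median() <= 0.6
        assert (disp.between(0.4, 0.6)).mean() > 0.8

    def test_single_sample_is_an_error(self):
        with pytest.raises(ValidationError):
            txage.estimate_dispersions(pd.DataFrame({"s": [1, 2]}))


# ---------------------------------------------------------------------------
# NB Wald fit


def two_group_counts(rng, n_genes, n_per_group, mu, alpha, log2fc=0.0,
                     n_affected=None):
    """Two-group NB counts; only the first ``n_affected`` genes carry the fold
    change (default all) so size factors stay anchored by null genes."""
    if n_affected is None:
        n_affected = n_genes
    lfc = np.zeros((n_genes, 1))
    lfc[:n_affected] = log2fc
    mu_b = mu * 2.0**lfc
    a = nb_counts(rng, np.full((n_genes, 1), float(mu)), alpha,
                  (n_genes, n_per_group))
    b = nb_counts(rng, mu_b, alpha, (n_genes, n_per_group))
    df = pd.DataFrame(
        np.hstack([a, b]),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(2 * n_per_group)],
    )
    design = pd.DataFrame(
        {"grp": [0.0] * n_per_group + [1.0] * n_per_group}, index=df.columns
    )
    return df, design


class TestNBWald:
    def test_null_genes_rarely_significant(self):
        rng = np.random.default_rng(5)
        df, design = two_group_counts(rng, 100, 100, 100.0, 0.1)
        sf = txage.size_factors(df)
        disp = txage.estimate_dispersions(df, sf)
        res = txage.fit_nb_wald(df, design, "grp", sf, disp, cooks_cutoff=None)
        calm = (res["log2fc"].abs() < 0.2) & (res["p"] > 0.01)
        assert calm.mean() >= 0.95

    def test_planted_log2fc_one_recovered(self):
        rng = np.random.default_rng(6)
        df, design = two_group_counts(rng, 2000, 50, 100.0, 0.1, log2fc=1.0,
                                      n_affected=100)
        sf = txage.size_factors(df)
        disp = txage.estimate_dispersions(df, sf)
        res = txage.fit_nb_wald(df, design, "grp", sf, disp, cooks_cutoff=None)
        assert 0.8 <= res["log2fc"].iloc[:100].mean() <= 1.2

    def test_all_zero_gene_untested(self):
        df = pd.DataFrame(
            [[0, 0, 0, 0], [5, 6, 7, 8]], index=["dead", "ok"],
            columns=list("abcd"),
        )
        design = pd.DataFrame({"grp": [0.0, 0, 1, 1]}, index=df.columns)
        sf = pd.Series(1.0, index=df.columns)
        disp = pd.Series(0.1, index=df.index)
        res = txage.fit_nb_wald(df, design, "grp", sf, disp)
        assert not res.loc["dead", "tested_flag"]
        assert np.isnan(res.loc["dead", "p"])
        assert res.loc["ok", "tested_flag"]

    def test_sign_convention_positive_means_higher_in_second_level(self):
        rng = np.random.default_rng(7)
        df, design = two_group_counts(rng, 200, 60, 100.0, 0.05, log2fc=1.0,
                                      n_affected=50)
        sf = txage.size_factors(df)
        disp = txage.estimate_dispersions(df, sf)
        res = txage.fit_nb_wald(df, design, "grp", sf, disp)
        assert (res["log2fc"].iloc[:50] > 0).mean() > 0.95

    def test_matches_statsmodels_glm_per_gene(self):
        """Dual route: the vectorised IRLS equals statsmodels' NB GLM with the
        same fixed dispersion, gene by gene."""
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        df, design = two_group_counts(rng, 5, 40, 80.0, 0.2, log2fc=0.5,
                                      n_affected=3)
        sf = txage.size_factors(df)
        disp = pd.Series(0.2, index=df.index)
        res = txage.fit_nb_wald(df, design, "grp", sf, disp, cooks_cutoff=None)
        X = np.column_stack([np.ones(df.shape[1]), design["grp"].to_numpy()])
        for gene in df.index:
            fit = sm.GLM(
                df.loc[gene].to_numpy(),
                X,
                family=sm.families.NegativeBinomial(alpha=0.2),
                offset=np.log(sf.to_numpy()),
            ).fit()
            np.testing.assert_allclose(
                res.loc[gene, "log2fc"], fit.params[1] / np.log(2), atol=1e-4
            )
            np.testing.assert_allclose(
                res.loc[gene, "se"], fit.bse[1] / np.log(2), rtol=1e-3
            )

    def test_rank_deficient_design_lists_columns(self):
        df = pd.DataFrame(
            np.random.default_rng(0).integers(1, 50, (10, 6)),
            columns=list("abcdef"),
        )
        design = pd.DataFrame(
            {"grp": [0.0, 0, 0, 1, 1, 1], "copy": [0.0, 0, 0, 1, 1, 1]},
            index=df.columns,
        )
        sf = pd.Series(1.0, index=df.columns)
        disp = pd.Series(0.1, index=df.index)
        with pytest.raises(ValidationError, match="copy"):
            txage.fit_nb_wald(df, design, "grp", sf, disp)


class TestCooks:
    def test_balanced_counts_not_flagged(self):
        rng = np.random.default_rng(9)
        df, design = two_group_counts(rng, 20, 50, 100.0, 0.05)
        sf = txage.size_factors(df)
        disp = txage.estimate_dispersions(df, sf)
        res = txage.fit_nb_wald(df, design, "grp", sf, disp, cooks_cutoff=0.2)
        assert res["outlier_flag"].mean() < 0.2

    def test_single_extreme_sample_flagged(self):
        rng = np.random.default_rng(10)
        df, design = two_group_counts(rng, 1, 20, 50.0, 0.05)
        df.iloc[0, 0] = 5000  # 100x the group mean
        sf = pd.Series(1.0, index=df.columns)
        disp = pd.Series(0.05, index=df.index)
        res = txage.fit_nb_wald(df, design, "grp", sf, disp, cooks_cutoff=0.2)
        assert res["outlier_flag"].iloc[0]
        assert not res["tested_flag"].iloc[0]

    def test_infinite_cutoff_flags_nothing(self):
        rng = np.random.default_rng(11)
        df, design = two_group_counts(rng, 20, 20, 50.0, 0.2)
        df.iloc[0, 0] = 5000
        sf = txage.size_factors(df)
        disp = txage.estimate_dispersions(df, sf)
        res = txage.fit_nb_wald(df, design, "grp", sf, disp, cooks_cutoff=np.inf)
        assert not res["outlier_flag"].any()


class TestRunDE:
    def test_quartile_contrast_on_age_runs(self, null_filtered):
        counts, metadata = null_filtered
        res = txage.run_de(
            counts, metadata, txage.ContrastSpec("age", mode="quartile")
        )
        assert res["tested_flag"].sum() > 1500
        assert len(txage.significant_genes(res, 0.01)) <= 2

    def test_missing_covariate_drops_samples_locally(self, null_filtered):
        counts, metadata = null_filtered
        md = txage.SampleMetadata(metadata.table.copy(), dict(metadata.covariate_kinds))
        md.table.loc[md.table.index[:5], "sex"] = np.nan
        res = txage.run_de(counts, md, txage.ContrastSpec("sex"))
        assert res["tested_flag"].sum() > 0  # runs on the remaining samples

    def test_contrast_covariate_cannot_be_adjusted_for(self):
        with pytest.raises(ValueError):
            txage.ContrastSpec("sex", adjustment_covariates=["sex"])


class TestEstimator:
    def test_sklearn_contract(self):
        from sklearn.base import clone

        est = NBWaldDE(alpha=0.05)
        assert clone(est).get_params()["alpha"] == 0.05
        est.set_params(cooks_cutoff=0.5)
        assert est.get_params()["cooks_cutoff"] == 0.5

    def test_fit_produces_results_table(self):
        rng = np.random.default_rng(12)
        df, design = two_group_counts(rng, 30, 30, 80.0, 0.1, log2fc=2.0,
                                      n_affected=5)
        est = NBWaldDE(cooks_cutoff=None).fit(df.T, design["grp"].to_numpy())
        assert est.results_.shape[0] == 30
        assert est.results_["tested_flag"].any()
        assert len(est.significant_()) > 0
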