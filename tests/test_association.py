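"""Association machinery: ANOVA, contrasts, Cook's-distance regression,
interactions, rank correlation and the per-SNP scan, each checked
against independent oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from brainage import (
    SimulationParams,
    category_anova,
    dosage_association,
    generate_genotypes,
    gwas_scan,
    interaction_model,
    pairwise_contrasts,
    spearman_correlation,
    two_step_regression,
)
from brainage.association import adjusted_category_means, cooks_distance
from brainage.containers import GenotypeMatrix


class TestCategoryAnova:
    def test_two_groups_equals_squared_t(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=60)
        g = np.repeat(["a", "b"], 30)
        res = category_anova(y, g)
        t, p = stats.ttest_ind(y[:30], y[30:])
        assert res.f_stat == pytest.approx(t**2, rel=1e-10)
        assert res.f_p == pytest.approx(p, rel=1e-10)

    def test_matches_statsmodels_extra_ss_oracle(self):
        rng = np.random.default_rng(1)
        n = 120
        g = rng.choice(list("abcd"), n)
        cov = pd.DataFrame({"sex": rng.choice(["m", "f"], n),
                            "edu": rng.integers(0, 2, n)})
        y = rng.normal(size=n) + (g == "d") * 0.5
        res = category_anova(y, g, cov)
        df = pd.DataFrame({"y": y, "g": g, "sex": cov["sex"], "edu": cov["edu"]})
        full = sm.OLS.from_formula("y ~ C(sex) + edu + C(g)", df).fit()
        reduced = sm.OLS.from_formula("y ~ C(sex) + edu", df).fit()
        q = 3
        f = ((reduced.ssr - full.ssr) / q) / (full.ssr / full.df_resid)
        assert res.f_stat == pytest.approx(f, rel=1e-10)
        assert res.f_p == pytest.approx(
            stats.f.sf(f, q, full.df_resid), rel=1e-10, abs=1e-300
        )

    def test_shifted_group_has_largest_adjusted_mean(self):
        """A +0.6-year RBA shift in the daily-smoking group shows up as
        that group's adjusted mean being the largest."""
        rng = np.random.default_rng(2)
        n = 2000
        levels = ["never", "tried once or twice", "occasionally", "most or all days"]
        g = rng.choice(levels, n, p=[0.5, 0.2, 0.1, 0.2])
        cov = pd.DataFrame({"sex": rng.choice(["m", "f"], n),
                            "edu": rng.integers(0, 2, n)})
        y = rng.normal(0, 2.4, n) + 0.6 * (g == "most or all days")
        means = adjusted_category_means(y, g, cov)
        assert means.idxmax() == "most or all days"
        res = category_anova(y, g, cov)
        assert res.f_p < 0.01

    def test_small_category_rejected(self):
        y = np.arange(10.0)
        g = ["a"] * 9 + ["b"]
        with pytest.raises(ValueError, match="b"):
            category_anova(y, g)

    def test_missing_rows_dropped_and_counted(self):
        y = np.array([1.0, 2.0, np.nan, 4.0, 2.0, 3.0, 1.0, 5.0])
        g = ["a", "a", "a", "a", "b", "b", "b", "b"]
        res = category_anova(y, g)
        assert res.n_used == 7
        assert res.n_missing == 1
        assert res.n_input == 8


class TestPairwiseContrasts:
    def test_identical_groups_large_p(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=300)
        g = np.repeat(list("abc"), 100)
        tab = pairwise_contrasts(y, g)
        assert (tab["p_bonferroni"] > 0.2).all()

    def test_contrast_transitivity(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=90) + np.repeat([0.0, 0.4, 1.0], 30)
        g = np.repeat(list("abc"), 30)
        cov = pd.DataFrame({"x": rng.normal(size=90)})
        tab = pairwise_contrasts(y, g, cov).set_index(["level_1", "level_2"])
        ab = tab.loc[("a", "b"), "estimate"]
        bc = tab.loc[("b", "c"), "estimate"]
        ac = tab.loc[("a", "c"), "estimate"]
        assert ab + bc == pytest.approx(ac, abs=1e-10)

    def test_shifted_group_dominates_smallest_p(self):
        rng = np.random.default_rng(5)
        n = 400
        g = np.repeat(list("abcd"), n // 4)
        y = rng.normal(size=n) + 2.0 * (g == "c")
        tab = pairwise_contrasts(y, g)
        best = tab.loc[tab["p"].idxmin()]
        assert "c" in (best["level_1"], best["level_2"])
        assert tab["p_bonferroni"].min() <= min(1.0, tab["p"].min() * len(tab))


class TestTwoStepRegression:
    @staticmethod
    def _data(n=200, seed=6):
        rng = np.random.default_rng(seed)
        py = rng.lognormal(2.7, 0.6, n)
        alc = rng.lognormal(2.2, 0.6, n)
        cov = pd.DataFrame({"sex": rng.choice(["m", "f"], n),
                            "edu": rng.integers(0, 2, n)})
        y = 0.03 * py + 0.02 * alc + rng.normal(0, 2.4, n)
        return y, py, alc, cov

    def test_cooks_distance_matches_loo_refit_oracle(self):
        """Cook's distance equals the leave-one-out definition
        D_i = sum_j (yhat_j - yhat_j(-i))^2 / (p * s^2)."""
        y, py, alc, cov = self._data(n=50)
        X = sm.add_constant(np.column_stack([py, alc]))
        fit = sm.OLS(y, X).fit()
        d = cooks_distance(fit)
        p = X.shape[1]
        s2 = fit.ssr / fit.df_resid
        for i in range(50):
            keep = np.ones(50, dtype=bool)
            keep[i] = False
            fit_i = sm.OLS(y[keep], X[keep]).fit()
            yhat_i = X @ fit_i.params
            d_loo = np.sum((fit.fittedvalues - yhat_i) ** 2) / (p * s2)
            assert d[i] == pytest.approx(d_loo, abs=1e-8)

    def test_stable_without_outliers(self):
        y, py, alc, cov = self._data(n=2000, seed=7)
        res = two_step_regression(y, py, alc, cov)
        s1 = res.extra["step1_terms"]
        assert res.n_excluded_influential < 0.15 * 2000
        assert res.terms.loc["pack_years", "beta"] == pytest.approx(
            s1.loc["pack_years", "beta"], abs=3 * s1.loc["pack_years", "se"]
        )

    def test_parameter_recovery_at_study_subset_size(self):
        """n = 2,327 daily smokers who drink: injected slopes inside the
        95% CIs of the step-2 estimates."""
        y, py, alc, cov = self._data(n=2327, seed=8)
        res = two_step_regression(y, py, alc, cov)
        for term, truth in (("pack_years", 0.03), ("alcohol_g_day", 0.02)):
            beta = res.terms.loc[term, "beta"]
            se = res.terms.loc[term, "se"]
            assert abs(beta - truth) < 1.96 * se
        assert res.n_used + res.n_excluded_influential == 2327

    def test_single_gross_outlier_excluded(self):
        y, py, alc, cov = self._data(n=100, seed=9)
        y[0] += 50.0
        py[0] = py.max() * 3
        res = two_step_regression(y, py, alc, cov)
        assert res.n_excluded_influential >= 1
        d = res.extra["cooks_distance"]
        assert d[0] > 3 * d.mean()


class TestInteraction:
    def test_centering_leaves_t_unchanged(self):
        rng = np.random.default_rng(10)
        n = 500
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = x1 + 0.5 * x2 + 0.3 * x1 * x2 + rng.normal(size=n)
        r1 = interaction_model(y, x1, x2)
        r2 = interaction_model(y, x1 - x1.mean(), x2 - x2.mean())
        t1 = r1.terms.loc[r1.extra["interaction_term"], "t"]
        t2 = r2.terms.loc[r2.extra["interaction_term"], "t"]
        assert t1 == pytest.approx(t2, rel=1e-8)

    def test_injected_interaction_detected(self):
        rng = np.random.default_rng(11)
        n = 1000
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = 0.3 * x1 * x2 + rng.normal(size=n)
        res = interaction_model(y, x1, x2)
        assert res.terms.loc[res.extra["interaction_term"], "p"] < 1e-6

    def test_perfect_collinearity_rejected(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=100)
        with pytest.raises(ValueError, match="collinear"):
            interaction_model(rng.normal(size=100), x, 2 * x)


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman_correlation(x, x**3)[0] == pytest.approx(1.0)
        assert spearman_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(13)
        x = rng.integers(0, 5, 200).astype(float)
        y = x + rng.integers(0, 3, 200)
        rho, _ = spearman_correlation(x, y)
        oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            spearman_correlation(np.ones(10), np.arange(10.0))


def _small_geno(dosages):
    d = np.asarray(dosages, dtype=float)
    snps = pd.DataFrame(
        {"chrom": "1", "pos": np.arange(d.shape[1]) + 1,
         "id": [f"v{j}" for j in range(d.shape[1])], "ref": "A", "alt": "G"}
    )
    return GenotypeMatrix(d, [f"S{i}" for i in range(d.shape[0])], snps)


class TestGwas:
    def test_additive_p_matches_statsmodels_oracle(self):
        rng = np.random.default_rng(14)
        n = 30
        d = rng.binomial(2, 0.4, size=(n, 5)).astype(float)
        cov = pd.DataFrame({"sex": rng.choice(["m", "f"], n),
                            "pc1": rng.normal(size=n)})
        y = rng.normal(size=n) + 0.5 * d[:, 2]
        tab = gwas_scan(y, _small_geno(d), cov).set_index("id")
        enc = pd.get_dummies(cov, drop_first=True, dtype=float)
        for j in range(5):
            X = sm.add_constant(np.column_stack([enc.to_numpy(), d[:, j]]))
            fit = sm.OLS(y, X).fit()
            assert tab.loc[f"v{j}", "beta_additive"] == pytest.approx(
                fit.params[-1], abs=1e-10
            )
            assert tab.loc[f"v{j}", "p_additive"] == pytest.approx(
                fit.pvalues[-1], abs=1e-10
            )

    def test_genotypic_2df_matches_f_oracle(self):
        rng = np.random.default_rng(15)
        n = 200
        d = rng.binomial(2, 0.4, size=(n, 3)).astype(float)
        y = rng.normal(size=n) + 0.4 * (d[:, 1] == 1)   # dominance signal
        tab = gwas_scan(y, _small_geno(d), mode="genotypic").set_index("id")
        for j in range(3):
            het = (d[:, j] == 1).astype(float)
            X0 = sm.add_constant(np.ones((n, 0)))
            X2 = sm.add_constant(np.column_stack([d[:, j], het]))
            f0 = sm.OLS(y, np.ones(n)).fit()
            f2 = sm.OLS(y, X2).fit()
            f = ((f0.ssr - f2.ssr) / 2) / (f2.ssr / f2.df_resid)
            assert tab.loc[f"v{j}", "p_genotypic_2df"] == pytest.approx(
                stats.f.sf(f, 2, f2.df_resid), abs=1e-10
            )

    def test_monomorphic_snp_noted(self):
        rng = np.random.default_rng(16)
        d = rng.binomial(2, 0.3, size=(50, 2)).astype(float)
        d[:, 1] = 1.0
        tab = gwas_scan(rng.normal(size=50), _small_geno(d)).set_index("id")
        assert tab.loc["v1", "note"] == "monomorphic"
        assert np.isnan(tab.loc["v1", "p_additive"])
        assert not tab.loc["v1", "genome_wide_significant"]

    def test_missing_genotypes_complete_case_per_snp(self):
        rng = np.random.default_rng(17)
        d = rng.binomial(2, 0.4, size=(60, 2)).astype(float)
        d[:10, 0] = np.nan
        tab = gwas_scan(rng.normal(size=60), _small_geno(d)).set_index("id")
        assert tab.loc["v0", "n"] == 50
        assert tab.loc["v1", "n"] == 60

    def test_significance_flag_matches_threshold(self):
        rng = np.random.default_rng(18)
        n = 800
        d = rng.binomial(2, 0.4, size=(n, 2)).astype(float)
        y = 1.0 * d[:, 0] + rng.normal(0, 1, n)   # huge effect
        tab = gwas_scan(y, _small_geno(d)).set_index("id")
        assert bool(tab.loc["v0", "genome_wide_significant"])
        assert tab.loc["v0", "p_additive"] < 5e-8
        assert tab["genome_wide_significant"].equals(tab["p_additive"] < 5e-8)


class TestDosageAssociation:
    def test_equals_gwas_additive_on_same_column(self):
        rng = np.random.default_rng(19)
        n = 150
        d = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
        cov = pd.DataFrame({"sex": rng.choice(["m", "f"], n)})
        y = 0.3 * d[:, 0] + rng.normal(size=n)
        res = dosage_association(y, d[:, 0], cov)
        tab = gwas_scan(y, _small_geno(d), cov)
        assert res.terms.loc["dosage", "p"] == pytest.approx(
            tab.loc[0, "p_additive"], abs=1e-12
        )
        assert res.terms.loc["dosage", "beta"] == pytest.approx(
            tab.loc[0, "beta_additive"], abs=1e-12
        )

    def test_constant_dosage_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            dosage_association(np.random.default_rng(20).normal(size=50),
                               np.ones(50), None)
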