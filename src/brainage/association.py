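"""Association analyses for relative brain age.

Covers the covariate-adjusted ANOVA of RBA across exposure-frequency
categories, pairwise category contrasts, the two-step continuous
exposure regression with Cook's-distance exclusion of influential
observations, exposure-interaction models, rank correlation with
cognitive scores, and the per-SNP genome-wide scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import OLSInfluence

GENOME_WIDE_THRESHOLD = 5e-8


@dataclass
class AssociationResult:
    """One fitted association model.

    ``terms`` holds per-term beta/SE/t/p; ``f_stat``/``f_p`` report an
    extra-sum-of-squares F test where one applies.  Sample accounting:
    ``n_input = n_used + n_missing + n_excluded_influential``.
    """

    terms: pd.DataFrame
    n_input: int
    n_used: int
    n_missing: int = 0
    n_excluded_influential: int = 0
    r_squared: float = float("nan")
    f_stat: float = float("nan")
    f_p: float = float("nan")
    f_df: tuple[int, int] | None = None
    extra: dict = field(default_factory=dict)


def _encode_covariates(covariates: pd.DataFrame | None, n: int):
    """Covariate design columns: numeric as-is, categoricals dummy-coded."""
    if covariates is None or (hasattr(covariates, "empty") and covariates.empty):
        return pd.DataFrame(index=pd.RangeIndex(n))
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    parts = []
    for col in cov.columns:
        s = cov[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            parts.append(pd.get_dummies(s, prefix=col, drop_first=True, dtype=float))
        else:
            parts.append(s.astype(float).to_frame(col))
    return pd.concat(parts, axis=1)


def _complete_cases(*frames):
    """Row mask where every input is non-missing."""
    mask = np.ones(len(frames[0]), dtype=bool)
    for f in frames:
        if f is None or (hasattr(f, "empty") and getattr(f, "empty", False)):
            continue
        arr = pd.DataFrame(f).reset_index(drop=True)
        mask &= ~arr.isna().any(axis=1).to_numpy()
    return mask


def _fit_ols(y: np.ndarray, X: pd.DataFrame):
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError("design matrix is rank deficient (perfect collinearity)")
    return sm.OLS(y, Xc).fit()


def _terms_table(fit) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "beta": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )


def category_anova(rba, category, covariates: pd.DataFrame | None = None) -> AssociationResult:
    """Covariate-adjusted ANOVA of RBA across exposure categories.

    Compares the model with covariates plus the category factor to the
    covariate-only model with an extra-sum-of-squares F test, keeping
    the covariates in both (the factor is tested after adjustment).
    """
    rba = np.asarray(rba, dtype=float)
    cat = pd.Series(category).reset_index(drop=True)
    n_input = len(rba)
    mask = _complete_cases(pd.Series(rba), cat, covariates)
    y = rba[mask]
    cat = cat[mask].reset_index(drop=True)
    cov = _encode_covariates(covariates, n_input).loc[mask].reset_index(drop=True)

    counts = cat.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 categories")
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"category with < 2 subjects: {list(small.index)}")

    dummies = pd.get_dummies(cat, prefix="cat", drop_first=True, dtype=float)
    full = _fit_ols(y, pd.concat([cov, dummies], axis=1))
    reduced = _fit_ols(y, cov)

    q = dummies.shape[1]
    df_den = int(full.df_resid)
    f = ((reduced.ssr - full.ssr) / q) / (full.ssr / df_den)
    f_p = float(stats.f.sf(f, q, df_den))
    return AssociationResult(
        terms=_terms_table(full),
        n_input=n_input,
        n_used=int(mask.sum()),
        n_missing=int(n_input - mask.sum()),
        r_squared=float(full.rsquared),
        f_stat=float(f),
        f_p=f_p,
        f_df=(q, df_den),
    )


def adjusted_category_means(rba, category, covariates: pd.DataFrame | None = None) -> pd.Series:
    """Covariate-adjusted mean RBA per category (at average covariates)."""
    rba = np.asarray(rba, dtype=float)
    cat = pd.Series(category).reset_index(drop=True)
    mask = _complete_cases(pd.Series(rba), cat, covariates)
    y = rba[mask]
    cat = cat[mask].reset_index(drop=True)
    cov = _encode_covariates(covariates, len(rba)).loc[mask].reset_index(drop=True)
    dummies = pd.get_dummies(cat, prefix="cat", dtype=float)  # cell-means coding
    X = pd.concat([dummies, cov - cov.mean()], axis=1) if cov.shape[1] else dummies
    fit = sm.OLS(y, X.astype(float)).fit()
    levels = [c[len("cat_"):] for c in dummies.columns]
    return pd.Series(fit.params[: len(levels)].to_numpy(), index=levels)


def pairwise_contrasts(rba, category, covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """All pairwise differences of adjusted category means.

    t-tests on contrasts of the covariate-adjusted model; raw and
    Bonferroni-adjusted p-values are reported side by side.
    """
    rba = np.asarray(rba, dtype=float)
    cat = pd.Series(category).reset_index(drop=True)
    mask = _complete_cases(pd.Series(rba), cat, covariates)
    y = rba[mask]
    cat = cat[mask].reset_index(drop=True)
    cov = _encode_covariates(covariates, len(rba)).loc[mask].reset_index(drop=True)

    counts = cat.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"category with < 2 subjects: {list(small.index)}")

    dummies = pd.get_dummies(cat, prefix="cat", dtype=float)
    levels = [c[len("cat_"):] for c in dummies.columns]
    X = pd.concat([dummies, cov - cov.mean()], axis=1) if cov.shape[1] else dummies
    Xm = X.astype(float)
    fit = sm.OLS(y, Xm).fit()
    V = fit.cov_params().to_numpy()
    beta = fit.params.to_numpy()
    df = int(fit.df_resid)

    rows = []
    n_levels = len(levels)
    n_pairs = n_levels * (n_levels - 1) // 2
    for i in range(n_levels):
        for j in range(i + 1, n_levels):
            c = np.zeros(len(beta))
            c[i], c[j] = 1.0, -1.0
            est = float(c @ beta)
            se = float(np.sqrt(c @ V @ c))
            t = est / se
            p = float(2 * stats.t.sf(abs(t), df))
            rows.append(
                {
                    "level_1": levels[i],
                    "level_2": levels[j],
                    "estimate": est,
                    "se": se,
                    "t": t,
                    "p": p,
                    "p_bonferroni": min(1.0, p * n_pairs),
                }
            )
    return pd.DataFrame(rows)


def cooks_distance(fit) -> np.ndarray:
    """Cook's distance for each observation of a fitted OLS model."""
    return OLSInfluence(fit).cooks_distance[0]


def two_step_regression(
    rba,
    pack_years,
    alcohol_g_day,
    covariates: pd.DataFrame | None = None,
    cook_multiplier: float = 3.0,
) -> AssociationResult:
    """Two-step exposure regression with influential-observation exclusion.

    Step 1 regresses RBA on smoking amount, alcohol amount and
    covariates; observations with Cook's distance greater than
    ``cook_multiplier`` times the mean Cook's distance are excluded
    exactly once; step 2 refits on the remainder and its estimates are
    reported.
    """
    rba = np.asarray(rba, dtype=float)
    py = pd.Series(np.asarray(pack_years, dtype=float), name="pack_years")
    alc = pd.Series(np.asarray(alcohol_g_day, dtype=float), name="alcohol_g_day")
    n_input = len(rba)
    mask = _complete_cases(pd.Series(rba), py, alc, covariates)
    cov = _encode_covariates(covariates, n_input).loc[mask].reset_index(drop=True)
    X = pd.concat(
        [py[mask].reset_index(drop=True), alc[mask].reset_index(drop=True), cov],
        axis=1,
    )
    y = rba[mask]
    if len(y) < X.shape[1] + 3:
        raise ValueError("too few subjects for the exposure regression")

    fit1 = _fit_ols(y, X)
    d = cooks_distance(fit1)
    keep = d <= cook_multiplier * d.mean()
    if keep.sum() < X.shape[1] + 2:
        raise ValueError("influence exclusion left too few subjects to refit")
    fit2 = _fit_ols(y[keep], X.loc[keep].reset_index(drop=True))

    return AssociationResult(
        terms=_terms_table(fit2),
        n_input=n_input,
        n_used=int(keep.sum()),
        n_missing=int(n_input - mask.sum()),
        n_excluded_influential=int((~keep).sum()),
        r_squared=float(fit2.rsquared),
        extra={"step1_terms": _terms_table(fit1),
               "cooks_distance": d},
    )


def interaction_model(
    rba, x1, x2, covariates: pd.DataFrame | None = None
) -> AssociationResult:
    """Linear model with an x1 x x2 interaction term.

    Reports each main effect and the interaction's t and p (the usual
    test of whether one exposure's slope depends on the other).
    """
    rba = np.asarray(rba, dtype=float)
    s1 = pd.Series(np.asarray(x1, dtype=float), name=getattr(x1, "name", None) or "x1")
    s2 = pd.Series(np.asarray(x2, dtype=float), name=getattr(x2, "name", None) or "x2")
    inter = pd.Series(s1.to_numpy() * s2.to_numpy(), name=f"{s1.name}:{s2.name}")
    n_input = len(rba)
    mask = _complete_cases(pd.Series(rba), s1, s2, covariates)
    cov = _encode_covariates(covariates, n_input).loc[mask].reset_index(drop=True)
    X = pd.concat(
        [s.loc[mask].reset_index(drop=True) for s in (s1, s2, inter)] + [cov],
        axis=1,
    )
    fit = _fit_ols(rba[mask], X)
    res = AssociationResult(
        terms=_terms_table(fit),
        n_input=n_input,
        n_used=int(mask.sum()),
        n_missing=int(n_input - mask.sum()),
        r_squared=float(fit.rsquared),
    )
    res.extra["interaction_term"] = inter.name
    return res


def spearman_correlation(rba, score) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and its p-value."""
    rba = np.asarray(rba, dtype=float)
    score = np.asarray(score, dtype=float)
    mask = ~(np.isnan(rba) | np.isnan(score))
    rba, score = rba[mask], score[mask]
    if len(rba) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(rba) == 0 or np.ptp(score) == 0:
        raise ValueError("constant input")
    rho, p = stats.spearmanr(rba, score)
    return float(rho), float(p)


def _snp_regression(y, Z, dosage):
    """Closed-form additive test of one SNP given covariate design Z."""
    X = np.column_stack([Z, dosage])
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        return None
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - p
    sigma2 = rss / df
    XtX_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * XtX_inv[-1, -1]))
    t = beta[-1] / se
    pval = float(2 * stats.t.sf(abs(t), df))
    return float(beta[-1]), se, float(t), pval, rss, df


def gwas_scan(
    rba,
    geno,
    covariates: pd.DataFrame | None = None,
    mode: str = "additive",
    sig_threshold: float = GENOME_WIDE_THRESHOLD,
) -> pd.DataFrame:
    """Per-SNP linear association scan of RBA.

    ``mode='additive'`` fits a 1-df dosage slope; ``mode='genotypic'``
    additionally tests dosage plus a heterozygote indicator jointly
    against the covariate-only model (2-df F).  Complete cases per SNP;
    monomorphic SNPs are reported with a note and no statistics.
    Rows are flagged genome-wide significant when the smallest reported
    p-value falls below ``sig_threshold``.
    """
    if mode not in ("additive", "genotypic"):
        raise ValueError("mode must be 'additive' or 'genotypic'")
    y_all = np.asarray(rba, dtype=float)
    if len(y_all) != geno.n_samples:
        raise ValueError("rba length must match number of genotype samples")
    cov = _encode_covariates(covariates, len(y_all))
    base_mask = _complete_cases(pd.Series(y_all), cov)
    Z_all = sm.add_constant(cov.astype(float), has_constant="add").to_numpy()
    if np.linalg.matrix_rank(Z_all[base_mask]) < Z_all.shape[1]:
        raise ValueError("covariate design is rank deficient (collinearity)")

    maf = geno.maf()
    rows = []
    for j in range(geno.n_snps):
        dos = geno.dosages[:, j]
        mask = base_mask & ~np.isnan(dos)
        y, Z, d = y_all[mask], Z_all[mask], dos[mask]
        row = dict(geno.snps.iloc[j])
        row.update(
            maf=maf[j], n=int(mask.sum()), beta_additive=np.nan, se=np.nan,
            p_additive=np.nan, p_genotypic_2df=np.nan,
            genome_wide_significant=False, note="",
        )
        if len(y) < Z.shape[1] + 3 or np.ptp(d) == 0:
            row["note"] = "monomorphic" if len(y) and np.ptp(d) == 0 else "too_few"
            rows.append(row)
            continue
        add = _snp_regression(y, Z, d)
        if add is None:
            row["note"] = "collinear"
            rows.append(row)
            continue
        beta, se, t, p_add, _, _ = add
        row.update(beta_additive=beta, se=se, p_additive=p_add)
        if mode == "genotypic":
            het = (d == 1).astype(float)
            X2 = np.column_stack([Z, d, het])
            if np.linalg.matrix_rank(X2) == X2.shape[1]:
                b0, _, _, _ = np.linalg.lstsq(Z, y, rcond=None)
                rss0 = float(np.sum((y - Z @ b0) ** 2))
                b2, _, _, _ = np.linalg.lstsq(X2, y, rcond=None)
                rss2 = float(np.sum((y - X2 @ b2) ** 2))
                df2 = len(y) - X2.shape[1]
                f = ((rss0 - rss2) / 2.0) / (rss2 / df2)
                row["p_genotypic_2df"] = float(stats.f.sf(f, 2, df2))
        pmin = np.nanmin([row["p_additive"], row["p_genotypic_2df"]])
        row["genome_wide_significant"] = bool(pmin < sig_threshold)
        rows.append(row)
    table = pd.DataFrame(rows)

    def _key(s):
        if s.name == "chrom":
            num = pd.to_numeric(s, errors="coerce")   # X/Y sort after numerics
            return num.fillna(num.max() + 1 if num.notna().any() else 0)
        return s.astype(int)

    return table.sort_values(["chrom", "pos"], key=_key).reset_index(drop=True)


def dosage_association(
    rba, dosage, covariates: pd.DataFrame | None = None
) -> AssociationResult:
    """Additive association of RBA with a single 0/1/2 dosage column
    (e.g. APOE e4 risk-allele count), via the same machinery as the
    per-SNP scan."""
    y_all = np.asarray(rba, dtype=float)
    dos = np.asarray(dosage, dtype=float)
    if len(dos) != len(y_all):
        raise ValueError("dosage length must match rba")
    n_input = len(y_all)
    cov = _encode_covariates(covariates, n_input)
    mask = _complete_cases(pd.Series(y_all), pd.Series(dos), cov)
    y = y_all[mask]
    d = dos[mask]
    if np.ptp(d) == 0:
        raise ValueError("dosage is constant (monomorphic)")
    Z = sm.add_constant(cov.loc[mask].astype(float), has_constant="add").to_numpy()
    out = _snp_regression(y, Z, d)
    if out is None:
        raise ValueError("design matrix is rank deficient (collinearity)")
    beta, se, t, p, rss, df = out
    terms = pd.DataFrame(
        {"beta": [beta], "se": [se], "t": [t], "p": [p]}, index=["dosage"]
    )
    tss = float(np.sum((y - y.mean()) ** 2))
    return AssociationResult(
        terms=terms,
        n_input=n_input,
        n_used=int(mask.sum()),
        n_missing=int(n_input - mask.sum()),
        r_squared=1.0 - rss / tss if tss > 0 else float("nan"),
    )
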