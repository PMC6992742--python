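"""Test RBA against smoking, alcohol, their interaction and cognition.

Reproduces the analysis layout on synthetic data: covariate-adjusted
ANOVA across exposure-frequency categories, pairwise contrasts, the
two-step continuous regression with Cook's-distance exclusion among
daily smokers who drink, and the rank correlation with fluid
intelligence.
"""

from brainage import (
    SimulationParams, category_anova, compute_rba, fit_brain_age_model,
    fit_epba, generate_cohort, interaction_model, pairwise_contrasts,
    predict_brain_age, spearman_correlation, split_cohort, two_step_regression,
)

params = SimulationParams(n_subjects=10_000, n_features=60,
                          n_informative_features=40, seed=1)
cohort, features = generate_cohort(params)
train, ev = split_cohort(cohort["subject_id"], 0.30, seed=1)
c = cohort.set_index("subject_id")
model = fit_brain_age_model(features.loc[train], c.loc[train, "ca"], seed=1)
epba = fit_epba(predict_brain_age(model, features.loc[train]), c.loc[train, "ca"])
evd = c.loc[ev]
rba = compute_rba(predict_brain_age(model, features.loc[ev]), evd["ca"], epba)
covars = evd[["sex", "education_degree"]]

res = category_anova(rba, evd["smoking_freq"], covars)
print(f"smoking-frequency ANOVA: F={res.f_stat:.1f}, p={res.f_p:.2e}, n={res.n_used}")
tab = pairwise_contrasts(rba, evd["smoking_freq"], covars)
best = tab.loc[tab["p"].idxmin()]
print(f"strongest contrast: {best['level_1']} vs {best['level_2']}: "
      f"{best['estimate']:+.2f} y (Bonferroni p={best['p_bonferroni']:.2e})")

daily = (evd["smoking_freq"] == "most or all days") & (evd["alcohol_freq"] != "never")
sub = evd[daily]
res2 = two_step_regression(rba[daily.to_numpy()], sub["pack_years"],
                           sub["alcohol_g_day"], sub[["sex", "education_degree"]])
py = res2.terms.loc["pack_years"]
al = res2.terms.loc["alcohol_g_day"]
print(f"\ndaily smokers who drink (n={res2.n_used}, "
      f"{res2.n_excluded_influential} influential excluded):")
print(f"  {py['beta']:+.4f} y RBA per pack-year        (p={py['p']:.2e})")
print(f"  {al['beta']:+.4f} y RBA per gram alcohol/day (p={al['p']:.2e})")
print(f"  model R-squared {res2.r_squared:.3f}")

inter = interaction_model(rba[daily.to_numpy()], sub["pack_years"],
                          sub["alcohol_g_day"], sub[["sex", "education_degree"]])
ip = inter.terms.loc[inter.extra["interaction_term"], "p"]
print(f"  smoking x alcohol interaction p={ip:.2f} (no interaction injected)")

rho, p = spearman_correlation(rba, evd["fluid_intelligence"])
print(f"\nfluid intelligence vs RBA: Spearman rho={rho:+.3f} (p={p:.1e})")
# Higher RBA (older-looking brain) goes with heavier exposure and
# slightly lower cognitive scores, matching the injected structure.
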