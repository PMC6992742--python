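"""End-to-end orchestration: simulate -> QC -> brain age -> associations.

A :class:`RunConfig` fully determines a run; for a fixed seed the result
tables are byte-identical across runs.  Each stage logs its subject/SNP
accounting (in/out counts) the way cohort-selection flowcharts do.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .association import (
    category_anova,
    dosage_association,
    gwas_scan,
    interaction_model,
    pairwise_contrasts,
    spearman_correlation,
    two_step_regression,
)
from .brain_age import (
    brain_age_table,
    compute_rba,
    fit_brain_age_model,
    fit_epba,
    mae,
    predict_brain_age,
    split_cohort,
)
from .io import ResultBundle, write_morphometrics, write_phenotypes, write_vcf
from .qc import filter_samples, filter_snps, genotype_pca, kinship, related_pairs, remove_related
from .simulate import SimulationParams, generate_dataset

log = logging.getLogger(__name__)


def exclusion_accounting(n_initial: int, exclusions: dict[str, int]) -> dict:
    """Sequential cohort-exclusion arithmetic.

    Each exclusion count is expressed as a percentage of the initial
    cohort (one decimal place, the usual flowchart convention); the
    remainder after all exclusions is returned alongside.
    """
    if n_initial < 0 or any(v < 0 for v in exclusions.values()):
        raise ValueError("counts must be non-negative")
    total = sum(exclusions.values())
    if total > n_initial:
        raise ValueError("exclusions exceed the initial cohort")
    out = {"n_initial": int(n_initial)}
    for name, count in exclusions.items():
        out[f"excluded_{name}"] = int(count)
        out[f"excluded_{name}_pct"] = round(100.0 * count / n_initial, 1)
    out["n_final"] = int(n_initial - total)
    return out


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serialized into the run metadata."""

    simulation: SimulationParams = field(default_factory=SimulationParams)
    training_fraction: float = 0.30
    cv_folds: int = 10
    miss_thresh: float = 0.02
    hwe_thresh: float = 1e-6
    call_thresh: float = 0.98
    het_sd: float = 3.0
    kinship_threshold: float = 0.1
    n_pcs: int = 5
    gwas_threshold: float = 5e-8
    gwas_mode: str = "genotypic"
    seed: int = 0
    output_dir: str = "brainage_run"

    def validate(self) -> None:
        self.simulation.validate()
        if not 0 < self.training_fraction < 1:
            raise ValueError("training_fraction must be in (0, 1)")
        for name in ("miss_thresh", "hwe_thresh", "call_thresh"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        sim = d["simulation"]
        for k, v in sim.items():
            if isinstance(v, tuple):
                sim[k] = list(v)
            elif isinstance(v, np.ndarray):
                sim[k] = v.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        for k in ("maf_range", "smoking_freq_probs", "alcohol_freq_probs"):
            if k in sim and isinstance(sim[k], list):
                sim[k] = tuple(sim[k])
        return cls(simulation=SimulationParams(**sim), **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig, write: bool = True) -> ResultBundle:
    """Run the full analysis on a synthetic cohort.

    Stages: generate cohort/morphometrics/genotypes; genotype and sample
    QC with relatedness pruning and ancestry PCs; train/evaluation
    split, lasso brain-age fit, EPBA correction and RBA; exposure,
    cognition and APOE associations; per-SNP scan.  Returns (and, if
    ``write``, writes) a :class:`ResultBundle`.
    """
    from . import __version__

    config.validate()
    out = Path(config.output_dir)
    t0 = time.time()

    # --- stage: simulate -------------------------------------------------
    cohort, features, geno = generate_dataset(config.simulation)
    log.info("simulate: %d subjects, %d features, %d SNPs",
             len(cohort), features.shape[1], geno.n_snps)

    # --- stage: genotype QC ----------------------------------------------
    geno_s, snp_report = filter_snps(geno, config.miss_thresh, config.hwe_thresh)
    geno_q, sample_report = filter_samples(geno_s, config.call_thresh, config.het_sd)
    kin = kinship(geno_q)
    kin_pairs = related_pairs(kin, config.kinship_threshold)
    missingness = pd.Series(1.0 - geno_q.sample_call_rate(), index=geno_q.samples)
    kept_ids = remove_related(kin, config.kinship_threshold, missingness)
    geno_q = geno_q.select_samples(kept_ids)
    pcs = genotype_pca(geno_q, k=config.n_pcs)
    log.info("qc: SNPs %d -> %d; samples %d -> %d (%d related removed)",
             geno.n_snps, geno_q.n_snps, geno.n_samples,
             geno_q.n_samples, len(geno.samples) - len(kept_ids))

    # --- stage: brain age ------------------------------------------------
    train_ids, eval_ids = split_cohort(
        cohort["subject_id"], config.training_fraction, config.seed
    )
    coh = cohort.set_index("subject_id")
    model = fit_brain_age_model(
        features.loc[train_ids], coh.loc[train_ids, "ca"],
        cv_folds=config.cv_folds, seed=config.seed,
    )
    epba = fit_epba(
        predict_brain_age(model, features.loc[train_ids]), coh.loc[train_ids, "ca"]
    )
    tables: dict[str, pd.DataFrame] = {}
    results = {}
    for name, ids in (("train", train_ids), ("evaluation", eval_ids)):
        pba = predict_brain_age(model, features.loc[ids])
        tables[f"brain_age_{name}"] = brain_age_table(ids, coh.loc[ids, "ca"], pba, epba)
        results[f"mae_{name}"] = mae(pba, coh.loc[ids, "ca"])
    eval_tab = tables["brain_age_evaluation"].set_index("subject_id")
    rba = eval_tab["rba"]
    results["corr_rba_ca_evaluation"] = float(np.corrcoef(rba, eval_tab["ca"])[0, 1])
    results["corr_pba_minus_ca_ca_evaluation"] = float(
        np.corrcoef(eval_tab["pba"] - eval_tab["ca"], eval_tab["ca"])[0, 1]
    )
    log.info("brain age: train n=%d MAE=%.2f; evaluation n=%d MAE=%.2f",
             len(train_ids), results["mae_train"],
             len(eval_ids), results["mae_evaluation"])

    # --- stage: exposure/cognition associations --------------------------
    ev = coh.loc[eval_ids]
    covars = ev[["sex", "education_degree"]]
    assoc_rows = []

    for exposure in ("smoking_freq", "alcohol_freq"):
        res = category_anova(rba, ev[exposure], covars)
        assoc_rows.append(
            {"analysis": f"{exposure}_anova", "stat": res.f_stat, "p": res.f_p,
             "n_used": res.n_used, "detail": f"F df={res.f_df}"}
        )
        tables[f"contrasts_{exposure}"] = pairwise_contrasts(rba, ev[exposure], covars)

    daily = (ev["smoking_freq"] == "most or all days") & (ev["alcohol_freq"] != "never")
    sub = ev[daily]
    if daily.sum() >= 30:
        res2 = two_step_regression(
            rba[daily], sub["pack_years"], sub["alcohol_g_day"],
            sub[["sex", "education_degree"]],
        )
        for term in ("pack_years", "alcohol_g_day"):
            assoc_rows.append(
                {"analysis": f"two_step_{term}",
                 "stat": res2.terms.loc[term, "beta"],
                 "p": res2.terms.loc[term, "p"],
                 "n_used": res2.n_used,
                 "detail": f"excluded_influential={res2.n_excluded_influential}"}
            )
        results["two_step_n_excluded"] = res2.n_excluded_influential
        results["two_step_r_squared"] = res2.r_squared
        inter = interaction_model(
            rba[daily], sub["pack_years"], sub["alcohol_g_day"],
            sub[["sex", "education_degree"]],
        )
        iname = inter.extra["interaction_term"]
        assoc_rows.append(
            {"analysis": "smoke_alcohol_interaction",
             "stat": inter.terms.loc[iname, "t"],
             "p": inter.terms.loc[iname, "p"],
             "n_used": inter.n_used, "detail": iname}
        )

    rho, p_rho = spearman_correlation(rba, ev["fluid_intelligence"])
    assoc_rows.append(
        {"analysis": "fluid_intelligence_spearman", "stat": rho, "p": p_rho,
         "n_used": len(rba), "detail": "rho"}
    )
    if ev["apoe_e4_dosage"].nunique() > 1:
        apoe = dosage_association(rba, ev["apoe_e4_dosage"], covars)
        assoc_rows.append(
            {"analysis": "apoe_e4_dosage", "stat": apoe.terms.loc["dosage", "beta"],
             "p": apoe.terms.loc["dosage", "p"], "n_used": apoe.n_used,
             "detail": "additive dosage"}
        )
    tables["associations"] = pd.DataFrame(assoc_rows)

    # --- stage: GWAS ------------------------------------------------------
    gwas_ids = [s for s in eval_ids if s in set(geno_q.samples)]
    geno_eval = geno_q.select_samples(gwas_ids)
    gcov = pd.concat(
        [coh.loc[gwas_ids, ["sex", "education_degree"]].reset_index(drop=True),
         pcs.loc[gwas_ids].reset_index(drop=True)],
        axis=1,
    )
    gwas = gwas_scan(
        rba.loc[gwas_ids].to_numpy(), geno_eval, gcov,
        mode=config.gwas_mode, sig_threshold=config.gwas_threshold,
    )
    tables["gwas"] = gwas
    results["gwas_n_snps"] = int(len(gwas))
    results["gwas_n_significant"] = int(gwas["genome_wide_significant"].sum())
    log.info("gwas: %d SNPs tested, %d genome-wide significant",
             results["gwas_n_snps"], results["gwas_n_significant"])

    tables["qc_snps"] = snp_report.snps
    tables["qc_samples"] = sample_report.samples
    tables["kinship_pairs"] = kin_pairs

    bundle = ResultBundle(
        tables=tables,
        metadata={
            "version": __version__,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "summary": results,
            "runtime_s": round(time.time() - t0, 2),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
    )
    if write:
        out.mkdir(parents=True, exist_ok=True)
        write_phenotypes(cohort, out / "phenotypes.tsv")
        write_morphometrics(features, out / "morphometrics.tsv")
        write_vcf(geno, out / "genotypes.vcf")
        bundle.write(out)
    return bundle
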