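"""Synthetic cohort, morphometric and genotype generator.

The generator emulates the statistical structure the downstream analysis
assumes: chronological age (CA) uniform over the study's age range; a
latent brain-aging offset ``true_delta`` driven by smoking amount,
alcohol amount and an optional causal SNP; morphometric features that
respond linearly to *effective age* (CA + true_delta), so exposure
effects reach the age predictor only through anatomy; and HWE genotypes
with optional population structure, relatedness and missingness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

SMOKING_LEVELS = ("never", "tried once or twice", "occasionally", "most or all days")
ALCOHOL_LEVELS = (
    "never",
    "special occasions",
    "1-3/month",
    "1-2/week",
    "3-4/week",
    "daily or almost daily",
)

# pack-years among daily smokers: log-normal with mean ~20, sd ~15 years
_PY_DAILY_SIGMA = math.sqrt(math.log(1.0 + (15.0 / 20.0) ** 2))
_PY_DAILY_MU = math.log(20.0) - _PY_DAILY_SIGMA**2 / 2.0
# occasional smokers accumulate little exposure
_PY_OCC_MU, _PY_OCC_SIGMA = math.log(2.0), 0.5
# grams/day by drinking frequency category (log-normal medians), sigma shared
_ALC_MEANS = {
    "special occasions": 2.0,
    "1-3/month": 6.0,
    "1-2/week": 10.0,
    "3-4/week": 16.0,
    "daily or almost daily": 24.0,
}
_ALC_SIGMA = 0.6


class ParameterError(ValueError):
    """A simulation parameter violates its constraints."""


@dataclass
class SimulationParams:
    """Conditions for one synthetic study.

    Defaults mirror the cohort the analysis was designed for: ages
    45.2-80.7 y, 403 morphometric features of which 50 carry an age
    signal, exposure effects of 0.03 y RBA per pack-year and 0.02 y per
    gram of alcohol per day, and a 0.08 correlation between the two
    amounts among daily smokers who drink.
    """

    n_subjects: int = 1000
    age_min: float = 45.2
    age_max: float = 80.7
    n_features: int = 403
    n_informative_features: int | None = None   # default: min(50, n_features)
    feature_age_slopes: np.ndarray | None = None   # units per effective-age year
    feature_noise_sd: float | np.ndarray = 8.0
    n_snps: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_snp_index: int | None = None
    beta_smoke: float = 0.03        # years RBA per pack-year
    beta_alcohol: float = 0.02      # years RBA per gram/day
    beta_snp: float = 0.0           # years RBA per ALT allele
    beta_apoe: float = 0.0          # years RBA per e4 allele
    delta_sd: float = 2.5           # residual sd of the latent offset, years
    smoke_alcohol_corr: float = 0.08
    missing_rate: float = 0.0
    n_related_pairs: int = 0
    n_subpopulations: int = 1
    fst_like_divergence: float = 0.0
    apoe_e4_freq: float = 0.15
    smoking_freq_probs: tuple[float, ...] = (0.55, 0.15, 0.10, 0.20)
    alcohol_freq_probs: tuple[float, ...] = (0.06, 0.11, 0.11, 0.26, 0.23, 0.23)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative_features is None:
            self.n_informative_features = min(50, self.n_features)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        if not self.age_min < self.age_max:
            raise ParameterError("age_min must be < age_max")
        if self.n_features < 1:
            raise ParameterError("n_features must be >= 1")
        if not 0 <= self.n_informative_features <= self.n_features:
            raise ParameterError("n_informative_features must be in [0, n_features]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ParameterError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.causal_snp_index is not None and not (
            0 <= self.causal_snp_index < self.n_snps
        ):
            raise ParameterError("causal_snp_index out of range")
        for name in ("delta_sd", "missing_rate", "apoe_e4_freq",
                     "fst_like_divergence"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.missing_rate >= 1:
            raise ParameterError("missing_rate must be < 1")
        noise = np.atleast_1d(np.asarray(self.feature_noise_sd, dtype=float))
        if (noise < 0).any():
            raise ParameterError("feature_noise_sd must be non-negative")
        if self.n_subpopulations not in (1, 2):
            raise ParameterError("n_subpopulations must be 1 or 2")
        if 2 * self.n_related_pairs > self.n_subjects:
            raise ParameterError("n_related_pairs*2 must be <= n_subjects")
        if not -1 < self.smoke_alcohol_corr < 1:
            raise ParameterError("smoke_alcohol_corr must be in (-1, 1)")
        if abs(sum(self.smoking_freq_probs) - 1) > 1e-9:
            raise ParameterError("smoking_freq_probs must sum to 1")
        if abs(sum(self.alcohol_freq_probs) - 1) > 1e-9:
            raise ParameterError("alcohol_freq_probs must sum to 1")


def _lognormal_latent_corr(target: float, s1: float, s2: float) -> float:
    """Latent normal correlation giving Pearson ``target`` between two
    log-normals with log-scale sds ``s1``, ``s2`` (exact inversion)."""
    spread = math.sqrt(math.expm1(s1**2) * math.expm1(s2**2))
    return math.log1p(target * spread) / (s1 * s2)


def _feature_params(params: SimulationParams, rng: np.random.Generator):
    """Slopes, intercepts and noise sds for the morphometric model."""
    k = params.n_informative_features
    slopes = np.zeros(params.n_features)
    if params.feature_age_slopes is not None:
        given = np.asarray(params.feature_age_slopes, dtype=float)
        if given.shape != (params.n_features,):
            raise ParameterError(
                f"feature_age_slopes must have length {params.n_features}"
            )
        slopes = given
    elif k > 0:
        mags = rng.uniform(0.6, 1.4, size=k)
        signs = rng.choice([-1.0, 1.0], size=k)
        slopes[:k] = mags * signs
    intercepts = rng.uniform(10.0, 100.0, size=params.n_features)
    noise = np.broadcast_to(
        np.asarray(params.feature_noise_sd, dtype=float), (params.n_features,)
    ).copy()
    return slopes, intercepts, noise


def generate_cohort(
    params: SimulationParams, causal_dosage: np.ndarray | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the phenotype table and the morphometric feature matrix.

    Returns ``(cohort, features)``: a DataFrame of per-subject phenotypes
    (including the latent ``true_delta``, synthetic-only) and a DataFrame
    of ``n_features`` continuous features indexed by ``subject_id``.

    If ``params.causal_snp_index`` is set and ``causal_dosage`` is not
    supplied, the causal SNP column is regenerated from the same seed as
    :func:`generate_genotypes`, so the two tables stay consistent.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 11]))
    n = params.n_subjects
    ids = [f"S{i:06d}" for i in range(n)]

    ca = rng.uniform(params.age_min, params.age_max, size=n)
    sex = np.where(rng.random(n) < 0.47, "male", "female")
    education_degree = (rng.random(n) < 0.45).astype(int)

    smoking = rng.choice(SMOKING_LEVELS, size=n, p=params.smoking_freq_probs)
    alcohol = rng.choice(ALCOHOL_LEVELS, size=n, p=params.alcohol_freq_probs)

    # correlated latent normals behind the two log-normal amounts
    rho = _lognormal_latent_corr(
        params.smoke_alcohol_corr, _PY_DAILY_SIGMA, _ALC_SIGMA
    )
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)

    pack_years = np.zeros(n)
    daily = smoking == "most or all days"
    occ = smoking == "occasionally"
    pack_years[daily] = np.exp(_PY_DAILY_MU + _PY_DAILY_SIGMA * z[daily, 0])
    pack_years[occ] = np.exp(_PY_OCC_MU + _PY_OCC_SIGMA * z[occ, 0])

    alcohol_g_day = np.zeros(n)
    for level, mean in _ALC_MEANS.items():
        mask = alcohol == level
        mu = math.log(mean) - _ALC_SIGMA**2 / 2.0
        alcohol_g_day[mask] = np.exp(mu + _ALC_SIGMA * z[mask, 1])

    if params.causal_snp_index is not None and causal_dosage is None:
        geno = generate_genotypes(params)
        causal_dosage = geno.dosages[:, params.causal_snp_index]
    if causal_dosage is not None:
        causal_dosage = np.asarray(causal_dosage, dtype=float)
        if causal_dosage.shape != (n,):
            raise ParameterError("causal_dosage length must equal n_subjects")
        dos = np.where(
            np.isnan(causal_dosage), np.nanmean(causal_dosage), causal_dosage
        )
    else:
        dos = np.zeros(n)

    apoe = rng.binomial(2, params.apoe_e4_freq, size=n)

    true_delta = (
        params.beta_smoke * pack_years
        + params.beta_alcohol * alcohol_g_day
        + params.beta_snp * dos
        + params.beta_apoe * apoe
        + rng.normal(0.0, params.delta_sd, size=n)
    )

    delta_c = true_delta - true_delta.mean()
    fluid = np.rint(
        np.clip(6.5 - 0.06 * delta_c + rng.normal(0.0, 2.1, size=n), 0, 13)
    ).astype(int)

    cohort = pd.DataFrame(
        {
            "subject_id": ids,
            "ca": ca,
            "sex": sex,
            "education_degree": education_degree,
            "smoking_freq": smoking,
            "pack_years": pack_years,
            "alcohol_freq": alcohol,
            "alcohol_g_day": alcohol_g_day,
            "fluid_intelligence": fluid,
            "apoe_e4_dosage": apoe,
            "true_delta": true_delta,
        }
    )

    slopes, intercepts, noise = _feature_params(params, rng)
    effective_age = ca + true_delta
    feats = (
        intercepts[None, :]
        + slopes[None, :] * effective_age[:, None]
        + rng.normal(0.0, 1.0, size=(n, params.n_features)) * noise[None, :]
    )
    names = [f"morph_{j:04d}" for j in range(params.n_features)]
    features = pd.DataFrame(feats, index=pd.Index(ids, name="subject_id"),
                            columns=names)
    return cohort, features


def generate_genotypes(params: SimulationParams) -> GenotypeMatrix:
    """Generate biallelic SNP dosages under HWE.

    Per SNP the ancestral MAF is uniform over ``maf_range``; with two
    subpopulations the per-population frequencies are drawn from a
    Balding-Nichols beta with divergence ``fst_like_divergence``.  The
    first ``2 * n_related_pairs`` subjects are full-sib pairs (each sib
    inherits one random allele from each of two shared parents), and
    genotypes are masked at ``missing_rate``.
    """
    params.validate()
    if params.n_snps < 1:
        raise ParameterError("n_snps must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 23]))
    n, m = params.n_subjects, params.n_snps

    anc = rng.uniform(*params.maf_range, size=m)
    if params.n_subpopulations == 2 and params.fst_like_divergence > 0:
        f = params.fst_like_divergence
        a, b = anc * (1 - f) / f, (1 - anc) * (1 - f) / f
        freqs = np.stack([rng.beta(a, b), rng.beta(a, b)])  # (2, m)
    else:
        freqs = np.tile(anc, (params.n_subpopulations, 1))
    pop = np.zeros(n, dtype=int)
    if params.n_subpopulations == 2:
        pop[n // 2:] = 1
    p_subj = freqs[pop, :]  # (n, m)

    dosages = rng.binomial(2, p_subj).astype(float)

    for k in range(params.n_related_pairs):
        i, j = 2 * k, 2 * k + 1
        p = p_subj[i, :]
        parent1 = rng.random((2, m)) < p[None, :]
        parent2 = rng.random((2, m)) < p[None, :]
        for subj in (i, j):
            pick1 = rng.integers(0, 2, size=m)
            pick2 = rng.integers(0, 2, size=m)
            dosages[subj, :] = (
                parent1[pick1, np.arange(m)].astype(float)
                + parent2[pick2, np.arange(m)].astype(float)
            )

    if params.missing_rate > 0:
        mask = rng.random((n, m)) < params.missing_rate
        dosages[mask] = np.nan

    chrom = (np.arange(m) % 22) + 1
    pos = 10_000 + (np.arange(m) // 22 + 1) * 1_000
    snps = pd.DataFrame(
        {
            "chrom": chrom.astype(str),
            "pos": pos.astype(int),
            "id": [f"snp{j:05d}" for j in range(m)],
            "ref": "A",
            "alt": "G",
        }
    )
    ids = [f"S{i:06d}" for i in range(n)]
    return GenotypeMatrix(dosages, ids, snps)


def generate_dataset(
    params: SimulationParams,
) -> tuple[pd.DataFrame, pd.DataFrame, GenotypeMatrix]:
    """Generate cohort, features and genotypes consistently.

    The causal SNP column (if configured) is generated once and wired
    into ``true_delta``.
    """
    geno = generate_genotypes(params)
    dos = (
        geno.dosages[:, params.causal_snp_index]
        if params.causal_snp_index is not None
        else None
    )
    cohort, features = generate_cohort(params, causal_dosage=dos)
    return cohort, features, geno
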