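"""Genotype quality control: SNP filters, sample filters, relatedness
and ancestry principal components.

Filters follow standard array-QC practice: SNPs must have missing rate
< 0.02 and Hardy-Weinberg exact-test p >= 1e-6; samples must have call
rate > 0.98 and heterozygosity within +/-3 SD of the mean; pairs with
kinship coefficient > 0.1 are pruned greedily.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, QcReport


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities
    of all heterozygote counts whose probability does not exceed that of
    the observed count (two-sided exact test, no mid-p).
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 or int(c) != c for c in counts):
        raise ValueError("genotype counts must be non-negative integers")
    n_hom_ref, n_het, n_hom_alt = (int(c) for c in counts)
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("all genotype counts are zero")

    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het    # rarer-allele count
    if rare == 0:
        return 1.0                                   # monomorphic

    # probabilities over het counts with the parity of `rare`, by the
    # standard two-term recurrence, scaled to avoid under/overflow
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    probs = {mid: 1.0}
    h = mid
    while h >= 2:
        probs[h - 2] = probs[h] * h * (h - 1) / (
            (rare - h + 2.0) * (2 * n - rare - h + 2.0)
        )
        h -= 2
    h = mid
    while h + 2 <= rare:
        probs[h + 2] = probs[h] * (rare - h) * (2 * n - rare - h) / (
            (h + 2.0) * (h + 1.0)
        )
        h += 2

    total = sum(probs.values())
    obs = probs[n_het]
    p = sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total
    return min(1.0, p)


def _genotype_counts(dosages: np.ndarray):
    """Per-SNP (hom_ref, het, hom_alt) counts ignoring missing."""
    hom_ref = np.nansum(dosages == 0, axis=0).astype(int)
    het = np.nansum(dosages == 1, axis=0).astype(int)
    hom_alt = np.nansum(dosages == 2, axis=0).astype(int)
    return hom_ref, het, hom_alt


def hwe_pvalues(geno: GenotypeMatrix) -> np.ndarray:
    """Exact HWE p per SNP (nan where no genotypes are observed)."""
    hr, het, ha = _genotype_counts(geno.dosages)
    out = np.full(geno.n_snps, np.nan)
    for j in range(geno.n_snps):
        if hr[j] + het[j] + ha[j] > 0:
            out[j] = hwe_exact_test(hr[j], het[j], ha[j])
    return out


def filter_snps(
    geno: GenotypeMatrix,
    miss_thresh: float = 0.02,
    hwe_thresh: float = 1e-6,
) -> tuple[GenotypeMatrix, QcReport]:
    """Keep SNPs with missing rate < ``miss_thresh`` and HWE p >= ``hwe_thresh``."""
    if geno.n_snps == 0 or geno.n_samples == 0:
        raise ValueError("empty genotype matrix")
    if not (0 <= miss_thresh <= 1) or not (0 <= hwe_thresh <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    miss = geno.snp_missing_rate()
    hwe = hwe_pvalues(geno)
    pass_miss = miss < miss_thresh if miss_thresh > 0 else miss == 0
    pass_hwe = ~np.isnan(hwe) & (hwe >= hwe_thresh)
    kept = pass_miss & pass_hwe
    reason = np.where(
        kept, "", np.where(~pass_miss, "missing_rate", "hwe")
    )
    report = QcReport(
        snps=pd.DataFrame(
            {
                "id": geno.snps["id"].to_numpy(),
                "missing_rate": miss,
                "maf": geno.maf(),
                "hwe_p": hwe,
                "kept": kept,
                "reason": reason,
            }
        )
    )
    return geno.subset(snp_idx=np.flatnonzero(kept)), report


def heterozygosity(geno: GenotypeMatrix) -> np.ndarray:
    """Per-sample fraction of non-missing genotypes that are heterozygous."""
    het = np.nansum(geno.dosages == 1, axis=1)
    called = (~np.isnan(geno.dosages)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(called > 0, het / called, np.nan)


def filter_samples(
    geno: GenotypeMatrix,
    call_thresh: float = 0.98,
    het_sd: float = 3.0,
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove samples with call rate <= ``call_thresh`` or heterozygosity
    outside mean +/- ``het_sd`` SD (SD computed on the passing-call-rate
    set; a zero SD removes nobody)."""
    if geno.n_samples < 2:
        raise ValueError("need at least 2 samples")
    call = geno.sample_call_rate()
    het = heterozygosity(geno)
    pass_call = call > call_thresh
    mu = het[pass_call].mean() if pass_call.any() else np.nan
    sd = het[pass_call].std() if pass_call.any() else np.nan
    if not np.isfinite(sd) or sd == 0:
        pass_het = np.ones(geno.n_samples, dtype=bool)
    else:
        pass_het = np.abs(het - mu) <= het_sd * sd
    kept = pass_call & pass_het
    if not kept.any():
        raise ValueError("sample QC removed every sample")
    reason = np.where(kept, "", np.where(~pass_call, "call_rate", "heterozygosity"))
    report = QcReport(
        samples=pd.DataFrame(
            {
                "id": geno.samples,
                "call_rate": call,
                "heterozygosity": het,
                "kept": kept,
                "reason": reason,
            }
        )
    )
    return geno.subset(sample_idx=np.flatnonzero(kept)), report


def kinship(geno: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise kinship coefficients (KING-robust style).

    For samples i, j over SNPs genotyped in both:

        phi_ij = (N_AaAa - 2 * N_AA,aa) / (N_Aa^i + N_Aa^j)

    where N_AaAa counts shared heterozygous SNPs, N_AA,aa counts
    opposite-homozygote SNPs and N_Aa^i counts SNPs heterozygous in i
    within the shared non-missing set.  Duplicates score ~0.5, full
    sibs ~0.25, unrelated pairs ~0; robust to population structure.
    """
    if geno.n_samples < 2:
        raise ValueError("need at least 2 samples")
    d = geno.dosages
    valid = (~np.isnan(d)).astype(float)
    H = (d == 1).astype(float)
    A0 = (d == 0).astype(float)
    A2 = (d == 2).astype(float)

    n_aa = H @ H.T
    n_opp = A0 @ A2.T + A2 @ A0.T
    het_shared = H @ valid.T             # [i, j] = N_Aa^i on shared SNPs
    denom = het_shared + het_shared.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(denom > 0, (n_aa - 2.0 * n_opp) / denom, np.nan)
    return pd.DataFrame(phi, index=geno.samples, columns=geno.samples)


def related_pairs(kin: pd.DataFrame, threshold: float = 0.1) -> pd.DataFrame:
    """Pairs with kinship above ``threshold`` (upper triangle)."""
    ids = list(kin.index)
    phi = kin.to_numpy()
    iu, ju = np.triu_indices(len(ids), k=1)
    mask = phi[iu, ju] > threshold
    return pd.DataFrame(
        {
            "id1": [ids[i] for i in iu[mask]],
            "id2": [ids[j] for j in ju[mask]],
            "kinship": phi[iu, ju][mask],
        }
    )


def remove_related(
    kin: pd.DataFrame,
    threshold: float = 0.1,
    missingness: pd.Series | None = None,
) -> list[str]:
    """Greedy pruning of related samples; returns kept ids.

    While any pair exceeds ``threshold``, the member with the higher
    genotype missingness is dropped (ties broken toward keeping the
    lexicographically smaller id).
    """
    ids = list(kin.index)
    if missingness is None:
        miss = np.zeros(len(ids))
    else:
        miss = np.asarray([missingness.get(s, 0.0) for s in ids], dtype=float)
    phi = kin.to_numpy()
    iu, ju = np.triu_indices(len(ids), k=1)
    above = phi[iu, ju] > threshold
    iu, ju, vals = iu[above], ju[above], phi[iu, ju][above]
    order = np.argsort(-vals, kind="stable")
    removed = np.zeros(len(ids), dtype=bool)
    for k in order:
        a, b = int(iu[k]), int(ju[k])
        if removed[a] or removed[b]:
            continue
        if miss[a] > miss[b]:
            removed[a] = True
        elif miss[b] > miss[a]:
            removed[b] = True
        else:
            removed[a if ids[a] > ids[b] else b] = True
    return [s for s, r in zip(ids, removed) if not r]


def genotype_pca(geno: GenotypeMatrix, k: int = 5,
                 return_loadings: bool = False):
    """Principal components of the column-standardized dosage matrix.

    Missing genotypes are imputed to the per-SNP mean; monomorphic SNPs
    (zero variance) are excluded; components are ordered by decreasing
    variance with each component's largest-magnitude loading made
    positive.  Returns a samples x k score DataFrame (and optionally the
    SNP loading matrix).
    """
    d = geno.dosages.copy()
    col_mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = col_mean[inds[1]]
    d -= d.mean(axis=0)
    sd = d.std(axis=0)
    keep = sd > 0
    X = d[:, keep] / sd[keep]

    rank = np.linalg.matrix_rank(X)
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k, :].T
    for j in range(k):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    cols = [f"PC{j + 1}" for j in range(k)]
    score_df = pd.DataFrame(scores, index=geno.samples, columns=cols)
    if return_loadings:
        load_df = pd.DataFrame(
            loadings, index=geno.snps["id"].to_numpy()[keep], columns=cols
        )
        return score_df, load_df
    return score_df
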