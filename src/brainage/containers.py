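"""Shared in-memory containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs allele-dosage matrix.

    ``dosages`` counts copies of the ALT allele: values 0, 1, 2 with
    ``numpy.nan`` for missing genotypes.  ``snps`` carries one row per
    variant with columns ``chrom``, ``pos`` (1-based), ``id``, ``ref``,
    ``alt``.  Minor-allele orientation is *not* applied at construction;
    :func:`brainage.qc` computes folded MAF on demand.
    """

    dosages: np.ndarray            # (n_samples, n_snps), float, nan = missing
    samples: list[str]
    snps: pd.DataFrame
    n_skipped_multiallelic: int = 0

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x snps)")
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.snps)} snps"
            )
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or nan")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def alt_freq(self) -> np.ndarray:
        """Per-SNP ALT-allele frequency from non-missing genotypes."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Per-SNP minor-allele frequency (folded, in [0, 0.5])."""
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def snp_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        """Row/column subset; indices are positional."""
        d = self.dosages
        samples = self.samples
        snps = self.snps
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            d = d[sample_idx, :]
            samples = [self.samples[i] for i in sample_idx]
        if snp_idx is not None:
            snp_idx = np.asarray(snp_idx)
            d = d[:, snp_idx]
            snps = snps.iloc[snp_idx].reset_index(drop=True)
        return GenotypeMatrix(d.copy(), list(samples), snps.copy(),
                              self.n_skipped_multiallelic)

    def select_samples(self, ids) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in genotype matrix: {missing[:5]}")
        return self.subset(sample_idx=[pos[s] for s in ids])


@dataclass
class QcReport:
    """Record of a QC pass: per-unit metrics plus removal reasons."""

    snps: pd.DataFrame = field(default_factory=pd.DataFrame)
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)
    kinship_pairs: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self) -> dict:
        out = {}
        if len(self.snps):
            out["n_snps_in"] = int(len(self.snps))
            out["n_snps_removed"] = int((~self.snps["kept"]).sum())
        if len(self.samples):
            out["n_samples_in"] = int(len(self.samples))
            out["n_samples_removed"] = int((~self.samples["kept"]).sum())
        if len(self.kinship_pairs):
            out["n_related_pairs"] = int(len(self.kinship_pairs))
        return out
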