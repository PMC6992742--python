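"""Readers and writers: phenotype/morphometric TSVs, VCF genotypes and
result bundles (TSV tables + JSON metadata sidecar)."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import GenotypeMatrix

log = logging.getLogger(__name__)

#: Columns every phenotype table must carry.
REQUIRED_PHENOTYPE_COLUMNS = ("subject_id", "ca", "sex")

_NA_VALUES = ["", "NA"]


class FormatError(ValueError):
    """A file violates the expected on-disk format."""


def read_phenotypes(path, required=REQUIRED_PHENOTYPE_COLUMNS) -> pd.DataFrame:
    """Read a tab-separated phenotype table.

    Empty fields and ``NA`` are treated as missing; unknown columns are
    preserved.  Duplicate subject ids or absent mandatory columns raise
    :class:`FormatError`.
    """
    table = pd.read_csv(path, sep="\t", na_values=_NA_VALUES,
                        keep_default_na=False, dtype={"subject_id": str})
    missing_cols = [c for c in required if c not in table.columns]
    if missing_cols:
        raise FormatError(f"missing mandatory column(s): {missing_cols}")
    dup = table["subject_id"][table["subject_id"].duplicated()]
    if len(dup):
        raise FormatError(f"duplicate subject_id: {sorted(set(dup))[:5]}")
    return table


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_morphometrics(path) -> pd.DataFrame:
    """Read a subjects x features TSV indexed by subject_id."""
    feats = pd.read_csv(path, sep="\t", index_col="subject_id",
                        na_values=_NA_VALUES, keep_default_na=False)
    if feats.index.duplicated().any():
        raise FormatError("duplicate subject_id in morphometric table")
    return feats


def write_morphometrics(features: pd.DataFrame, path) -> None:
    features.to_csv(path, sep="\t", index=True, na_rep="NA")


_GT_STRINGS = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with GT-only genotype fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(geno.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        for j, snp in geno.snps.iterrows():
            gts = [
                _GT_STRINGS.get(geno.dosages[i, j], "./.")
                for i in range(geno.n_samples)
            ]
            fh.write(
                f"{snp['chrom']}\t{snp['pos']}\t{snp['id']}\t{snp['ref']}\t"
                f"{snp['alt']}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into an ALT-dosage matrix.

    ``./.`` genotypes become missing; multi-allelic records are skipped
    with a warning and counted in ``n_skipped_multiallelic``.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows = []
    dosage_cols = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        # with gts012=True: 0/1/2 = ALT-allele count, 3 = missing
        gt = np.asarray(var.gt_types, dtype=float)
        gt[gt == 3] = np.nan
        dosage_cols.append(gt)
        rows.append(
            {
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "id": var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}",
                "ref": var.REF,
                "alt": var.ALT[0],
            }
        )
    vcf.close()
    if n_skipped:
        msg = f"skipped {n_skipped} multi-allelic record(s)"
        log.warning(msg)
        warnings.warn(msg)
    if not rows:
        raise FormatError("no biallelic SNP records found")
    dosages = np.column_stack(dosage_cols)
    return GenotypeMatrix(dosages, samples, pd.DataFrame(rows), n_skipped)


@dataclass
class ResultBundle:
    """A run's outputs: named tables plus JSON-serializable metadata.

    Writes each table as a TSV and the metadata as a sidecar
    ``metadata.json``; round-trips losslessly.
    """

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(out / f"{name}.tsv", sep="\t", index=False, na_rep="NA")
        meta = dict(self.metadata)
        meta["_tables"] = sorted(self.tables)
        with open(out / "metadata.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)

    @classmethod
    def read(cls, out_dir) -> "ResultBundle":
        out = Path(out_dir)
        with open(out / "metadata.json") as fh:
            meta = json.load(fh)
        names = meta.pop("_tables")
        tables = {
            name: pd.read_csv(out / f"{name}.tsv", sep="\t",
                              na_values=_NA_VALUES, keep_default_na=False)
            for name in names
        }
        return cls(tables=tables, metadata=meta)
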