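"""Readers, writers and curation steps for genotype and phenotype data.

The pipeline's genotype substrate is a biallelic SNP dosage matrix
(accessions x loci, alt-allele counts 0/1/2 with NaN for missing calls).
Genotypes enter as VCF; phenotypes as long-format trial records
(accession, environment, trial, block, trait, value); repeated qualitative
scores as (accession, year, trait, value) tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRIAL_COLUMNS = ["accession", "environment", "trial", "block", "trait", "value"]
QUAL_COLUMNS = ["accession", "year", "trait", "value"]


def _chrom_sort_key(chrom: str):
    """Numeric chromosomes before lexicographic ones (1..18 < chrX)."""
    s = str(chrom)
    s_stripped = s[3:] if s.lower().startswith("chr") else s
    try:
        return (0, int(s_stripped), "")
    except ValueError:
        return (1, 0, s)


@dataclass
class GenotypeMatrix:
    """Accessions x loci alt-allele dosage matrix.

    dosages holds floats: 0/1/2 for called genotypes, NaN for missing.
    After mean imputation values become real-valued and ``imputed`` is set;
    diversity statistics refuse imputed matrices because fabricated
    fractional heterozygotes would bias Ho/Hs.
    """

    accession_ids: list
    loci: pd.DataFrame  # columns: chrom, pos, ref, alt
    dosages: np.ndarray
    imputed: bool = False

    def __post_init__(self):
        self.accession_ids = list(self.accession_ids)
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ValueError("duplicated accession ids in genotype matrix")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.accession_ids), len(self.loci)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.loci)} loci"
            )
        if not self.imputed:
            vals = self.dosages[~np.isnan(self.dosages)]
            if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
                raise ValueError("raw dosages must lie in {0, 1, 2, NaN}")
        self._sort_loci()

    def _sort_loci(self):
        loci = self.loci.reset_index(drop=True)
        key = [(_chrom_sort_key(c), p) for c, p in zip(loci["chrom"], loci["pos"])]
        order = sorted(range(len(loci)), key=lambda i: key[i])
        self.loci = loci.iloc[order].reset_index(drop=True)
        self.dosages = self.dosages[:, order]

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def index_of(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        missing = [a for a in ids if a not in lookup]
        if missing:
            raise KeyError(f"accessions absent from genotype matrix: {missing[:5]}")
        return np.array([lookup[a] for a in ids], dtype=int)

    def subset(self, ids) -> "GenotypeMatrix":
        idx = self.index_of(ids)
        return GenotypeMatrix(
            accession_ids=[self.accession_ids[i] for i in idx],
            loci=self.loci.copy(),
            dosages=self.dosages[idx].copy(),
            imputed=self.imputed,
        )


# ---------------------------------------------------------------------------
# VCF

_GT_TO_DOSAGE = {(0, 0): 0.0, (0, 1): 1.0, (1, 0): 1.0, (1, 1): 2.0}
_DOSAGE_TO_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Load a biallelic SNP VCF into a dosage matrix.

    GT fields are converted to alt-allele counts; ``./.`` becomes NaN.
    Multiallelic records are rejected (the record's CHROM:POS is named).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicated sample ids in VCF header")
    chroms, poss, refs, alts, rows = [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {var.CHROM}:{var.POS}; "
                "only biallelic SNPs are supported"
            )
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        dos = np.empty(len(samples))
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                dos[i] = np.nan
            else:
                dos[i] = _GT_TO_DOSAGE[(a, b)]
        rows.append(dos)
    vcf.close()
    loci = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    dosages = np.array(rows).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(accession_ids=samples, loci=loci, dosages=dosages)


def write_genotypes_vcf(gm: GenotypeMatrix, path) -> None:
    """Write the matrix as a minimal plain-text VCFv4.2 (GT only)."""
    if gm.imputed:
        raise ValueError("refusing to write imputed (real-valued) dosages as GT")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=germcore\n")
        seen = dict.fromkeys(gm.loci["chrom"])
        for chrom in seen:
            sub = gm.loci[gm.loci["chrom"] == chrom]
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(a) for a in gm.accession_ids)
            + "\n"
        )
        for j, locus in gm.loci.iterrows():
            gts = [
                "./." if np.isnan(d) else _DOSAGE_TO_GT[d] for d in gm.dosages[:, j]
            ]
            fh.write(
                f"{locus['chrom']}\t{int(locus['pos'])}\t.\t{locus['ref']}\t"
                f"{locus['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# QC, imputation, aggregation


def qc_filter(gm: GenotypeMatrix, maf_min: float = 0.05, max_missing: float = 0.20):
    """Drop loci failing minor-allele-frequency or missingness thresholds.

    MAF is computed on non-missing calls only. Returns the filtered matrix
    and a log dict with per-rule drop counts (a locus failing both rules is
    counted under both, but dropped once).
    """
    if not (0 <= maf_min < 0.5):
        raise ValueError("maf_min must lie in [0, 0.5)")
    if not (0 <= max_missing <= 1):
        raise ValueError("max_missing must lie in [0, 1]")
    d = gm.dosages
    n_called = np.sum(~np.isnan(d), axis=0)
    miss_frac = 1.0 - n_called / gm.n_accessions
    with np.errstate(invalid="ignore"):
        p_alt = np.nansum(d, axis=0) / np.maximum(2 * n_called, 1)
    maf = np.minimum(p_alt, 1 - p_alt)
    fail_maf = (maf < maf_min) | (n_called == 0)
    fail_miss = miss_frac > max_missing
    keep = ~(fail_maf | fail_miss)
    log = {
        "n_input": gm.n_loci,
        "n_dropped_maf": int(fail_maf.sum()),
        "n_dropped_missing": int(fail_miss.sum()),
        "n_kept": int(keep.sum()),
        "maf_min": maf_min,
        "max_missing": max_missing,
    }
    if log["n_kept"] == 0:
        warnings.warn("qc_filter removed every locus", stacklevel=2)
    out = GenotypeMatrix(
        accession_ids=list(gm.accession_ids),
        loci=gm.loci[keep].reset_index(drop=True),
        dosages=gm.dosages[:, keep].copy(),
        imputed=gm.imputed,
    )
    return out, log


def impute_mean(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the locus mean (real-valued).

    The result is flagged imputed: ordination accepts it, diversity
    statistics do not. An all-missing locus is an error.
    """
    d = gm.dosages.copy()
    n_called = np.sum(~np.isnan(d), axis=0)
    if (n_called == 0).any():
        j = int(np.argmax(n_called == 0))
        locus = gm.loci.iloc[j]
        raise ValueError(f"locus {locus['chrom']}:{locus['pos']} has no calls")
    means = np.nanmean(d, axis=0)
    nan_r, nan_c = np.where(np.isnan(d))
    d[nan_r, nan_c] = means[nan_c]
    return GenotypeMatrix(
        accession_ids=list(gm.accession_ids),
        loci=gm.loci.copy(),
        dosages=d,
        imputed=True,
    )


def aggregate_mode(qual: pd.DataFrame) -> pd.DataFrame:
    """Collapse repeated yearly qualitative scores to one modal class.

    Ties are broken by the most recent year among tied classes, then by the
    lowest class code. Output has one row per (accession, trait).
    """
    required = set(QUAL_COLUMNS)
    if not required.issubset(qual.columns):
        raise ValueError(f"qualitative table must have columns {QUAL_COLUMNS}")
    rows = []
    for (acc, trait), grp in qual.groupby(["accession", "trait"], sort=True):
        counts = grp.groupby("value").agg(n=("value", "size"), last=("year", "max"))
        counts = counts.reset_index()
        counts = counts.sort_values(
            ["n", "last", "value"], ascending=[False, False, True]
        )
        rows.append({"accession": acc, "trait": trait, "value": counts.iloc[0]["value"]})
    return pd.DataFrame(rows, columns=["accession", "trait", "value"])


# ---------------------------------------------------------------------------
# Trial records


def validate_trial_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"trial records missing columns: {missing}")
    if not np.isfinite(records["value"]).all():
        raise ValueError("non-finite phenotype values in trial records")
    key = ["accession", "environment", "trial", "block", "trait"]
    if records.duplicated(key).any():
        raise ValueError("duplicate (accession, environment, trial, block, trait) keys")
    return records


def read_trial_records(path) -> pd.DataFrame:
    return validate_trial_records(pd.read_csv(path, sep="\t"))


def write_trial_records(records: pd.DataFrame, path) -> None:
    validate_trial_records(records).to_csv(path, sep="\t", index=False)


def read_qualitative(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_qualitative(qual: pd.DataFrame, path) -> None:
    qual.to_csv(path, sep="\t", index=False)
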