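"""Cohort ingestion: delimited phenotype/genotype tables and VCF.

Genotypes are oriented as counts of the *minor* allele, recomputed from
the data (ties at frequency 0.5 keep the ALT/file orientation), so
results do not depend on how the file happened to be coded.  Subjects
with a missing trait are dropped globally; missing genotypes are
handled per SNP (complete-case), and SNPs whose missingness exceeds a
configurable fraction (default 15%) are flagged for exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .rank_stats import InputError

logger = logging.getLogger("twophase_npt")

DEFAULT_MISSINGNESS_THRESHOLD = 0.15


@dataclass
class CohortTable:
    """Per-subject trait, 0/1/2 genotype dosages (NaN = missing), covariates."""

    trait: pd.Series
    genotypes: pd.DataFrame
    covariates: pd.DataFrame | None = None
    missingness: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    excluded_snps: list[str] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.trait)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.genotypes.columns)

    def for_snp(self, snp: str) -> tuple[np.ndarray, np.ndarray]:
        """Complete-case (traits, genotypes) for one SNP; logs exclusions."""
        if snp not in self.genotypes.columns:
            raise InputError(f"unknown SNP {snp!r}")
        g = self.genotypes[snp]
        keep = g.notna() & self.trait.notna()
        dropped = int((~keep).sum())
        if dropped:
            logger.info("SNP %s: excluding %d subjects with missing data", snp, dropped)
        return self.trait[keep].to_numpy(float), g[keep].to_numpy().astype(int)

    def analyzable_snps(self) -> list[str]:
        return [s for s in self.snp_ids if s not in self.excluded_snps]

    def write(self, phenotype_path, genotype_path) -> None:
        """Write the cohort back to two CSVs (lossless round trip)."""
        pheno = pd.DataFrame({"subject": self.trait.index, "trait": self.trait.values})
        if self.covariates is not None:
            for c in self.covariates.columns:
                pheno[c] = self.covariates[c].values
        pheno.to_csv(phenotype_path, index=False)
        geno = self.genotypes.copy()
        geno.insert(0, "subject", geno.index)
        geno.to_csv(genotype_path, index=False)


def _read_delimited(path) -> pd.DataFrame:
    """Read a headered table, auto-detecting comma vs tab from the header."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"file not found: {path}")
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    try:
        return pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:
        raise InputError(f"malformed delimited file {path}: {exc}") from exc


def _orient_minor(dosages: pd.Series) -> tuple[pd.Series, bool]:
    """Flip dosages to count the minor allele; ties at 0.5 keep orientation."""
    freq = dosages.mean(skipna=True) / 2.0
    if freq > 0.5:
        return 2.0 - dosages, True
    return dosages, False


def _genotypes_from_vcf(path) -> pd.DataFrame:
    """ALT-allele dosages per subject from a diploid VCF (NaN = missing).

    Multi-allelic records are skipped with a warning; half-calls count
    as missing.
    """
    from cyvcf2 import VCF

    path = str(path)
    if not Path(path).exists():
        raise InputError(f"file not found: {path}")
    vcf = VCF(path)
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning(
                "skipping multi-allelic record %s:%d", var.CHROM, var.POS
            )
            continue
        name = var.ID or f"{var.CHROM}:{var.POS}"
        gts = np.asarray(var.genotypes, dtype=object)
        dos = np.full(len(samples), np.nan)
        for i, gt in enumerate(gts):
            alleles = [a for a in gt[:-1]]
            if len(alleles) != 2 or any(a < 0 for a in alleles):
                continue  # missing or half-call
            dos[i] = sum(1 for a in alleles if a > 0)
        columns[name] = dos
    return pd.DataFrame(columns, index=pd.Index(samples, name="subject"))


def read_cohort(
    phenotype_path,
    genotype_path,
    fmt: str = "delimited",
    trait_column: str | None = None,
    covariate_columns: list[str] | None = None,
    missingness_threshold: float = DEFAULT_MISSINGNESS_THRESHOLD,
) -> CohortTable:
    """Load a cohort from a phenotype table plus genotypes.

    The phenotype table (CSV/TSV, header row) needs a subject-id first
    column and a trait column (``trait_column`` or the second column).
    Genotypes come either from a delimited table of 0/1/2 dosages
    (subjects in rows, SNPs in columns) or from a VCF.  Genotypes are
    re-oriented to minor-allele counts and per-SNP missingness above
    ``missingness_threshold`` flags the SNP as excluded.
    """
    pheno = _read_delimited(phenotype_path)
    if pheno.shape[1] < 2:
        raise InputError("phenotype table needs subject-id and trait columns")
    subj_col = pheno.columns[0]
    trait_col = trait_column or pheno.columns[1]
    if trait_col not in pheno.columns:
        raise InputError(f"trait column {trait_col!r} not in phenotype table")
    pheno = pheno.set_index(subj_col)
    pheno.index = pheno.index.astype(str)

    if fmt == "delimited":
        geno = _read_delimited(genotype_path)
        geno = geno.set_index(geno.columns[0])
        geno.index = geno.index.astype(str)
        geno = geno.apply(pd.to_numeric, errors="coerce")
        bad = geno.stack(future_stack=True).dropna()
        offending = bad[~bad.isin([0, 1, 2])]
        if len(offending):
            subj, snp = offending.index[0]
            raise InputError(
                f"genotype outside {{0,1,2}} for subject {subj!r} at SNP {snp!r}"
            )
    elif fmt == "vcf":
        geno = _genotypes_from_vcf(genotype_path)
    else:
        raise InputError(f"unknown genotype format {fmt!r}")

    common = pheno.index.intersection(geno.index)
    if len(common) == 0:
        raise InputError("no overlapping subjects between phenotype and genotype files")
    pheno = pheno.loc[common]
    geno = geno.loc[common]

    trait = pd.to_numeric(pheno[trait_col], errors="coerce")
    n_missing_trait = int(trait.isna().sum())
    if n_missing_trait:
        logger.info("excluding %d subjects with missing trait", n_missing_trait)
        keep = trait.notna()
        trait, geno, pheno = trait[keep], geno[keep], pheno[keep]

    flipped = []
    for snp in geno.columns:
        geno[snp], was_flipped = _orient_minor(geno[snp])
        if was_flipped:
            flipped.append(snp)
    if flipped:
        logger.info("re-oriented %d SNPs to minor-allele counts", len(flipped))

    missingness = geno.isna().mean()
    excluded = list(missingness.index[missingness > missingness_threshold])
    for snp in excluded:
        logger.warning(
            "SNP %s excluded: %.1f%% missing genotypes (threshold %.0f%%)",
            snp, 100 * missingness[snp], 100 * missingness_threshold,
        )

    covariates = None
    if covariate_columns:
        missing_cols = [c for c in covariate_columns if c not in pheno.columns]
        if missing_cols:
            raise InputError(f"covariate columns not found: {missing_cols}")
        covariates = pheno[covariate_columns].astype(float)

    return CohortTable(
        trait=trait,
        genotypes=geno,
        covariates=covariates,
        missingness=missingness,
        excluded_snps=excluded,
    )
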