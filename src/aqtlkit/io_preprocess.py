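"""Data containers, file readers/writers and transcriptome preprocessing.

The containers here are thin, validated wrappers around pandas objects:

* :class:`ExpressionMatrix` — genes x samples abundance with a tracked unit
  (``rpkm``, ``tpm``, ``log2tpm`` or ``zscore``) and optional gene TSS
  coordinates.
* :class:`GenotypeMatrix` — variants x samples alt-allele dosages in [0, 2]
  with 1-based variant coordinates.
* :class:`PhenotypeTable` — one row per sample; quantitative phenotypes plus
  an ``age`` column used as a QTL covariate.
* :class:`GwasSummary` — per-variant marginal association statistics
  (beta, se, p) for one trait.

Preprocessing follows the standard RNA-seq recipe for this kind of study:
RPKM is renormalised per sample to TPM, genes are dropped when fewer than
5% of samples exceed a global expression floor (the minimum per-sample
TPM/RPKM scaling factor), and the retained matrix is log2 transformed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VALID_UNITS = ("rpkm", "tpm", "log2tpm", "zscore")


def _check_unique(index: pd.Index, what: str) -> None:
    if index.duplicated().any():
        dups = index[index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what} ids: {dups}")


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with unit metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
    unit
        One of ``rpkm``, ``tpm``, ``log2tpm``, ``zscore``.
    gene_coords
        Optional DataFrame indexed by gene id with columns ``chrom`` and
        ``tss`` (1-based transcription start position).
    """

    values: pd.DataFrame
    unit: str
    gene_coords: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if self.unit in ("rpkm", "tpm") and (arr < 0).any():
            raise ValueError(f"{self.unit} values must be nonnegative")
        if self.gene_coords is not None:
            missing = self.values.index.difference(self.gene_coords.index)
            if len(missing):
                raise ValueError(f"{len(missing)} genes lack coordinates")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_genes(self, genes) -> "ExpressionMatrix":
        coords = None
        if self.gene_coords is not None:
            coords = self.gene_coords.loc[genes]
        return ExpressionMatrix(self.values.loc[genes], self.unit, coords)


@dataclass
class GenotypeMatrix:
    """Variants x samples dosage matrix with coordinates and MAF."""

    dosages: pd.DataFrame
    variant_coords: pd.DataFrame  # index variant_id, columns chrom, pos

    def __post_init__(self) -> None:
        _check_unique(self.dosages.index, "variant")
        _check_unique(self.dosages.columns, "sample")
        arr = self.dosages.to_numpy()
        if np.nanmin(arr) < 0 or np.nanmax(arr) > 2:
            raise ValueError("dosages must lie in [0, 2]")
        missing = self.dosages.index.difference(self.variant_coords.index)
        if len(missing):
            raise ValueError(f"{len(missing)} variants lack coordinates")
        pos = self.variant_coords["pos"].to_numpy()
        if (pos < 1).any():
            raise ValueError("variant positions must be positive (1-based)")

    @property
    def variant_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def maf(self) -> pd.Series:
        p = self.dosages.mean(axis=1) / 2.0
        return np.minimum(p, 1.0 - p).rename("maf")


@dataclass
class PhenotypeTable:
    """Per-sample phenotype values; ``age`` is the standard QTL covariate."""

    table: pd.DataFrame  # index sample_id

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def phenotype(self, name: str) -> pd.Series:
        return self.table[name]


GWAS_COLUMNS = ("variant_id", "chrom", "pos", "beta", "se", "p")


@dataclass
class GwasSummary:
    """Marginal GWAS summary statistics for one trait."""

    table: pd.DataFrame
    trait: str = "trait"

    def __post_init__(self) -> None:
        for col in GWAS_COLUMNS:
            if col not in self.table.columns:
                raise ValueError(f"GWAS table missing column {col!r}")
        t = self.table
        if (t["se"] <= 0).any():
            raise ValueError("GWAS se must be > 0")
        if ((t["p"] <= 0) | (t["p"] > 1)).any():
            raise ValueError("GWAS p must lie in (0, 1]")
        # flag p-values inconsistent with the normal approximation from beta/se
        from scipy.stats import norm

        z = np.abs(t["beta"].to_numpy() / t["se"].to_numpy())
        expected = 2.0 * norm.sf(z)
        self.inconsistent_p = pd.Series(
            np.abs(t["p"].to_numpy() - expected) > 1e-6, index=t.index
        )
        if self.inconsistent_p.any():
            log.warning(
                "%d GWAS rows have p inconsistent with beta/se (flagged)",
                int(self.inconsistent_p.sum()),
            )


# ---------------------------------------------------------------------------
# preprocessing


def rpkm_to_tpm(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Renormalise RPKM to TPM: each sample's values scaled to sum to 1e6."""
    if expr.unit != "rpkm":
        raise ValueError(f"expected rpkm input, got {expr.unit}")
    colsums = expr.values.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise ValueError(f"all-zero RPKM for sample(s): {zero.index.tolist()}")
    tpm = expr.values.div(colsums, axis=1) * 1e6
    return ExpressionMatrix(tpm, "tpm", expr.gene_coords)


def scaling_factors(expr_rpkm: ExpressionMatrix, expr_tpm: ExpressionMatrix) -> pd.Series:
    """Per-sample ratio of mean TPM to mean RPKM across all genes."""
    if not expr_rpkm.values.index.equals(expr_tpm.values.index) or not (
        expr_rpkm.values.columns.equals(expr_tpm.values.columns)
    ):
        raise ValueError("RPKM and TPM matrices must share gene and sample ids")
    factors = expr_tpm.values.mean(axis=0) / expr_rpkm.values.mean(axis=0)
    return factors.rename("scaling_factor")


def filter_low_expression(
    expr_tpm: ExpressionMatrix, factors: pd.Series, frac: float = 0.05
) -> ExpressionMatrix:
    """Drop genes expressed above the floor in fewer than ``frac`` of samples.

    The floor is the minimum per-sample scaling factor; a gene is kept when
    TPM exceeds it in at least ``frac`` of samples (strictly fewer → dropped).
    """
    if expr_tpm.unit != "tpm":
        raise ValueError(f"expected tpm input, got {expr_tpm.unit}")
    if not 0 < frac <= 1:
        raise ValueError(f"frac must lie in (0, 1], got {frac}")
    floor = float(factors.min())
    n = expr_tpm.values.shape[1]
    n_above = (expr_tpm.values > floor).sum(axis=1)
    keep = n_above >= frac * n
    dropped = int((~keep).sum())
    if dropped:
        log.info("filter_low_expression: dropped %d/%d genes", dropped, len(keep))
    return expr_tpm.subset_genes(expr_tpm.gene_ids[keep.to_numpy()])


def log2_transform(expr_tpm: ExpressionMatrix, pseudocount: float = 1e-3) -> ExpressionMatrix:
    """log2(TPM + pseudocount)."""
    if (expr_tpm.values.to_numpy() < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    out = np.log2(expr_tpm.values + pseudocount)
    return ExpressionMatrix(out, "log2tpm", expr_tpm.gene_coords)


# ---------------------------------------------------------------------------
# readers / writers

FLOAT_FMT = "%.10g"


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FMT, na_rep=".")


def read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["."])
    df.index.name = None
    df.columns.name = None
    return df


def read_gwas_tsv(path, trait: str | None = None) -> GwasSummary:
    df = pd.read_csv(path, sep="\t", na_values=["."])
    if trait is None:
        trait = str(df["trait"].iloc[0]) if "trait" in df.columns else "trait"
    return GwasSummary(df, trait=trait)


def write_gwas_tsv(gwas: GwasSummary, path) -> None:
    gwas.table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT, na_rep=".")


def read_regulator_list(path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split("\t")[0])
    return out


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic variants from a VCF into a dosage matrix.

    The DS FORMAT field is used when present, otherwise the GT alt-allele
    count. Multi-allelic records are skipped with a logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, rows = [], [], [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        ds = None
        if "DS" in (rec.FORMAT or []):
            ds = np.asarray(rec.format("DS"), dtype=float).reshape(-1)
        else:
            # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = rec.gt_types
            ds = np.where(gt == 3, 2.0, np.where(gt == 1, 1.0, 0.0))
            ds[gt == 2] = np.nan
        ids.append(rec.ID or f"{rec.CHROM}_{rec.POS}")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        rows.append(ds)
    if n_skipped:
        log.info("read_vcf: skipped %d non-biallelic records", n_skipped)
    if not rows:
        raise ValueError(f"no biallelic variants in {path}")
    dosages = pd.DataFrame(np.vstack(rows), index=ids, columns=samples)
    coords = pd.DataFrame({"chrom": chroms, "pos": poss}, index=ids)
    return GenotypeMatrix(dosages, coords)


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a dosage matrix as a minimal VCF v4.2 with GT and DS fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        chroms = geno.variant_coords["chrom"]
        for c in pd.unique(chroms):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.sample_ids)
            + "\n"
        )
        order = geno.variant_coords.sort_values(["chrom", "pos"]).index
        for vid in order:
            chrom = geno.variant_coords.at[vid, "chrom"]
            pos = geno.variant_coords.at[vid, "pos"]
            ds = geno.dosages.loc[vid]
            fields = []
            for d in ds:
                g = int(round(d))
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}[min(max(g, 0), 2)]
                fields.append(f"{gt}:{d:.6g}")
            fh.write(
                f"{chrom}\t{pos}\t{vid}\tA\tG\t.\tPASS\t.\tGT:DS\t" + "\t".join(fields) + "\n"
            )


def assemble_covariates(
    pheno: PhenotypeTable, pcs: pd.DataFrame | None = None, age_col: str = "age"
) -> pd.DataFrame:
    """Join age with genotype PCs on the shared samples."""
    cov = pheno.table[[age_col]].copy()
    if pcs is not None:
        cov = cov.join(pcs, how="inner")
    return cov
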