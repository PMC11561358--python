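"""Readers and writers for the pipeline's external formats.

Summary statistics, dosage matrices (VCF 4.2 with a DS FORMAT field, or a
plain TSV), whitespace pedigrees (FID IID PAT MAT SEX), phenotype tables and
result tables.  All readers are strict: a malformed input raises a typed
error rather than producing a silently wrong value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeSet",
    "read_sumstats", "write_sumstats",
    "read_genotypes_vcf", "write_genotypes_vcf",
    "read_genotypes_tsv", "write_genotypes_tsv",
    "read_pedigree", "write_pedigree",
    "read_phenotypes", "write_phenotypes",
    "read_results", "write_results",
    "RESULT_COLUMNS",
]

DEFAULT_SUMSTATS_COLUMNS = {
    "id": "SNP", "chrom": "CHR", "pos": "BP",
    "effect_allele": "A1", "other_allele": "A2",
    "weight": "BETA", "se": "SE", "p": "P", "maf": "FRQ", "info": "INFO",
}

RESULT_COLUMNS = ["outcome", "model", "n", "estimate", "se",
                  "ci_low", "ci_high", "p", "p_fdr", "r2_delta"]

_VARIANT_COLUMNS = ["id", "chrom", "pos", "counted_allele", "other_allele"]


@dataclass
class GenotypeSet:
    """Sample-by-variant dosage matrix with variant metadata.

    Dosages count the ``counted_allele`` (ALT) and lie in [0, 2]; fractional
    values represent imputed genotypes and NaN marks missingness.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray
    haplotypes: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        if self.dosage.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError("dosage matrix shape does not match samples x variants")
        if self.variants["id"].duplicated().any():
            dup = self.variants.loc[self.variants["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate variant id {dup!r}")
        finite = self.dosage[~np.isnan(self.dosage)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2] or be missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)


def read_sumstats(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read GWAS summary statistics from a delimited text file.

    Rows with unparseable numeric fields are dropped (count logged);
    duplicate variant ids raise a ``ValueError`` naming the id.
    """
    colmap = dict(DEFAULT_SUMSTATS_COLUMNS)
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    if df.empty:
        raise ValueError(f"empty summary-statistics file: {path}")
    missing = [src for src in colmap.values() if src not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s) {missing} in {path}")
    out = pd.DataFrame({dst: df[src] for dst, src in colmap.items()})
    numeric = ["pos", "weight", "se", "p", "maf", "info"]
    for col in numeric:
        out[col] = pd.to_numeric(out[col], errors="coerce")
    bad = out[numeric].isna().any(axis=1)
    if bad.any():
        logger.info("read_sumstats: dropped %d row(s) with unparseable numerics",
                    int(bad.sum()))
    out = out[~bad].reset_index(drop=True)
    out["pos"] = out["pos"].astype(int)
    if out["id"].duplicated().any():
        dup = out.loc[out["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicated variant id {dup!r} in {path}")
    out.attrs["n_dropped"] = int(bad.sum())
    return out


def write_sumstats(sumstats: pd.DataFrame, path) -> None:
    df = sumstats
    if "id" in df.columns:  # internal naming -> file naming
        inv = {dst: src for dst, src in DEFAULT_SUMSTATS_COLUMNS.items()}
        df = df.rename(columns=inv)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes

def read_genotypes_vcf(path) -> GenotypeSet:
    """Read dosages from a VCF.  DS is preferred; otherwise dosage is the GT
    ALT-allele count.  Multi-allelic records are dropped with a logged count."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    meta_rows, dosage_rows = [], []
    n_multi = 0
    saw_field = False
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        fmt = list(v.FORMAT)
        if "DS" in fmt:
            saw_field = True
            row = v.format("DS")[:, 0].astype(float)
            row[row < 0] = np.nan
        elif "GT" in fmt:
            saw_field = True
            alleles = np.array([[g[0], g[1]] for g in v.genotypes], dtype=float)
            alleles[alleles < 0] = np.nan
            row = alleles.sum(axis=1)
        else:
            raise ValueError(f"VCF record {v.ID} has no DS and no GT field")
        meta_rows.append((v.ID, v.CHROM, v.POS, v.ALT[0], v.REF))
        dosage_rows.append(row)
    if not saw_field and not dosage_rows:
        raise ValueError(f"no usable DS or GT records in {path}")
    if n_multi:
        logger.info("read_genotypes_vcf: dropped %d multi-allelic record(s)", n_multi)
    variants = pd.DataFrame(meta_rows, columns=_VARIANT_COLUMNS)
    gs = GenotypeSet(sample_ids=samples, variants=variants,
                     dosage=np.array(dosage_rows).T if dosage_rows
                     else np.empty((len(samples), 0)))
    gs.variants.attrs["n_multiallelic_dropped"] = n_multi
    return gs


def write_genotypes_vcf(gs: GenotypeSet, path, write_gt: bool = False) -> None:
    """Write a minimal VCF 4.2 with per-sample DS (dosage) values."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        if write_gt:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gs.sample_ids) + "\n")
        fmt = "GT:DS" if write_gt else "DS"
        for j, row in gs.variants.iterrows():
            cells = []
            for i in range(gs.n_samples):
                d = gs.dosage[i, j]
                ds = "." if np.isnan(d) else f"{d:.6g}"
                if write_gt:
                    gt = "./." if np.isnan(d) else \
                        {0: "0/0", 1: "0/1", 2: "1/1"}.get(int(round(d)), "./.")
                    cells.append(f"{gt}:{ds}")
                else:
                    cells.append(ds)
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t"
                     f"{row['other_allele']}\t{row['counted_allele']}\t.\t.\t.\t"
                     f"{fmt}\t" + "\t".join(cells) + "\n")


def write_genotypes_tsv(gs: GenotypeSet, path) -> None:
    df = gs.variants[_VARIANT_COLUMNS].copy()
    for i, sid in enumerate(gs.sample_ids):
        df[sid] = gs.dosage[i]
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_genotypes_tsv(path) -> GenotypeSet:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in _VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing variant metadata column(s) {missing} in {path}")
    sample_cols = [c for c in df.columns if c not in _VARIANT_COLUMNS]
    if not sample_cols:
        raise ValueError(f"no sample columns in {path}")
    dosage = df[sample_cols].to_numpy(dtype=float).T
    return GenotypeSet(sample_ids=sample_cols,
                       variants=df[_VARIANT_COLUMNS].copy(), dosage=dosage)


# ---------------------------------------------------------------------------
# pedigree / phenotypes / results

def read_pedigree(path) -> pd.DataFrame:
    """Whitespace pedigree FID IID PAT MAT SEX; missing parent coded '0'.

    A row with exactly one known parent is flagged in ``half_parent_info``
    (such records cannot enter full-sib strata)."""
    ped = pd.read_csv(path, sep=r"\s+", header=None,
                      names=["family_id", "individual_id", "father_id",
                             "mother_id", "sex"],
                      dtype={0: str, 1: str, 2: str, 3: str})
    if ped["individual_id"].duplicated().any():
        dup = ped.loc[ped["individual_id"].duplicated(), "individual_id"].iloc[0]
        raise ValueError(f"duplicate individual id {dup!r} in {path}")
    ped["sex"] = pd.to_numeric(ped["sex"], errors="coerce").astype("Int64")
    ped["half_parent_info"] = (ped["father_id"] == "0") != (ped["mother_id"] == "0")
    if ped["half_parent_info"].any():
        logger.info("read_pedigree: %d record(s) with exactly one known parent",
                    int(ped["half_parent_info"].sum()))
    return ped


def write_pedigree(ped: pd.DataFrame, path) -> None:
    cols = ["family_id", "individual_id", "father_id", "mother_id", "sex"]
    ped[cols].to_csv(path, sep=" ", index=False, header=False)


def read_phenotypes(path, schema: list[str] | None = None) -> pd.DataFrame:
    """Phenotype/covariate TSV with a header row.  ``schema`` lists required
    columns; missing ones raise a ``ValueError`` naming them."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if schema:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype file {path} is missing column(s) {missing}")
    return df


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")


def write_results(results: pd.DataFrame, path) -> None:
    df = results.copy()
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    extra = [c for c in df.columns if c not in RESULT_COLUMNS]
    df[RESULT_COLUMNS + extra].to_csv(path, sep="\t", index=False,
                                      na_rep="NA", float_format="%.15g")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"results file {path} is missing column(s) {missing}")
    return df
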