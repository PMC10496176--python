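"""Readers and writers for every on-disk format the pipeline touches.

Tab-separated tables for phenotypes, kinship, dosages, summary statistics
and literature loci; VCF (GT + DS, INFO/R2) for genotypes; YAML for schemes
and pipeline configuration.  Every writer round-trips through its reader.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .schemes import parse_braak, parse_cerad, parse_lewy

__all__ = [
    "read_phenotypes",
    "write_phenotypes",
    "read_kinship",
    "write_kinship",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_vcf",
    "write_vcf",
    "read_literature_loci",
    "packaged_literature_loci",
    "write_summary_stats",
    "read_summary_stats",
]

PHENOTYPE_COLUMNS = ["id", "site", "sex", "age_at_death", "braak", "cerad", "lewy_dist"]

_SEX_CODES = {
    "0": 0.0, "m": 0.0, "male": 0.0,
    "1": 1.0, "f": 1.0, "female": 1.0,
}


def _parse_sex(value) -> float:
    if pd.isna(value) or str(value).strip() == "":
        return np.nan
    s = str(value).strip().lower()
    if s.endswith(".0"):
        s = s[:-2]
    if s in _SEX_CODES:
        return _SEX_CODES[s]
    raise ValueError(f"invalid sex code: {value!r}")


def read_phenotypes(path) -> tuple:
    """Read a phenotype TSV into a typed frame plus a parse-error report.

    Returns (records, errors).  ``records`` has integer braak/cerad (NaN
    where missing or unparseable), canonical lewy_dist strings, numeric
    sex/age_at_death.  ``errors`` lists (id, field, value, message) for every
    cell that failed to parse; bad cells become NaN rather than being
    silently coerced, so downstream stages can exclude those individuals
    with an explicit reason.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"phenotype table missing required columns: {missing}")

    errors = []

    def cell(row_id, fieldname, value, parser):
        if pd.isna(value) or str(value).strip() == "":
            return np.nan
        try:
            return parser(value)
        except ValueError as exc:
            errors.append((row_id, fieldname, value, str(exc)))
            return np.nan

    records = pd.DataFrame({"id": raw["id"].astype(str), "site": raw["site"]})
    records["sex"] = [
        cell(i, "sex", v, _parse_sex) for i, v in zip(records["id"], raw["sex"])
    ]
    records["age_at_death"] = [
        cell(i, "age_at_death", v, float)
        for i, v in zip(records["id"], raw["age_at_death"])
    ]
    records["braak"] = [
        cell(i, "braak", v, parse_braak) for i, v in zip(records["id"], raw["braak"])
    ]
    records["cerad"] = [
        cell(i, "cerad", v, parse_cerad) for i, v in zip(records["id"], raw["cerad"])
    ]
    records["lewy_dist"] = [
        cell(i, "lewy_dist", v, parse_lewy)
        for i, v in zip(records["id"], raw["lewy_dist"])
    ]
    error_report = pd.DataFrame(errors, columns=["id", "field", "value", "message"])
    return records, error_report


def write_phenotypes(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False, columns=PHENOTYPE_COLUMNS)


def read_kinship(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id1": str, "id2": str})
    missing = [c for c in ("id1", "id2", "kinship") if c not in df.columns]
    if missing:
        raise ValueError(f"kinship table missing columns: {missing}")
    return df


def write_kinship(kinship: pd.DataFrame, path) -> None:
    kinship.to_csv(path, sep="\t", index=False, columns=["id1", "id2", "kinship"])


# --- dosage matrix TSV ------------------------------------------------------

_DOSAGE_META = ["id", "chrom", "pos", "ref", "alt", "imputation_r2"]


def write_dosage_tsv(gm: GenotypeMatrix, path) -> None:
    """Variants as rows: metadata columns then one dosage column per sample."""
    table = gm.variants[_DOSAGE_META].copy()
    dosage_cols = pd.DataFrame(gm.dosages, columns=gm.samples)
    pd.concat([table, dosage_cols], axis=1).to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in _DOSAGE_META if c not in df.columns]
    if missing:
        raise ValueError(f"dosage table missing columns: {missing}")
    samples = [c for c in df.columns if c not in _DOSAGE_META]
    variants = df[_DOSAGE_META].copy()
    variants["id"] = variants["id"].astype(str)
    variants["chrom"] = variants["chrom"].astype(str)
    dosages = df[samples].to_numpy(dtype=float)
    return GenotypeMatrix(variants=variants, samples=samples, dosages=dosages)


# --- VCF --------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt-allele dosage">
"""


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write an uncompressed VCF with GT and DS per sample and INFO/R2."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in gm.samples)
            + "\n"
        )
        hard = gm.hard_genotypes
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
        for i, v in gm.variants.iterrows():
            r2 = v["imputation_r2"]
            info = "." if pd.isna(r2) else f"R2={r2:g}"
            cells = []
            for j in range(gm.n_samples):
                d = gm.dosages[i, j]
                if np.isnan(d):
                    cells.append("./.:.")
                    continue
                if hard is not None and not np.isnan(hard[i, j]):
                    g = int(hard[i, j])
                else:
                    g = int(np.clip(np.rint(d), 0, 2))
                cells.append(f"{gt_strings[g]}:{d:g}")
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['ref']}\t{v['alt']}"
                f"\t.\t.\t{info}\tGT:DS\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a bi-allelic VCF with DS (or GT) fields via cyvcf2."""
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    meta_rows = []
    dosage_rows = []
    hard_rows = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS}; "
                "input must be bi-allelic"
            )
        r2 = rec.INFO.get("R2")
        meta_rows.append(
            {
                "id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "imputation_r2": np.nan if r2 is None else float(r2),
            }
        )
        try:
            ds = np.asarray(rec.format("DS"), dtype=float).reshape(-1)
        except (TypeError, KeyError):
            ds = None
        gts = np.asarray(rec.gt_types, dtype=float)  # 0,1,2 and 3=unknown
        gts[gts == 3] = np.nan
        # cyvcf2 codes HOM_ALT as 3 when gts012=False; use genotype array
        g = np.array(
            [
                np.nan
                if -1 in alleles[:2]
                else float(alleles[0] + alleles[1])
                for alleles in rec.genotypes
            ]
        )
        hard_rows.append(g)
        dosage_rows.append(g.copy() if ds is None else ds)
    vcf.close()
    variants = pd.DataFrame(meta_rows)
    dosages = np.array(dosage_rows, dtype=float)
    hard = np.array(hard_rows, dtype=float)
    # missing dosage wherever the genotype was missing
    if dosages.size:
        dosages[np.isnan(hard) & ~np.isnan(dosages)] = np.nan
    return GenotypeMatrix(
        variants=variants, samples=samples, dosages=dosages, hard_genotypes=hard
    )


# --- literature loci and summary statistics ---------------------------------


def read_literature_loci(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chrom": str})
    required = ["rsid", "chrom", "pos", "effect_allele", "other_allele",
                "direction", "source", "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"locus table missing columns: {missing}")
    return df


def packaged_literature_loci() -> pd.DataFrame:
    """Synthetic-coordinate locus fixture shipped with the package."""
    ref = importlib.resources.files("copath.data").joinpath("literature_loci.tsv")
    with ref.open() as fh:
        return read_literature_loci(fh)


SUMMARY_STAT_COLUMNS = [
    "variant_id",
    "chromosome",
    "base_pair_location",
    "effect_allele",
    "other_allele",
    "effect_allele_frequency",
    "beta",
    "standard_error",
    "p_value",
]

_INTERNAL_TO_CATALOG = {
    "variant": "variant_id",
    "chrom": "chromosome",
    "pos": "base_pair_location",
    "eaf": "effect_allele_frequency",
    "se": "standard_error",
    "p": "p_value",
}


def write_summary_stats(results: pd.DataFrame, path) -> None:
    """Write association/meta results with GWAS-Catalog-style headers."""
    out = results.rename(columns=_INTERNAL_TO_CATALOG)
    cols = SUMMARY_STAT_COLUMNS + [
        c for c in out.columns if c not in SUMMARY_STAT_COLUMNS
    ]
    out.to_csv(path, sep="\t", index=False, columns=cols, na_rep="NA")


def read_summary_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"chromosome": str})
    inverse = {v: k for k, v in _INTERNAL_TO_CATALOG.items()}
    return df.rename(columns=inverse)
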