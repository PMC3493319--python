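"""Readers and writers for the plain-text formats the toolkit exchanges.

Dialect: tab-separated, UTF-8, no quoting, ``.`` for absent numeric
fields. Genotype TSV is samples x markers with a header of marker ids and
sample ids in column 1; phenotype TSV has the trait in column 2 and any
further columns as covariates. VCF v4.x is read through cyvcf2, using the
DS (dosage) FORMAT field when present and the GT allele count otherwise.
"""

from __future__ import annotations

import warnings
from os import PathLike
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypeMatrix, PhenotypeTable, VQTLTestResult
from .errors import FormatError, ParseError, ValidationError

__all__ = [
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_phenotypes_tsv",
    "write_phenotypes_tsv",
    "read_genotypes_vcf",
    "write_results_tsv",
    "results_to_frame",
]

NA_TOKEN = "."

RESULT_COLUMNS = [
    "marker_id", "method", "n_used",
    "mean_beta", "mean_se", "mean_p",
    "disp_beta", "disp_se", "disp_stat", "disp_df", "disp_p", "disp_p_adj",
    "converged", "warnings",
]


def read_genotypes_tsv(path: str | PathLike) -> GenotypeMatrix:
    """Read a samples x markers dosage matrix from TSV."""
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
    fields = header.split("\t")
    if len(fields) < 2:
        raise FormatError(f"{path}: header must list at least one marker id")
    marker_ids = fields[1:]
    df = pd.read_csv(path, sep="\t", dtype={fields[0]: str}, na_values=[], keep_default_na=False)
    sample_ids = df.iloc[:, 0].tolist()
    body = df.iloc[:, 1:]
    try:
        dosages = body.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for j, col in enumerate(body.columns):
            for i, cell in enumerate(body[col]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"{path}: non-numeric dosage {cell!r} at sample "
                        f"{sample_ids[i]!r}, marker {marker_ids[j]!r}"
                    ) from None
        raise
    return GenotypeMatrix(sample_ids, marker_ids, dosages)


def write_genotypes_tsv(genotypes: GenotypeMatrix, path: str | PathLike) -> None:
    df = pd.DataFrame(genotypes.dosages, columns=genotypes.marker_ids)
    df.insert(0, "sample_id", genotypes.sample_ids)
    df.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


def read_phenotypes_tsv(path: str | PathLike) -> PhenotypeTable:
    """Read a phenotype table: sample id, trait, then covariate columns."""
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN, ""], dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need at least sample-id and trait columns")
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    try:
        trait = df.iloc[:, 1].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-numeric trait value ({exc})") from None
    covariates = df.iloc[:, 2:].astype(float) if df.shape[1] > 2 else pd.DataFrame()
    return PhenotypeTable(sample_ids, trait, covariates)


def write_phenotypes_tsv(phenotypes: PhenotypeTable, path: str | PathLike) -> None:
    df = pd.DataFrame({"sample_id": phenotypes.sample_ids, "trait": phenotypes.trait})
    for col in phenotypes.covariates.columns:
        df[col] = phenotypes.covariates[col].to_numpy()
    df.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


def read_genotypes_vcf(path: str | PathLike, missing_policy: str = "error") -> GenotypeMatrix:
    """Read biallelic markers from a VCF into a dosage matrix.

    The DS FORMAT field, when present, takes precedence over the GT allele
    count. Multi-allelic records are skipped with a warning. Missing hard
    calls are either rejected (``missing_policy='error'``) or replaced by
    the marker mean dosage (``'mean_impute'``).
    """
    from cyvcf2 import VCF

    if missing_policy not in ("error", "mean_impute"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    marker_ids: list[str] = []
    columns: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            warnings.warn(
                f"skipping multi-allelic record {variant.CHROM}:{variant.POS}",
                stacklevel=2,
            )
            continue
        marker_id = variant.ID if variant.ID not in (None, ".") else (
            f"{variant.CHROM}:{variant.POS}_{variant.REF}_{variant.ALT[0]}"
        )
        ds = variant.format("DS")
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gts = variant.genotypes  # [allele1, allele2, phased] per sample
            col = np.empty(len(sample_ids))
            for i, gt in enumerate(gts):
                alleles = [a for a in gt[:-1] if a >= 0]
                if len(alleles) < 2:
                    col[i] = np.nan
                else:
                    col[i] = float(sum(alleles))
        if np.isnan(col).any():
            if missing_policy == "error":
                raise ValidationError(f"missing genotype at marker {marker_id}")
            observed = col[~np.isnan(col)]
            if observed.size == 0:
                raise ValidationError(f"marker {marker_id} has no observed genotypes")
            col = np.where(np.isnan(col), observed.mean(), col)
        marker_ids.append(marker_id)
        columns.append(col)
    if not marker_ids:
        raise ValidationError(f"{path}: no biallelic markers found")
    return GenotypeMatrix(sample_ids, marker_ids, np.column_stack(columns))


def _adjust_pvalues(p: np.ndarray, method: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if method == "none":
        out[ok] = p[ok]
    elif method == "bonferroni":
        out[ok] = np.minimum(1.0, p[ok] * ok.sum())
    elif method == "bh":
        out[ok] = stats.false_discovery_control(p[ok], method="bh")
    else:
        raise ValueError(f"unknown adjustment {method!r}")
    return out


def results_to_frame(
    results: Iterable[VQTLTestResult], adjust: str = "none"
) -> pd.DataFrame:
    """Tabulate results, adding a dispersion p-value adjusted within method."""
    results = list(results)
    if not results:
        raise ValidationError("no results to write")
    rows = []
    for r in results:
        rows.append({
            "marker_id": r.marker_id, "method": r.method, "n_used": r.n_used,
            "mean_beta": r.mean_beta, "mean_se": r.mean_se, "mean_p": r.mean_p,
            "disp_beta": r.disp_beta, "disp_se": r.disp_se,
            "disp_stat": r.disp_stat, "disp_df": r.disp_df, "disp_p": r.disp_p,
            "disp_p_adj": np.nan,
            "converged": r.converged,
            "warnings": ";".join(r.warnings) if r.warnings else "",
        })
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    for method in df["method"].unique():
        mask = df["method"] == method
        df.loc[mask, "disp_p_adj"] = _adjust_pvalues(
            df.loc[mask, "disp_p"].to_numpy(), adjust
        )
    return df


def write_results_tsv(
    results: Iterable[VQTLTestResult], path: str | PathLike, adjust: str = "none"
) -> None:
    """Write one row per marker x method with a fixed column order."""
    df = results_to_frame(results, adjust=adjust)
    df.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)
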