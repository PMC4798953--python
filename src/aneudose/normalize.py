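"""Log2-ratio normalization and per-chromosome copy-number summaries.

Normalization centers the euploid-chromosome ratios to zero: within each
(strain, replicate, assay) the mean log2 ratio over genes on the declared
euploid chromosomes is subtracted from every gene.  Copy numbers follow
``c = P * 2**(log2 ratio)``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import GeneTable
from .errors import ValidationError

ASSAY_COLUMNS = {"dna": "dna_log2", "rna": "rna_log2"}


def log2_to_copy(r, base_ploidy: int):
    """Copy number from a centered log2 ratio: ``P * 2**r``."""
    if base_ploidy not in (1, 2):
        raise ValidationError("base_ploidy must be 1 or 2")
    return base_ploidy * np.exp2(r)


def copy_to_log2(c, base_ploidy: int):
    """Inverse of :func:`log2_to_copy`: expected log2 ratio of copy ``c``."""
    if base_ploidy not in (1, 2):
        raise ValidationError("base_ploidy must be 1 or 2")
    return np.log2(np.asarray(c, dtype=float) / base_ploidy)


def center_to_euploid(
    table: GeneTable,
    euploid_chromosomes,
    center: str = "mean",
) -> GeneTable:
    """Center each (strain, replicate, assay) so euploid genes average zero.

    All genes within a (strain, replicate, assay) are shifted by the same
    constant — the mean (or, optionally, median) log2 ratio of genes on the
    euploid chromosomes.  Centering is idempotent and shift-equivariant.
    """
    euploid = set(euploid_chromosomes)
    if not euploid:
        raise ValidationError("euploid chromosome set must not be empty")
    if not euploid & set(table.df["chromosome"]):
        raise ValidationError("euploid set covers no genes in the table")
    if center not in ("mean", "median"):
        raise ValidationError("center must be 'mean' or 'median'")
    df = table.df.copy()
    on_euploid = df["chromosome"].isin(euploid)
    for col in ASSAY_COLUMNS.values():
        ref = df.loc[on_euploid & df[col].notna(), [
            "strain", "replicate", col]]
        if ref.empty:
            continue
        agg = ref.groupby(["strain", "replicate"])[col].agg(center)
        shift = df.set_index(["strain", "replicate"]).index.map(agg)
        df[col] = df[col] - np.asarray(shift, dtype=float)
    return table.with_df(df)


def auto_euploid(table: GeneTable, assay: str = "dna", tol: float = 0.15) -> set[str]:
    """Heuristic euploid set: chromosomes whose uncentered mean log2 ratio
    lies within ``tol`` of the genome median.

    Convenience only — on heterogeneous strains the declared-karyotype route
    is the safe one, and silent auto-detection is exactly where small
    normalization offsets (0.1–0.2 log2 units) creep in.
    """
    col = ASSAY_COLUMNS[assay]
    means = table.df.groupby("chromosome")[col].mean().dropna()
    med = means.median()
    return set(means.index[(means - med).abs() <= tol])


def chromosome_summaries(table: GeneTable, base_ploidy: int | None = None) -> pd.DataFrame:
    """Per-(strain, chromosome, assay) mean log2 ratio and copy number.

    The grand mean is the mean of replicate-level chromosome means; the
    replicate SD is the SD across those replicate means (NaN for a single
    replicate).  Chromosomes with no genes carrying an assay are omitted
    with a warning.
    """
    P = base_ploidy if base_ploidy is not None else table.base_ploidy
    rows = []
    for assay, col in ASSAY_COLUMNS.items():
        sub = table.df[table.df[col].notna()]
        if sub.empty:
            continue
        rep_means = (
            sub.groupby(["strain", "chromosome", "replicate"])[col]
            .mean()
            .reset_index()
        )
        for (strain, chrom), grp in rep_means.groupby(["strain", "chromosome"]):
            mean = grp[col].mean()
            sd = grp[col].std(ddof=1) if len(grp) > 1 else np.nan
            n_genes = sub[(sub["strain"] == strain) & (sub["chromosome"] == chrom)][
                "gene_id"].nunique()
            rows.append({
                "strain": strain, "chromosome": chrom, "assay": assay,
                "mean_log2": mean, "replicate_sd": sd, "n_genes": n_genes,
                "copy_number": float(log2_to_copy(mean, P)),
            })
    out = pd.DataFrame(rows)
    if not out.empty:
        for assay in out["assay"].unique():
            have = set(out.loc[out["assay"] == assay, "chromosome"])
            missing = set(table.df["chromosome"].unique()) - have
            if missing:
                warnings.warn(f"{assay}: no values on chromosome(s) {sorted(missing)}; omitted")
        order = {c: i for i, c in enumerate(table.chromosome_set)}
        out = out.sort_values(
            ["strain", "assay", "chromosome"],
            key=lambda s: s.map(order) if s.name == "chromosome" else s,
        ).reset_index(drop=True)
    return out
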