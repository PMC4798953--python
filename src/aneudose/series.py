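"""Ploidy-series slope analysis and its false-discovery machinery.

In a strain series carrying 2, 3 and 4 copies of one chromosome, a gene
whose expression tracks its copy number has slope 1 when RNA log2 ratios
are regressed on dose in doubling units, x = log2(c / P); a fully
compensated gene has slope 0.  A slope threshold (default 0.5) surrogates
the published classifier's dividing line.  With only three dose levels and
noisy RNA, low slopes arise readily by chance, which is what the
slope-permutation FDR and the one-SD replicate-consistency filter quantify.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GeneTable
from .errors import InsufficientDataError, UndefinedFdrError, ValidationError
from .fdr import FdrResult
from .normalize import copy_to_log2


@dataclass
class SeriesGeneFit:
    gene_id: str | None
    doses: list[int]
    x: np.ndarray                 # log2(c / P) per fitted point
    rna: np.ndarray
    slope: float
    intercept: float
    residual_ss: float
    classification: str           # "proportional" | "candidate-compensated"


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    if sxx == 0:
        raise InsufficientDataError("need >= 2 distinct dose levels")
    slope = ((x - xm) * (y - ym)).sum() / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    return float(slope), float(intercept), float((resid ** 2).sum())


def per_gene_slope(
    doses,
    rna,
    base_ploidy: int = 2,
    gene_id: str | None = None,
    slope_threshold: float = 0.5,
    average_replicates: bool = True,
) -> SeriesGeneFit:
    """OLS of RNA log2 ratios on dose in doubling units, for one gene.

    ``rna`` is either one value per dose level or a (dose x replicate)
    array; replicates are averaged per dose before fitting by default
    (``average_replicates=False`` pools all points instead).
    """
    doses = list(doses)
    if len(set(doses)) < 2:
        raise InsufficientDataError("need >= 2 distinct dose levels")
    x_levels = copy_to_log2(doses, base_ploidy)
    rna_arr = np.asarray(rna, dtype=float)
    if rna_arr.ndim == 1:
        x, y = np.asarray(x_levels), rna_arr
    elif average_replicates:
        x, y = np.asarray(x_levels), np.nanmean(rna_arr, axis=1)
    else:
        reps = rna_arr.shape[1]
        x = np.repeat(np.asarray(x_levels), reps)
        y = rna_arr.ravel()
        keep = np.isfinite(y)
        x, y = x[keep], y[keep]
    slope, intercept, rss = _ols(x, y)
    cls = "candidate-compensated" if slope < slope_threshold else "proportional"
    return SeriesGeneFit(gene_id=gene_id, doses=doses, x=x, rna=y,
                         slope=slope, intercept=intercept, residual_ss=rss,
                         classification=cls)


def deviation_check(rna, doses, base_ploidy: int = 2, sigma: float = 0.3) -> np.ndarray:
    """Per-point z scores of RNA values against the proportional expectation
    log2(c / P), at an assumed measurement SD."""
    if not sigma > 0:
        raise ValidationError("sigma must be > 0")
    expected = copy_to_log2(doses, base_ploidy)
    return (np.asarray(rna, dtype=float) - expected) / sigma


# --- batch machinery over series tables -------------------------------------


def _series_matrices(series: list[tuple[int, GeneTable]], chromosome=None,
                     assay_col="rna_log2"):
    """Stack a series into genes x (dose, replicate) matrices.

    Returns (gene index, dose per column, Y matrix, X matrix) where X holds
    the measured dna_log2 (the matching DNA measurements) and Y the RNA.
    """
    y_blocks, x_blocks, col_doses = [], [], []
    gene_index = None
    for copy_number, table in series:
        sub = table if chromosome is None else table.subset(chromosomes=[chromosome])
        df = sub.df
        y = df.pivot_table(index="gene_id", columns="replicate", values="rna_log2")
        x = df.pivot_table(index="gene_id", columns="replicate", values="dna_log2")
        if gene_index is None:
            gene_index = y.index
        else:
            gene_index = gene_index.intersection(y.index)
        y_blocks.append(y)
        x_blocks.append(x)
        col_doses.extend([copy_number] * y.shape[1])
    Y = np.hstack([b.loc[gene_index].to_numpy(dtype=float) for b in y_blocks])
    X = np.hstack([b.loc[gene_index].to_numpy(dtype=float) for b in x_blocks])
    return gene_index, np.array(col_doses), Y, X


def _row_slopes(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Vectorized per-row OLS slope of Y on X."""
    xc = X - X.mean(axis=1, keepdims=True)
    yc = Y - Y.mean(axis=1, keepdims=True)
    return (xc * yc).sum(axis=1) / (xc ** 2).sum(axis=1)


def series_gene_fits(
    series: list[tuple[int, GeneTable]],
    chromosome: str | None = None,
    base_ploidy: int = 2,
    slope_threshold: float = 0.5,
    use_measured_dna: bool = True,
) -> pd.DataFrame:
    """Per-gene slopes across a ploidy series (all replicate points pooled).

    ``series`` is a list of (copy number, GeneTable).  The abscissa is the
    measured dna_log2 when available (``use_measured_dna``), else the
    nominal dose log2(c / P).  Returns a DataFrame indexed by gene with
    columns ``slope``, ``intercept``, ``classification``.
    """
    gene_index, col_doses, Y, X = _series_matrices(series, chromosome)
    if len(gene_index) == 0:
        raise ValidationError("no genes shared across the series tables")
    if not use_measured_dna or np.isnan(X).all():
        X = np.tile(copy_to_log2(col_doses, base_ploidy), (len(gene_index), 1))
    slopes = _row_slopes(X, Y)
    xm, ym = X.mean(axis=1), Y.mean(axis=1)
    out = pd.DataFrame({
        "slope": slopes,
        "intercept": ym - slopes * xm,
    }, index=gene_index)
    out["classification"] = np.where(out["slope"] < slope_threshold,
                                     "candidate-compensated", "proportional")
    return out


def replicate_consistency(
    series: dict[int, GeneTable],
    chromosome: str,
    k: float = 1.0,
    center: str = "mean",
) -> dict:
    """One-SD replicate-consistency filter for lower-than-expected genes.

    Within each ploidy level and replicate, genes on the aneuploid
    chromosome whose rna_log2 falls below (center - k * replicate SD) are
    flagged; a gene is consistent at a ploidy iff flagged in every
    replicate; the final set is the intersection across the supplied
    ploidies (classically the trisomic and tetrasomic strains).

    ``center="mean"`` uses each replicate's empirical mean over the
    chromosome's genes (the operational description of the filter);
    ``center="dose"`` uses the proportional expectation log2(c / P), which
    is robust when a substantial compensated fraction inflates the
    empirical spread.
    """
    if len(series) < 1:
        raise ValidationError("at least one ploidy level is required")
    if center not in ("mean", "dose"):
        raise ValidationError("center must be 'mean' or 'dose'")
    per_ploidy: dict[int, frozenset] = {}
    for copy_number, table in series.items():
        sub = table.subset(chromosomes=[chromosome])
        df = sub.df[sub.df["rna_log2"].notna()]
        if df.empty:
            raise ValidationError(f"{copy_number}: no RNA values on {chromosome}")
        reps = sorted(df["replicate"].unique())
        if len(reps) < 2:
            raise ValidationError(f"{copy_number}: need >= 2 replicates")
        flagged_sets = []
        for r in reps:
            rep = df[df["replicate"] == r]
            sd = rep["rna_log2"].std(ddof=1)
            mu = (rep["rna_log2"].mean() if center == "mean"
                  else float(copy_to_log2(copy_number, table.base_ploidy)))
            flagged_sets.append(set(rep.loc[rep["rna_log2"] < mu - k * sd, "gene_id"]))
        per_ploidy[copy_number] = frozenset(set.intersection(*flagged_sets))
    final = frozenset(set.intersection(*(set(s) for s in per_ploidy.values())))
    return {"per_ploidy": per_ploidy, "final": final}


def slope_permutation_fdr(
    series: list[tuple[int, GeneTable]],
    chromosome: str | None = None,
    slope_threshold: float = 0.5,
    B: int = 10_000,
    seed: int = 0,
    base_ploidy: int = 2,
    use_measured_dna: bool = True,
) -> FdrResult:
    """Permutation FDR for slope-threshold dosage-compensation calls.

    Slopes are fitted on all per-replicate measurements (e.g. nine RNA
    points and matching DNA points for a three-level, three-replicate
    series).  Each randomization permutes the RNA and DNA values across
    genes independently within every (strain, replicate) column,
    recomputes all slopes, and counts slopes below the threshold; FDR =
    100 x mean null count / observed count.
    """
    gene_index, col_doses, Y, X = _series_matrices(series, chromosome)
    n = len(gene_index)
    if n == 0:
        raise ValidationError("no genes shared across the series tables")
    if np.isnan(Y).any() or np.isnan(X).any():
        raise ValidationError("slope permutation FDR requires complete data")
    if not use_measured_dna:
        X = np.tile(copy_to_log2(col_doses, base_ploidy), (n, 1))
    observed = int((_row_slopes(X, Y) < slope_threshold).sum())
    if observed == 0:
        raise UndefinedFdrError("no observed gene below the slope threshold")
    rng = np.random.default_rng(seed)
    r = Y.shape[1]
    null_counts = np.empty(B)
    for b in range(B):
        yp = Y[np.argsort(rng.random((n, r)), axis=0), np.arange(r)]
        xp = X[np.argsort(rng.random((n, r)), axis=0), np.arange(r)]
        null_counts[b] = (_row_slopes(xp, yp) < slope_threshold).sum()
    return FdrResult(observed=observed, null_counts=null_counts)
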