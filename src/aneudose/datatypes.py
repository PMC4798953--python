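"""Shared data containers: gene tables and analysis configuration.

The universal exchange object is :class:`GeneTable`, a thin validated wrapper
around a pandas DataFrame with one row per (gene, strain, replicate) holding
the DNA and/or RNA log2(aneuploid/euploid) ratio of that gene.  Every
downstream stage consumes GeneTable / AnalysisConfig; no stage reads files
directly.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Default chromosome set: the sixteen S. cerevisiae chromosomes.
ROMAN_CHROMOSOMES: tuple[str, ...] = (
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII",
    "IX", "X", "XI", "XII", "XIII", "XIV", "XV", "XVI",
)

#: Columns a gene table must carry (position_index is derived when absent).
GENE_TABLE_COLUMNS = (
    "gene_id", "chromosome", "strain", "replicate", "dna_log2", "rna_log2",
)


@dataclass
class GeneTable:
    """Per-gene, per-replicate DNA/RNA log2 ratios with chromosome assignments.

    Parameters
    ----------
    df
        DataFrame with columns ``gene_id, chromosome, strain, replicate,
        dna_log2, rna_log2`` and optionally ``position_index``.  Missing
        ratios are NaN.
    chromosome_set
        Ordered chromosome labels the table is allowed to use.
    base_ploidy
        Base ploidy P of the strains (1 or 2).
    """

    df: pd.DataFrame
    chromosome_set: tuple[str, ...] = ROMAN_CHROMOSOMES
    base_ploidy: int = 2

    def __post_init__(self) -> None:
        self.chromosome_set = tuple(self.chromosome_set)
        if self.base_ploidy not in (1, 2):
            raise ValidationError(f"base_ploidy must be 1 or 2, got {self.base_ploidy}")
        df = self.df.copy()
        missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"gene table missing columns: {missing}")
        df["replicate"] = df["replicate"].astype(int)
        if len(df) and (df["replicate"] < 1).any():
            raise ValidationError("replicate indices must be >= 1")
        bad_chrom = set(df["chromosome"].unique()) - set(self.chromosome_set)
        if bad_chrom:
            raise ValidationError(f"chromosomes outside declared set: {sorted(bad_chrom)}")
        for col in ("dna_log2", "rna_log2"):
            df[col] = pd.to_numeric(df[col], errors="raise")
            inf = np.isinf(df[col].to_numpy(dtype=float))
            if inf.any():
                row = int(np.flatnonzero(inf)[0])
                raise ValidationError(f"non-finite {col} at row {row}")
        if len(df):
            both_absent = df["dna_log2"].isna() & df["rna_log2"].isna()
            if both_absent.any():
                row = int(np.flatnonzero(both_absent.to_numpy())[0])
                raise ValidationError(
                    f"row {row}: at least one of dna_log2/rna_log2 must be present"
                )
            dup = df.duplicated(subset=["gene_id", "strain", "replicate"])
            if dup.any():
                key = df.loc[dup.idxmax(), ["gene_id", "strain", "replicate"]].tolist()
                raise ValidationError(f"duplicate (gene, strain, replicate): {key}")
            multi = df.groupby("gene_id")["chromosome"].nunique()
            if (multi > 1).any():
                raise ValidationError(
                    f"gene mapped to several chromosomes: {multi[multi > 1].index.tolist()}"
                )
        if "position_index" not in df.columns or df["position_index"].isna().all():
            # ordinal rank along the chromosome, in row order
            df["position_index"] = (
                df.groupby(["chromosome", "strain", "replicate"], sort=False)
                .cumcount()
            )
        self.df = df.reset_index(drop=True)

    # -- convenience accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def strains(self) -> list[str]:
        return list(dict.fromkeys(self.df["strain"]))

    @property
    def replicates(self) -> list[int]:
        return sorted(self.df["replicate"].unique())

    def subset(self, *, strain=None, chromosomes=None) -> "GeneTable":
        """Return a new table restricted to a strain and/or chromosome set."""
        df = self.df
        if strain is not None:
            df = df[df["strain"] == strain]
        if chromosomes is not None:
            df = df[df["chromosome"].isin(set(chromosomes))]
        return GeneTable(df.reset_index(drop=True), self.chromosome_set, self.base_ploidy)

    def with_df(self, df: pd.DataFrame) -> "GeneTable":
        return GeneTable(df.reset_index(drop=True), self.chromosome_set, self.base_ploidy)


@dataclass
class AnalysisConfig:
    """Tunable parameters of the pipeline, with the field's default values.

    bin_width
        Histogram bin width h in log2 units.
    outlier_multiplier
        k in the mean +/- k*SD outlier rule.
    heterogeneity_alpha
        Significance level for karyotype heterogeneity t-tests.
    n_randomizations
        B, number of randomizations for the FDR engines.
    dna_sd_default
        Default per-gene DNA log2-ratio SD (approx. 10%).
    cutoff_bin_width
        Width of effective-cutoff bins in log space.
    slope_threshold
        Slope below which a ploidy-series gene is called candidate-compensated.
    random_seed
        Seed for every stochastic step.
    """

    bin_width: float = 0.2
    outlier_multiplier: float = 2.0
    heterogeneity_alpha: float = 0.01
    n_randomizations: int = 10_000
    dna_sd_default: float = 0.10
    cutoff_bin_width: float = 0.1
    slope_threshold: float = 0.5
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not self.bin_width > 0:
            raise ValidationError("bin_width must be > 0")
        if not self.outlier_multiplier > 0:
            raise ValidationError("outlier_multiplier must be > 0")
        if not 0 < self.heterogeneity_alpha < 1:
            raise ValidationError("heterogeneity_alpha must be in (0, 1)")
        if not self.n_randomizations >= 1:
            raise ValidationError("n_randomizations must be >= 1")
        if self.dna_sd_default < 0:
            raise ValidationError("dna_sd_default must be >= 0")
        if not self.cutoff_bin_width > 0:
            raise ValidationError("cutoff_bin_width must be > 0")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "AnalysisConfig":
        """Build a config from a key-value mapping; unknown keys warn."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}")
        try:
            return cls(**{k: v for k, v in mapping.items() if k in known})
        except TypeError as exc:  # pragma: no cover - defensive
            raise ValidationError(str(exc)) from exc
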