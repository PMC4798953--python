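"""Reading and writing gene tables (TSV) and analysis configuration (YAML/JSON).

The on-disk gene-table format is a UTF-8 tab-separated file with header
``gene_id  chromosome  strain  replicate  dna_log2  rna_log2`` (an optional
``position_index`` column is preserved).  Empty cells denote absent ratios.
Round-trips are lossless: floats are serialized with ``repr`` precision.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .datatypes import GENE_TABLE_COLUMNS, ROMAN_CHROMOSOMES, AnalysisConfig, GeneTable
from .errors import FormatError, ValidationError


def read_gene_table(
    path,
    base_ploidy: int = 2,
    chromosome_set=ROMAN_CHROMOSOMES,
) -> GeneTable:
    """Read a TSV gene table and validate it.

    Raises :class:`FormatError` naming any missing mandatory column and
    :class:`ValidationError` for duplicate (gene, strain, replicate) rows or
    non-finite ratios (with the offending row number).
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str, "strain": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty or header-less file") from exc
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    return GeneTable(df, chromosome_set=chromosome_set, base_ploidy=base_ploidy)


def write_gene_table(table: GeneTable, path) -> None:
    """Write a gene table as TSV; ``read_gene_table`` reproduces it exactly."""
    cols = list(GENE_TABLE_COLUMNS) + ["position_index"]
    table.df.to_csv(path, sep="\t", index=False, columns=cols, na_rep="")


def load_config(path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML (or JSON) key-value file.

    Unspecified keys take their defaults; unknown keys emit a warning.
    """
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise FormatError(f"{path}: malformed config: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a key-value mapping")
    try:
        return AnalysisConfig.from_mapping(data)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
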