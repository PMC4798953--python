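"""Synthetic gene tables with known karyotype, noise and compensation truth.

The generator mirrors the statistical structure the downstream analysis
assumes: per-gene DNA log2 ratios scatter tightly (SD ~ 0.1) around
log2(c_eff / P) for a chromosome at effective copy c_eff in a strain of base
ploidy P, while RNA log2 ratios scatter more widely (per-gene SD drawn from
a configurable range) around s_g * log2(c_eff / P), where the slope s_g is 1
for an ordinary gene and 1 - d for a dosage-compensated gene of depth d.
Karyotype heterogeneity (subpopulations of cells with different copy
numbers) enters through mixture copy states, which produce non-integer
effective copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ROMAN_CHROMOSOMES, GeneTable
from .errors import ValidationError

#: Genes quantified per chromosome in a typical yeast RNA-seq experiment
#: (approximate, ~6200 genes total across the sixteen chromosomes).
DEFAULT_GENES_PER_CHROMOSOME: dict[str, int] = {
    "I": 110, "II": 430, "III": 180, "IV": 790, "V": 300, "VI": 135,
    "VII": 570, "VIII": 290, "IX": 230, "X": 380, "XI": 330, "XII": 520,
    "XIII": 480, "XIV": 410, "XV": 560, "XVI": 480,
}


@dataclass
class KaryotypeSpec:
    """Base ploidy plus per-chromosome copy states.

    ``chromosome_copies`` maps a chromosome either to an integer copy number
    or to a subpopulation mixture ``[(fraction, copy), ...]`` with fractions
    summing to 1 — the source of non-integer effective copies.  Chromosomes
    not listed sit at the base ploidy.
    """

    base_ploidy: int = 2
    chromosome_copies: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.base_ploidy not in (1, 2):
            raise ValidationError("base_ploidy must be 1 or 2")
        for chrom, state in self.chromosome_copies.items():
            if isinstance(state, (int, np.integer)):
                if state < 0:
                    raise ValidationError(f"{chrom}: copy number must be >= 0")
                continue
            fracs = [f for f, _ in state]
            copies = [c for _, c in state]
            if any(not (0 < f <= 1) for f in fracs):
                raise ValidationError(f"{chrom}: mixture fractions must lie in (0, 1]")
            if abs(sum(fracs) - 1.0) > 1e-9:
                raise ValidationError(f"{chrom}: mixture fractions must sum to 1")
            if any(c != int(c) or c < 0 for c in copies):
                raise ValidationError(f"{chrom}: mixture copies must be non-negative integers")

    def effective_copy(self, chromosome: str) -> float:
        """Population-average copy number c_eff = sum f_i * c_i."""
        state = self.chromosome_copies.get(chromosome, self.base_ploidy)
        if isinstance(state, (int, np.integer)):
            return float(state)
        return float(sum(f * c for f, c in state))

    def aneuploid_chromosomes(self, chromosomes) -> list[str]:
        """Chromosomes whose effective copy differs from the base ploidy."""
        return [
            c for c in chromosomes
            if abs(self.effective_copy(c) - self.base_ploidy) > 1e-12
        ]


@dataclass
class NoiseModel:
    """Measurement noise on the log2 scale.

    DNA per-gene SD is a single value (default 0.10, i.e. ~10% copy error);
    each gene's RNA SD is drawn once, uniformly from ``sigma_rna_range``, and
    shared across replicates — measurement dispersion is a gene property.
    """

    sigma_dna: float = 0.10
    sigma_rna_range: tuple[float, float] = (0.4, 0.8)

    def __post_init__(self) -> None:
        lo, hi = self.sigma_rna_range
        if lo > hi:
            raise ValidationError("sigma_rna_range must be (low, high)")
        if not 0 <= self.sigma_dna < lo or lo < 0:
            raise ValidationError(
                "require 0 <= sigma_dna < min(sigma_rna_range): RNA noise must exceed DNA noise"
            )


@dataclass
class CompensationSpec:
    """Which fraction of amplified-chromosome genes is compensated, how deeply.

    A compensated gene's expected rna_log2 is (1 - depth) * log2(c_eff / P):
    depth 1 pulls expression all the way back to the euploid level.
    """

    fraction: float = 0.0
    depth: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise ValidationError("fraction must lie in [0, 1]")
        if not 0 <= self.depth <= 1:
            raise ValidationError("depth must lie in [0, 1]")


@dataclass
class StrainTruth:
    """Ground truth emitted alongside a simulated strain."""

    strain: str
    effective_copies: dict[str, float]
    compensated_gene_ids: frozenset[str]
    rna_sd: pd.Series            # per-gene sigma_g
    dose: pd.Series              # per-gene log2(c_eff / P)
    compensation_depth: float


def genome_layout(genes_per_chromosome: dict[str, int] | None = None) -> pd.DataFrame:
    """Deterministic gene-to-chromosome assignment.

    Returns a DataFrame with columns ``gene_id, chromosome, position_index``;
    gene ids are ``g_<chrom>_0001`` ... in chromosome order.
    """
    if genes_per_chromosome is None:
        genes_per_chromosome = DEFAULT_GENES_PER_CHROMOSOME
    if not genes_per_chromosome:
        raise ValidationError("genes_per_chromosome must not be empty")
    rows = []
    for chrom, count in genes_per_chromosome.items():
        if count < 1:
            raise ValidationError(f"{chrom}: gene count must be >= 1")
        for i in range(int(count)):
            rows.append((f"g_{chrom}_{i + 1:04d}", chrom, i))
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "position_index"])


def _chromosome_set(layout: pd.DataFrame) -> tuple[str, ...]:
    seen = tuple(dict.fromkeys(layout["chromosome"]))
    # keep the canonical order when the layout is a subset of the yeast genome
    if set(seen) <= set(ROMAN_CHROMOSOMES):
        return tuple(c for c in ROMAN_CHROMOSOMES if c in set(seen))
    return seen


def _draw_gene_params(layout, karyotype, noise, comp, rng):
    """Per-gene dose, RNA SD and compensated set (shared by all replicates)."""
    dose = layout["chromosome"].map(
        lambda c: np.log2(karyotype.effective_copy(c) / karyotype.base_ploidy)
        if karyotype.effective_copy(c) > 0 else -np.inf
    )
    lo, hi = noise.sigma_rna_range
    sigma_g = pd.Series(rng.uniform(lo, hi, len(layout)), index=layout.index)
    aneu = karyotype.aneuploid_chromosomes(layout["chromosome"].unique())
    on_aneu = layout.index[layout["chromosome"].isin(aneu)]
    n_comp = int(round(comp.fraction * len(on_aneu)))
    comp_idx = rng.choice(on_aneu, size=n_comp, replace=False) if n_comp else []
    compensated = frozenset(layout.loc[comp_idx, "gene_id"])
    return dose, sigma_g, compensated


def _assemble(layout, karyotype, dose, sigma_g, compensated, noise, comp,
              n_replicates, strain, rng, average_dna):
    n = len(layout)
    slope = np.where(layout["gene_id"].isin(compensated), 1.0 - comp.depth, 1.0)
    dna = rng.normal(dose.to_numpy()[:, None], noise.sigma_dna, (n, n_replicates))
    if average_dna:
        # emulate mean-only DNA reporting: every replicate carries the mean
        dna = np.repeat(dna.mean(axis=1, keepdims=True), n_replicates, axis=1)
    rna = rng.normal(
        (slope * dose.to_numpy())[:, None],
        sigma_g.to_numpy()[:, None],
        (n, n_replicates),
    )
    frames = []
    for r in range(n_replicates):
        frames.append(pd.DataFrame({
            "gene_id": layout["gene_id"],
            "chromosome": layout["chromosome"],
            "strain": strain,
            "replicate": r + 1,
            "dna_log2": dna[:, r],
            "rna_log2": rna[:, r],
            "position_index": layout["position_index"],
        }))
    df = pd.concat(frames, ignore_index=True)
    return GeneTable(df, chromosome_set=_chromosome_set(layout),
                     base_ploidy=karyotype.base_ploidy)


def simulate_strain(
    layout: pd.DataFrame,
    karyotype: KaryotypeSpec,
    noise: NoiseModel | None = None,
    comp: CompensationSpec | None = None,
    n_replicates: int = 3,
    seed: int = 0,
    strain: str = "sim",
    average_dna: bool = False,
) -> tuple[GeneTable, StrainTruth]:
    """Simulate one strain's gene table plus its ground truth.

    Per replicate, gene g on a chromosome at effective copy c_eff gets
    ``dna_log2 ~ N(log2(c_eff/P), sigma_dna)`` and
    ``rna_log2 ~ N(s_g * log2(c_eff/P), sigma_g)`` with s_g = 1 - depth for
    compensated genes and 1 otherwise.  Identical seeds give identical
    tables.  ``average_dna=True`` replaces per-replicate DNA values by their
    mean (mean-only DNA reporting).
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    noise = noise if noise is not None else NoiseModel()
    comp = comp if comp is not None else CompensationSpec()
    rng = np.random.default_rng(seed)
    dose, sigma_g, compensated = _draw_gene_params(layout, karyotype, noise, comp, rng)
    if np.isneginf(dose.to_numpy()).any():
        raise ValidationError("zero-copy chromosomes cannot be simulated (log2 ratio -inf)")
    table = _assemble(layout, karyotype, dose, sigma_g, compensated, noise,
                      comp, n_replicates, strain, rng, average_dna)
    truth = StrainTruth(
        strain=strain,
        effective_copies={c: karyotype.effective_copy(c)
                          for c in dict.fromkeys(layout["chromosome"])},
        compensated_gene_ids=compensated,
        rna_sd=pd.Series(sigma_g.to_numpy(), index=layout["gene_id"].to_numpy()),
        dose=pd.Series(dose.to_numpy(), index=layout["gene_id"].to_numpy()),
        compensation_depth=comp.depth,
    )
    return table, truth


def simulate_ploidy_series(
    layout: pd.DataFrame,
    chromosome: str,
    copies: list[int],
    noise: NoiseModel | None = None,
    comp: CompensationSpec | None = None,
    n_replicates: int = 3,
    seed: int = 0,
    base_ploidy: int = 2,
) -> list[tuple[GeneTable, StrainTruth]]:
    """Simulate a strain series carrying increasing copies of one chromosome.

    All strains share the same layout, the same per-gene RNA SDs and the same
    compensated gene set, so e.g. ``copies=[2, 3, 4]`` reproduces a
    2n / 2n+1 / 2n+2 series design with a stable compensation truth.
    """
    if not copies or any(c < 1 for c in copies):
        raise ValidationError("copies must be a non-empty list of integers >= 1")
    if chromosome not in set(layout["chromosome"]):
        raise ValidationError(f"chromosome {chromosome!r} not in layout")
    noise = noise if noise is not None else NoiseModel()
    comp = comp if comp is not None else CompensationSpec()
    rng = np.random.default_rng(seed)
    # shared gene properties, drawn once from the karyotype with the most copies
    ref_karyo = KaryotypeSpec(base_ploidy, {chromosome: max(copies)})
    _, sigma_g, compensated = _draw_gene_params(layout, ref_karyo, noise, comp, rng)
    out = []
    for c in copies:
        karyo = KaryotypeSpec(base_ploidy, {chromosome: int(c)})
        dose = layout["chromosome"].map(
            lambda ch: np.log2(karyo.effective_copy(ch) / base_ploidy)
        )
        strain = f"{chromosome}_{c}n"
        table = _assemble(layout, karyo, dose, sigma_g, compensated, noise,
                          comp, n_replicates, strain, rng, average_dna=False)
        truth = StrainTruth(
            strain=strain,
            effective_copies={ch: karyo.effective_copy(ch)
                              for ch in dict.fromkeys(layout["chromosome"])},
            compensated_gene_ids=compensated if c != base_ploidy else frozenset(),
            rna_sd=pd.Series(sigma_g.to_numpy(), index=layout["gene_id"].to_numpy()),
            dose=pd.Series(dose.to_numpy(), index=layout["gene_id"].to_numpy()),
            compensation_depth=comp.depth,
        )
        out.append((table, truth))
    return out
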