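"""False-discovery-rate engines for dosage-compensation calls.

The question both engines answer: of the genes a threshold procedure labels
"dosage compensated", how many would pass by chance alone?  Two nulls are
built — (i) a replicate-permutation null that scrambles the per-replicate
compensation statistics across genes, independently per replicate column,
before re-averaging per gene; and (ii) a parametric noise null that redraws
per-gene statistics from a zero-mean normal whose SD combines the empirical
per-gene RNA noise with the DNA noise in quadrature.  FDR = mean null hit
count / observed hit count, in percent; values near 100% mean the hit list
is indistinguishable from noise.

The classification procedure itself is an input, encoded as an "effective
cutoff": per 0.1-wide bin of the compensation statistic, the probability
that a gene in that bin was flagged — reconstructable from any published
hit list without access to the original classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GeneTable
from .errors import UndefinedFdrError, ValidationError


@dataclass
class CompensationStatistics:
    """Per-gene compensation statistic: log2(RNA/DNA aneuploid-vs-euploid).

    ``per_replicate`` is a genes x replicates matrix of rna_log2 - dna_log2;
    ``per_gene`` its row means; genes lacking any complete replicate pair
    are excluded (``n_excluded``).
    """

    per_replicate: pd.DataFrame
    per_gene: pd.Series
    n_excluded: int


def compensation_statistic(table: GeneTable, strain: str | None = None,
                           chromosomes=None) -> CompensationStatistics:
    """rna_log2 - dna_log2 per gene and replicate, averaged per gene.

    On the log2 scale the difference of the RNA and DNA ratios is the
    RNA/DNA fold ratio; 0 means expression tracks copy number, -log2(c/P)
    means full compensation of the amplification.
    """
    sub = table if strain is None and chromosomes is None else table.subset(
        strain=strain, chromosomes=chromosomes)
    df = sub.df
    ok = df["rna_log2"].notna() & df["dna_log2"].notna()
    stat = (df.loc[ok, "rna_log2"] - df.loc[ok, "dna_log2"])
    wide = (
        df.loc[ok].assign(stat=stat)
        .pivot_table(index="gene_id", columns="replicate", values="stat")
    )
    complete = wide.dropna(how="all")
    n_excluded = df["gene_id"].nunique() - len(complete)
    return CompensationStatistics(
        per_replicate=complete,
        per_gene=complete.mean(axis=1),
        n_excluded=int(n_excluded),
    )


def per_gene_rna_sem(table: GeneTable, strain: str | None = None,
                     chromosomes=None) -> pd.Series:
    """Per-gene SEM of rna_log2 across replicates (SD / sqrt(r)).

    The natural noise scale for replicate-averaged statistics; genes with a
    single replicate get the median SEM of the remaining genes.
    """
    sub = table if strain is None and chromosomes is None else table.subset(
        strain=strain, chromosomes=chromosomes)
    df = sub.df[sub.df["rna_log2"].notna()]
    grp = df.groupby("gene_id")["rna_log2"]
    sem = grp.std(ddof=1) / np.sqrt(grp.count())
    med = sem.dropna().median()
    return sem.fillna(med)


# --- effective cutoff -------------------------------------------------------


@dataclass
class EffectiveCutoff:
    """Bin-wise probability of being classified compensated.

    Bins are ``width``-wide, anchored at 0, spanning the observed statistic
    range; values outside the covered range (and empty bins) carry
    probability 0.
    """

    bin_edges: np.ndarray
    probabilities: np.ndarray
    width: float = 0.1

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if ((p < 0) | (p > 1)).any():
            raise ValidationError("cutoff probabilities must lie in [0, 1]")
        if len(self.bin_edges) != len(p) + 1:
            raise ValidationError("need len(bin_edges) == len(probabilities) + 1")

    def flag_probability(self, values) -> np.ndarray:
        """Per-value probability of being flagged."""
        v = np.asarray(values, dtype=float)
        lo = int(round(self.bin_edges[0] / self.width))
        idx = np.floor(v / self.width).astype(int) - lo
        out = np.zeros(v.shape)
        inside = (idx >= 0) & (idx < len(self.probabilities))
        out[inside] = self.probabilities[idx[inside]]
        return out

    def expected_flags(self, values) -> float:
        return float(self.flag_probability(values).sum())

    def draw_flags(self, values, rng: np.random.Generator) -> np.ndarray:
        """Bernoulli realization of the per-bin flag probabilities."""
        p = self.flag_probability(values)
        return rng.random(len(p)) < p

    @classmethod
    def from_threshold(cls, threshold: float, lo: float = -6.0, hi: float = 6.0,
                       width: float = 0.1) -> "EffectiveCutoff":
        """Hard cutoff: flag everything strictly below ``threshold``."""
        lo_i, hi_i = int(np.floor(lo / width)), int(np.ceil(hi / width))
        edges = np.arange(lo_i, hi_i + 1) * width
        probs = (edges[:-1] + width / 2 < threshold).astype(float)
        return cls(bin_edges=edges, probabilities=probs, width=width)


def estimate_effective_cutoff(statistics, flagged, width: float = 0.1) -> EffectiveCutoff:
    """Reconstruct a classifier's effective cutoff from its hit list.

    ``flagged`` is either a boolean mask aligned with ``statistics`` or a
    collection of flagged gene ids (when ``statistics`` is a Series indexed
    by gene).  Per bin, the probability is flagged / total; empty bins get 0.
    """
    values = np.asarray(statistics, dtype=float)
    if isinstance(flagged, (set, frozenset, list, tuple)) and not isinstance(
            statistics, np.ndarray):
        mask = pd.Index(statistics.index).isin(set(flagged))
    else:
        mask = np.asarray(flagged, dtype=bool)
    if mask.sum() == 0:
        raise ValidationError("at least one flagged gene is required")
    idx = np.floor(values / width).astype(int)
    lo, hi = idx.min(), idx.max()
    total = np.bincount(idx - lo, minlength=hi - lo + 1)
    hit = np.bincount(idx[mask] - lo, minlength=hi - lo + 1)
    probs = np.divide(hit, total, out=np.zeros_like(hit, dtype=float),
                      where=total > 0)
    edges = np.arange(lo, hi + 2) * width
    return EffectiveCutoff(bin_edges=edges, probabilities=probs, width=width)


# --- FDR engines ------------------------------------------------------------


@dataclass
class FdrResult:
    """Observed hit count, null hit counts over B randomizations, FDR in %."""

    observed: int
    null_counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.observed <= 0:
            raise UndefinedFdrError("FDR undefined with zero observed flags")
        self.null_counts = np.asarray(self.null_counts, dtype=float)

    @property
    def fdr_percent(self) -> float:
        return 100.0 * float(self.null_counts.mean()) / self.observed

    @property
    def null_spread(self) -> float:
        """SD of the null hit counts across randomizations."""
        return float(self.null_counts.std(ddof=1)) if len(self.null_counts) > 1 else 0.0

    @property
    def monte_carlo_se_percent(self) -> float:
        """SE of the FDR estimate from randomization noise alone."""
        return 100.0 * self.null_spread / np.sqrt(len(self.null_counts)) / self.observed


def _observed_count(per_gene, cutoff, observed_count):
    if observed_count is not None:
        return int(observed_count)
    # expectation of the stochastic cutoff on the observed statistics
    return int(round(cutoff.expected_flags(np.asarray(per_gene, dtype=float))))


def permutation_fdr(
    per_replicate: pd.DataFrame,
    cutoff: EffectiveCutoff,
    B: int = 10_000,
    seed: int = 0,
    observed_count: int | None = None,
) -> FdrResult:
    """Replicate-permutation FDR.

    Each randomization permutes every replicate column independently across
    genes (preserving each column's value multiset exactly), re-averages per
    gene, applies the effective cutoff as a Bernoulli draw per gene, and
    counts hits.  The observed count defaults to the expected flag count of
    the cutoff on the unpermuted per-gene means.
    """
    if per_replicate.shape[1] < 2:
        raise ValidationError("permutation FDR needs >= 2 replicate columns")
    V = per_replicate.to_numpy(dtype=float)
    if np.isnan(V).any():
        # permute within the observed values of each column; missing cells are
        # filled per column with that column's mean so averaging stays fair
        col_means = np.nanmean(V, axis=0)
        inds = np.where(np.isnan(V))
        V = V.copy()
        V[inds] = np.take(col_means, inds[1])
    n, r = V.shape
    observed = _observed_count(per_replicate.mean(axis=1), cutoff, observed_count)
    if observed <= 0:
        raise UndefinedFdrError("FDR undefined with zero observed flags")
    rng = np.random.default_rng(seed)
    null_counts = np.empty(B)
    for b in range(B):
        order = np.argsort(rng.random((n, r)), axis=0)
        means = V[order, np.arange(r)].mean(axis=1)
        null_counts[b] = cutoff.draw_flags(means, rng).sum()
    return FdrResult(observed=observed, null_counts=null_counts)


def combine_noise(sigma_rna, sigma_dna=0.10):
    """Combined noise: sqrt(sigma_rna**2 + sigma_dna**2)."""
    sigma_rna = np.asarray(sigma_rna, dtype=float)
    if (sigma_rna < 0).any() or np.any(np.asarray(sigma_dna) < 0):
        raise ValidationError("noise SDs must be >= 0")
    return np.hypot(sigma_rna, sigma_dna)


def sampling_fdr(
    sigma_rna,
    sigma_dna: float,
    cutoff: EffectiveCutoff,
    observed_count: int,
    B: int = 10_000,
    seed: int = 0,
    expected_mean: float = 0.0,
) -> FdrResult:
    """Noise-model sampling FDR.

    Each randomization draws one statistic per gene from
    ``Normal(expected_mean, combine_noise(sigma_g, sigma_dna))`` where each
    gene's sigma_g is resampled from the empirical per-gene RNA-noise list,
    applies the cutoff (Bernoulli per gene), and counts hits.
    """
    sig = np.asarray(sigma_rna, dtype=float)
    sig = sig[np.isfinite(sig)]
    if sig.size == 0:
        raise ValidationError("per-gene sigma list must be non-empty")
    if observed_count <= 0:
        raise UndefinedFdrError("FDR undefined with zero observed flags")
    n = sig.size
    rng = np.random.default_rng(seed)
    null_counts = np.empty(B)
    for b in range(B):
        s = combine_noise(rng.choice(sig, size=n, replace=True), sigma_dna)
        draws = rng.normal(expected_mean, s)
        null_counts[b] = cutoff.draw_flags(draws, rng).sum()
    return FdrResult(observed=int(observed_count), null_counts=null_counts)
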