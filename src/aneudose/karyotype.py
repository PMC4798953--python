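"""Karyotype calling and heterogeneity testing.

A chromosome whose gene-level copy numbers deviate significantly from every
nearby integer is heterogeneous: its population-average copy number is not
an integral copy state, which happens when the described aneuploidy is only
present in a subpopulation of cells.  The test is a two-sided one-sample
t-test of per-gene copy numbers against the nearest integer(s), corrected
for multiple testing within the strain.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneTable
from .errors import InsufficientDataError, ValidationError
from .normalize import log2_to_copy

_HALF_TOL = 1e-9


@dataclass
class TTestResult:
    t: float
    p: float
    degenerate: bool = False


@dataclass
class ChromosomeCall:
    chromosome: str
    c_hat: float
    tested: list[int]
    t_stats: list[float]
    p_raw: list[float]
    p_corrected: list[float]
    verdict: str                  # "stable" or "heterogeneous"
    stable_copy: int | None       # accepted integer when stable
    n_genes: int


@dataclass
class KaryotypeReport:
    strain: str
    calls: list[ChromosomeCall]
    verdict: str                  # strain-level verdict
    alpha: float
    correction: str

    @property
    def heterogeneous(self) -> bool:
        return self.verdict == "heterogeneous"


def integer_candidates(c_hat: float) -> list[int]:
    """Nearest integer copy state(s) to test ``c_hat`` against.

    Exact half-integers return both neighbours — a 2.5-copy chromosome must
    reject both 2 and 3 to be called heterogeneous, never "stable at 3" by
    rounding luck.  Copy 0 (a lost chromosome) is an allowed candidate.
    """
    if not c_hat > 0:
        raise ValidationError("copy estimate must be > 0")
    lower = math.floor(c_hat)
    if abs(c_hat - lower - 0.5) < _HALF_TOL:
        return [lower, lower + 1]
    return [int(round(c_hat))]


def chromosome_t_test(copies, expected: int) -> TTestResult:
    """Two-sided one-sample t-test of gene-level copy numbers vs an integer.

    Zero-variance input is degenerate: p = 1 when the common value equals
    ``expected`` exactly, else p = 0, with the degenerate flag set.
    """
    values = np.asarray(copies, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 3:
        raise InsufficientDataError(
            f"need >= 3 finite copy values, got {len(values)}"
        )
    if np.ptp(values) == 0.0:
        same = values[0] == expected
        return TTestResult(t=0.0 if same else np.inf, p=1.0 if same else 0.0,
                           degenerate=True)
    t, p = stats.ttest_1samp(values, popmean=expected)
    return TTestResult(t=float(t), p=float(p))


def per_gene_copies(table: GeneTable, base_ploidy: int | None = None,
                    per_replicate: bool = False):
    """Gene-level DNA copy numbers, averaged across replicates by default."""
    P = base_ploidy if base_ploidy is not None else table.base_ploidy
    df = table.df[table.df["dna_log2"].notna()]
    if df.empty:
        raise ValidationError("DNA assay absent from table")
    if per_replicate:
        out = df.set_index(["gene_id", "chromosome"])["dna_log2"]
    else:
        out = df.groupby(["gene_id", "chromosome"])["dna_log2"].mean()
    return log2_to_copy(out, P)


def call_karyotype(
    table: GeneTable,
    base_ploidy: int | None = None,
    alpha: float = 0.01,
    correction: str = "bonferroni",
    per_replicate: bool = False,
) -> KaryotypeReport:
    """Call each chromosome's copy state and the strain's stability verdict.

    Each chromosome's estimated copy c_hat is tested against its integer
    candidate(s); p-values are corrected across all tests within the strain
    (Bonferroni by default, Benjamini–Hochberg via ``correction="bh"``).  A
    chromosome is heterogeneous iff every candidate integer is rejected; the
    strain is heterogeneous iff any chromosome is, "stable aneuploid
    confined to <=2 chromosomes" when stable with one or two chromosomes at
    an integer copy other than the base ploidy, "euploid" when none is, and
    "stable complex aneuploid" otherwise.
    """
    strains = table.strains
    if len(strains) != 1:
        raise ValidationError(
            f"call_karyotype expects a single-strain table, got {strains}; use subset()"
        )
    if correction not in ("bonferroni", "bh"):
        raise ValidationError("correction must be 'bonferroni' or 'bh'")
    P = base_ploidy if base_ploidy is not None else table.base_ploidy
    copies = per_gene_copies(table, P, per_replicate=per_replicate)
    chrom_of = copies.index.get_level_values("chromosome")

    tests = []   # (chrom_index, candidate, TTestResult)
    calls: list[ChromosomeCall] = []
    for chrom in dict.fromkeys(table.df["chromosome"]):
        vals = copies[chrom_of == chrom].to_numpy()
        if len(vals) == 0:
            continue
        c_hat = float(np.mean(vals))
        try:
            candidates = integer_candidates(c_hat)
            results = [chromosome_t_test(vals, c) for c in candidates]
        except (InsufficientDataError, ValidationError) as exc:
            warnings.warn(f"{chrom}: {exc}; skipped")
            continue
        call = ChromosomeCall(
            chromosome=chrom, c_hat=c_hat, tested=candidates,
            t_stats=[r.t for r in results], p_raw=[r.p for r in results],
            p_corrected=[], verdict="", stable_copy=None, n_genes=len(vals),
        )
        for cand, res in zip(candidates, results):
            tests.append((len(calls), cand, res))
        calls.append(call)

    if not tests:
        raise ValidationError("no chromosome could be tested")
    raw = np.array([res.p for _, _, res in tests])
    if correction == "bonferroni":
        corrected = np.minimum(raw * len(raw), 1.0)
    else:
        corrected = multipletests(raw, method="fdr_bh")[1]
    for (idx, cand, _), p_corr in zip(tests, corrected):
        calls[idx].p_corrected.append(float(p_corr))

    n_aneuploid = 0
    any_hetero = False
    for call in calls:
        accepted = [c for c, p in zip(call.tested, call.p_corrected) if p >= alpha]
        if accepted:
            call.verdict = "stable"
            # with a half-integer tie, keep the less-rejected neighbour
            call.stable_copy = max(
                accepted, key=lambda c: call.p_corrected[call.tested.index(c)]
            )
            if call.stable_copy != P:
                n_aneuploid += 1
        else:
            call.verdict = "heterogeneous"
            any_hetero = True

    if any_hetero:
        verdict = "heterogeneous"
    elif n_aneuploid == 0:
        verdict = "euploid"
    elif n_aneuploid <= 2:
        verdict = "stable aneuploid confined to <=2 chromosomes"
    else:
        verdict = "stable complex aneuploid"
    return KaryotypeReport(strain=strains[0], calls=calls, verdict=verdict,
                           alpha=alpha, correction=correction)
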