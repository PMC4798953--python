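"""Distribution diagnostics for log2-ratio gene sets.

If expression scales with copy number, the log2 ratios of genes on an
amplified chromosome form a Gaussian centered at log2(c/P) with no skew;
widespread dosage compensation would instead produce a left-shifted, left-
skewed mixture.  This module provides the diagnostics that distinguish the
two: fixed-width histograms, least-squares Gaussian fits with R², moments
(including adjusted Fisher–Pearson skewness), symmetric SD-outlier counts,
and the closed-form two-component compensated mixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import GaussianFitError, InsufficientDataError, ValidationError


@dataclass
class Histogram:
    """Half-open bins [m*h, (m+1)*h) anchored at zero."""
    edges: np.ndarray      # length n_bins + 1
    counts: np.ndarray     # length n_bins
    bin_width: float

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0


@dataclass
class GaussianFit:
    mean: float
    sd: float
    amplitude: float
    r_squared: float


@dataclass
class Moments:
    n: int
    mean: float
    median: float
    sd: float
    skewness: float          # NaN when undefined
    skewness_defined: bool


@dataclass
class DistributionSummary:
    """All Fig-3-style diagnostics for one gene set."""
    moments: Moments
    histogram: Histogram
    gaussian: GaussianFit | None
    n_below: int
    n_above: int
    outlier_k: float


def histogram(values, bin_width: float = 0.2) -> Histogram:
    """Bin values into half-open bins [m*h, (m+1)*h) anchored at 0."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValidationError("histogram needs at least one finite value")
    if not bin_width > 0:
        raise ValidationError("bin_width must be > 0")
    idx = np.floor(v / bin_width).astype(int)
    lo, hi = idx.min(), idx.max()
    counts = np.bincount(idx - lo, minlength=hi - lo + 1)
    edges = np.arange(lo, hi + 2) * bin_width
    return Histogram(edges=edges, counts=counts, bin_width=bin_width)


def _gauss(x, amplitude, mean, sd):
    return amplitude * np.exp(-0.5 * ((x - mean) / sd) ** 2)


def fit_gaussian(hist: Histogram) -> GaussianFit:
    """Least-squares fit of a scaled Gaussian to bin-center frequencies.

    R² is computed on the frequencies (1 - SS_res / SS_tot), the usual
    goodness-of-fit a curve-fitting package reports for histogram fits.
    """
    x = hist.centers
    y = hist.counts.astype(float)
    if np.count_nonzero(y) < 4:
        raise InsufficientDataError("Gaussian fit needs >= 4 non-empty bins")
    w = y / y.sum()
    mu0 = float((w * x).sum())
    sd0 = float(np.sqrt((w * (x - mu0) ** 2).sum())) or hist.bin_width
    p0 = (float(y.max()), mu0, sd0)
    try:
        popt, _ = optimize.curve_fit(_gauss, x, y, p0=p0, maxfev=10_000)
    except RuntimeError as exc:
        raise GaussianFitError(f"Gaussian fit did not converge: {exc}", p0=p0) from exc
    amplitude, mean, sd = popt
    resid = y - _gauss(x, *popt)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return GaussianFit(mean=float(mean), sd=float(abs(sd)),
                       amplitude=float(amplitude), r_squared=r2)


def moments(values) -> Moments:
    """Mean, median, sample SD (n-1) and adjusted Fisher–Pearson skewness."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise InsufficientDataError("moments need >= 3 values")
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        return Moments(n=v.size, mean=float(v[0]), median=float(v[0]),
                       sd=0.0, skewness=np.nan, skewness_defined=False)
    return Moments(
        n=int(v.size),
        mean=float(np.mean(v)),
        median=float(np.median(v)),
        sd=sd,
        skewness=float(stats.skew(v, bias=False)),
        skewness_defined=True,
    )


def count_sd_outliers(values, k: float = 2.0) -> tuple[int, int]:
    """Counts strictly below/above mean ± k*SD of the same value set."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise InsufficientDataError("outlier counting needs >= 3 values")
    if not k > 0:
        raise ValidationError("k must be > 0")
    mean, sd = float(np.mean(v)), float(np.std(v, ddof=1))
    if sd == 0.0:
        return 0, 0
    return int((v < mean - k * sd).sum()), int((v > mean + k * sd).sum())


def summarize(values, bin_width: float = 0.2, k: float = 2.0) -> DistributionSummary:
    """One-call Fig-3-style summary; the Gaussian fit is None when there are
    too few populated bins."""
    mom = moments(values)
    hist = histogram(values, bin_width)
    try:
        fit = fit_gaussian(hist)
    except (InsufficientDataError, GaussianFitError):
        fit = None
    below, above = count_sd_outliers(values, k)
    return DistributionSummary(moments=mom, histogram=hist, gaussian=fit,
                               n_below=below, n_above=above, outlier_k=k)


# --- theoretical compensated mixture ---------------------------------------


@dataclass
class MixtureSpec:
    """Two-component Gaussian mixture of duplicated-gene RNA log2 ratios:
    a fraction ``f`` of genes compensated down to ``mu_compensated`` while
    the rest sit at ``mu_uncompensated``; components share ``sigma``."""

    fraction: float
    mu_uncompensated: float = 1.0
    mu_compensated: float = 0.0
    sigma: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise ValidationError("fraction must lie in [0, 1]")
        if not self.sigma > 0:
            raise ValidationError("sigma must be > 0")


@dataclass
class MixtureDistribution:
    grid: np.ndarray
    density: np.ndarray
    mean: float
    sd: float
    skewness: float


def mixture_distribution(spec: MixtureSpec, grid=None) -> MixtureDistribution:
    """Density and closed-form moments of the compensated mixture
    ``(1-f) N(mu_unc, sigma) + f N(mu_comp, sigma)``.

    Moments come from the mixture raw moments (normal raw moments
    ``E X = mu``, ``E X² = mu² + sigma²``, ``E X³ = mu³ + 3 mu sigma²``),
    so with compensation (0 < f < 1, mu_comp < mu_unc) the skewness is
    negative — the left shoulder of attenuated genes.
    """
    f, s = spec.fraction, spec.sigma
    mus = np.array([spec.mu_uncompensated, spec.mu_compensated])
    wts = np.array([1.0 - f, f])
    m1 = float((wts * mus).sum())
    m2 = float((wts * (mus ** 2 + s ** 2)).sum())
    m3 = float((wts * (mus ** 3 + 3 * mus * s ** 2)).sum())
    var = m2 - m1 ** 2
    mu3 = m3 - 3 * m1 * m2 + 2 * m1 ** 3
    skew = mu3 / var ** 1.5 if var > 0 else 0.0
    if grid is None:
        lo = mus.min() - 4 * s
        hi = mus.max() + 4 * s
        grid = np.linspace(lo, hi, 512)
    grid = np.asarray(grid, dtype=float)
    density = sum(w * stats.norm.pdf(grid, mu, s) for w, mu in zip(wts, mus))
    return MixtureDistribution(grid=grid, density=np.asarray(density),
                               mean=m1, sd=float(np.sqrt(var)), skewness=float(skew))
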