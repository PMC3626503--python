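"""Somatic mutant allele frequency spectrum (SMAFS) and its tests.

Per-site mutant allele frequencies across the cell population are computed
either by direct haploid counting,

    f = (n_het + 2 n_hom) / (2 n_covered),

or by a maximum-likelihood estimator that marginalizes genotype uncertainty:
each cell contributes sum_g P(obs | g) P(g | f) with Hardy-Weinberg genotype
weights {(1-f)^2, 2f(1-f), f^2} and the ADO/FDR-calibrated genotype
likelihoods of the posterior model.  The spectrum is a 10-bin histogram; a
clonal population shows a peak near 50% frequency on top of the ~c/f decay
expected from neutral expansion, which the hyperbolic goodness-of-fit test
quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .clonal import genotype_likelihood_arrays

BIN_EDGES = np.linspace(0.0, 1.0, 11)
PEAK_BINS = frozenset({4, 5})  # the 40%-60% frequency bins


def count_frequency(genotypes) -> float:
    """Haploid-count frequency of the mutant allele at one site."""
    g = pd.Series(genotypes).astype(str)
    n = len(g)
    if n == 0:
        raise ValueError("no covered cells at site")
    n_het = int((g == "NC").sum())
    n_hom = int((g == "CC").sum())
    return (n_het + 2 * n_hom) / (2.0 * n)


def _site_loglik(freqs: np.ndarray, lik: np.ndarray) -> np.ndarray:
    """Log-likelihood of candidate frequencies given per-cell genotype liks."""
    f = freqs[:, None]
    hw = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f ** 2], axis=-1)[:, 0, :]
    mix = hw @ lik.T  # (n_freqs, n_cells)
    return np.log(np.clip(mix, 1e-300, None)).sum(axis=1)


def ml_frequency(site_obs: pd.DataFrame, rates, grid: float = 1e-3) -> float:
    """Maximum-likelihood site frequency marginalizing genotype calls.

    ``site_obs`` holds one row per covered cell (columns genotype, mut_reads,
    depth).  Grid search at ``grid`` resolution with local refinement.
    """
    if len(site_obs) == 0:
        raise ValueError("no covered cells at site")
    lik = genotype_likelihood_arrays(
        site_obs.genotype.astype(str).to_numpy(),
        site_obs.mut_reads.to_numpy(), site_obs.depth.to_numpy(), rates)
    fgrid = np.arange(0.0, 1.0 + grid / 2, grid)
    ll = _site_loglik(fgrid, lik)
    best = fgrid[int(np.argmax(ll))]
    lo, hi = max(0.0, best - grid), min(1.0, best + grid)
    res = optimize.minimize_scalar(
        lambda f: -_site_loglik(np.array([f]), lik)[0],
        bounds=(lo, hi), method="bounded",
        options={"xatol": grid * 1e-3})
    return float(res.x)


@dataclass
class Spectrum:
    """10-bin frequency histogram, optionally stratified by class."""

    counts: np.ndarray
    by_class: dict = field(default_factory=dict)
    bin_edges: np.ndarray = field(default_factory=lambda: BIN_EDGES.copy())

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "bin_low": self.bin_edges[:-1], "bin_high": self.bin_edges[1:],
            "count": self.counts.astype(int)})
        for cls, c in self.by_class.items():
            df[cls] = c.astype(int)
        return df


def build_spectrum(frequencies, classes=None) -> Spectrum:
    """Bin frequencies into the 10-column spectrum (left-closed bins, the
    final bin closed so f = 1 is counted)."""
    f = np.asarray(frequencies, dtype=float)
    if f.size and (f.min() < 0 or f.max() > 1):
        raise ValueError("frequencies outside [0, 1]")
    counts, _ = np.histogram(f, bins=BIN_EDGES)
    by_class = {}
    if classes is not None:
        cls = np.asarray(classes)
        for c in pd.unique(cls):
            by_class[str(c)], _ = np.histogram(f[cls == c], bins=BIN_EDGES)
    return Spectrum(counts=counts, by_class=by_class)


@dataclass
class HyperbolicFit:
    scale: float
    intercept: float
    expected: np.ndarray
    chi2: float
    pvalue: float
    peak_excess: bool
    exclude_bins: tuple


def fit_hyperbolic(spectrum: Spectrum, exclude_bins=PEAK_BINS,
                   with_intercept: bool = False) -> HyperbolicFit:
    """Minimum-chi-square fit of expected bin counts c/f (optionally c/f + d).

    The scale is fitted on the non-excluded bins (by default the 40-60%
    clonal-peak bins are excluded) but the Pearson goodness-of-fit statistic
    and p-value are computed over all bins, so a clonal peak shows up as a
    poor fit.  ``peak_excess`` flags observed > 3x fitted in the peak bins.
    """
    obs = spectrum.counts.astype(float)
    if obs.sum() == 0:
        raise ValueError("degenerate all-zero spectrum")
    mids = (spectrum.bin_edges[:-1] + spectrum.bin_edges[1:]) / 2.0
    fit_mask = np.array([i not in exclude_bins for i in range(len(obs))])
    if (obs[fit_mask] > 0).sum() < 3:
        raise ValueError("need >= 3 non-excluded bins with counts")

    def chi2_of(params):
        c = params[0]
        d = params[1] if with_intercept else 0.0
        e = np.clip(c / mids + d, 1e-9, None)
        return float((((obs - e) ** 2) / e)[fit_mask].sum())

    c0 = max(obs[fit_mask].sum() / (1.0 / mids[fit_mask]).sum(), 1e-6)
    if with_intercept:
        res = optimize.minimize(chi2_of, x0=[c0, 0.0], method="Nelder-Mead")
        c, d = float(res.x[0]), float(res.x[1])
        n_params = 2
    else:
        res = optimize.minimize_scalar(lambda c: chi2_of([c]),
                                       bounds=(1e-9, max(10 * c0, 1.0)),
                                       method="bounded")
        c, d = float(res.x), 0.0
        n_params = 1
    expected = np.clip(c / mids + d, 1e-9, None)
    stat = float(((obs - expected) ** 2 / expected).sum())
    dof = max(len(obs) - 1 - n_params, 1)
    p = float(stats.chi2.sf(stat, dof))
    peak = bool(any(obs[i] > 3.0 * expected[i] for i in exclude_bins
                    if i < len(obs)))
    return HyperbolicFit(scale=c, intercept=d, expected=expected, chi2=stat,
                         pvalue=p, peak_excess=peak,
                         exclude_bins=tuple(sorted(exclude_bins)))


def test_ns_shift(ns_freqs, s_freqs, cutoff: float = 0.1,
                  exclude_peak: bool = False,
                  two_sided: bool = False) -> tuple[float, np.ndarray]:
    """Fisher exact test for nonsynonymous excess above the cutoff frequency.

    One-sided in the direction of NS enrichment unless ``two_sided``.  With
    ``exclude_peak`` the 40-60% clonal-peak frequencies are dropped first.
    """
    ns = np.asarray(ns_freqs, dtype=float)
    s = np.asarray(s_freqs, dtype=float)
    if exclude_peak:
        ns = ns[(ns < 0.4) | (ns >= 0.6)]
        s = s[(s < 0.4) | (s >= 0.6)]
    if ns.size == 0 or s.size == 0:
        raise ValueError("both mutation classes must be nonempty")
    table = np.array([[int((ns > cutoff).sum()), int((ns <= cutoff).sum())],
                      [int((s > cutoff).sum()), int((s <= cutoff).sum())]])
    alt = "two-sided" if two_sided else "greater"
    _, p = stats.fisher_exact(table, alternative=alt)
    return float(p), table


def correlate_with_bulk(cell_freqs, bulk_freqs) -> float:
    """Coefficient of determination between cell-count and bulk-read
    frequencies over paired sites."""
    x = np.asarray(cell_freqs, dtype=float)
    y = np.asarray(bulk_freqs, dtype=float)
    if x.size != y.size:
        raise ValueError("paired sites required")
    if x.size < 3:
        raise ValueError("need >= 3 paired sites")
    res = stats.linregress(x, y)
    return float(res.rvalue ** 2)
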