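"""First-principles windowed population-genetic statistics.

Implements the per-site and per-window estimators used by the sweep scan:

* nucleotide diversity π (unbiased pairwise-difference form),
* Watterson's θ_W,
* Tajima's D,
* Weir & Cockerham's (1984) two-population F_ST via the a/b/c variance
  components, windowed as the ratio-of-sums Σa / Σ(a+b+c),
* Nei's absolute divergence d_XY.

All window statistics are reported per bp of window by default (per-SNP mode
is available for π); undefined quantities are NaN, never silently 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variants import PopulationMap, SiteAlleleCounts, VariantTable, allele_counts

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Window:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"degenerate window {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def make_windows(chrom_lengths: dict[str, int], size: int, step: int | None = None
                 ) -> list[Window]:
    """Tile chromosomes with windows of ``size`` bp every ``step`` bp.

    Tiling starts at position 1; the last window is truncated at the
    chromosome end.  ``step == size`` (the default) gives a non-overlapping
    tiling.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    step = size if step is None else step
    if step <= 0 or step > size:
        raise ValueError("require 0 < step <= size")
    windows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        start = 1
        while start <= length:
            windows.append(Window(chrom, start, min(start + size - 1, length)))
            start += step
    return windows


def site_pi(n: int, c: int) -> float:
    """Per-site nucleotide diversity 2·c·(n−c)/(n·(n−1)).

    Equals the fraction of distinct haplotype pairs that differ at the site
    when ``c`` of ``n`` sampled alleles carry the alternate base.  Undefined
    (NaN) for n < 2.
    """
    if n < 2:
        return math.nan
    return 2.0 * c * (n - c) / (n * (n - 1.0))


def _site_pi_vec(n: np.ndarray, c: np.ndarray) -> np.ndarray:
    n = n.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * c * (n - c) / (n * (n - 1.0))
    return np.where(n >= 2, pi, np.nan)


def window_pi(site_pis: Sequence[float] | np.ndarray, window: Window,
              denominator: str = "bp") -> float:
    """Sum per-site π over a window, per bp (default) or per SNP."""
    vals = np.asarray(site_pis, dtype=float)
    vals = vals[~np.isnan(vals)]
    if denominator == "bp":
        return float(vals.sum() / window.length)
    if denominator == "snp":
        return float(vals.mean()) if len(vals) else 0.0
    raise ValueError("denominator must be 'bp' or 'snp'")


@lru_cache(maxsize=None)
def tajima_constants(n: int):
    """Tajima's (1989) normalising constants for ``n`` sampled alleles."""
    if n < 4:
        raise ValueError("Tajima's D requires at least 4 sampled alleles")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def watterson_theta(S: int, n: int, L: float) -> float:
    """Watterson's estimator (S/a1)/L per bp; 0 when S == 0."""
    if n < 2:
        return math.nan
    if S == 0:
        return 0.0
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    return S / a1 / L


def tajimas_d(S: int, pi_sum: float, n: int) -> float:
    """Tajima's D from segregating sites and summed per-site π.

    D contrasts the pairwise-difference estimate of θ (``pi_sum``) with the
    segregating-site estimate S/a1; negative values indicate an excess of
    rare variants (sweeps, expansion), positive an excess of intermediate
    frequencies.  Undefined (NaN) when S == 0; raises for n < 4.  D is
    scale-free: it does not depend on window length.
    """
    k = tajima_constants(n)
    if S == 0:
        return math.nan
    var = k["e1"] * S + k["e2"] * S * (S - 1.0)
    return (pi_sum - S / k["a1"]) / math.sqrt(var)


def wc_fst_site(n1: int, p1: float, h1: float, n2: int, p2: float, h2: float
                ) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) variance components for one site, two pops.

    Parameters are per-population called *individual* counts ``n_i``,
    alternate-allele frequencies ``p_i`` and observed heterozygote
    proportions ``h_i``.  Returns the among-population (a), among-individual
    (b) and within-individual (c) components; the site-wise estimate is
    a/(a+b+c) and windows use the ratio of sums.  Sites where both
    populations are fixed for the same allele yield (0, 0, 0) and contribute
    nothing.
    """
    r = 2.0
    if n1 < 1 or n2 < 1:
        raise ValueError("each population needs at least one called individual")
    nbar = (n1 + n2) / r
    if nbar <= 1.0:
        raise ValueError("Weir-Cockerham components undefined for nbar <= 1")
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1.0))
        * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
        - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def _wc_components_vec(n1, p1, h1, n2, p2, h2):
    """Vectorised Weir-Cockerham components; NaN where undefined."""
    r = 2.0
    n1 = n1.astype(float)
    n2 = n2.astype(float)
    nbar = (n1 + n2) / r
    ok = (n1 >= 1) & (n2 >= 1) & (nbar > 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
    nan = np.full_like(nbar, np.nan)
    return (np.where(ok, a, nan), np.where(ok, b, nan), np.where(ok, c, nan))


def wc_fst_window(components: Iterable[tuple[float, float, float]]) -> float:
    """Weighted (ratio-of-sums) F_ST over site components.

    Sites with a+b+c == 0 contribute nothing; NaN when no site contributes.
    The estimator may be negative and is reported raw.
    """
    num = 0.0
    den = 0.0
    for a, b, c in components:
        tot = a + b + c
        if tot == 0.0 or math.isnan(tot):
            continue
        num += a
        den += tot
    if den == 0.0:
        return math.nan
    return num / den


def dxy_site(p1: float, p2: float) -> float:
    """Per-site absolute divergence p1(1−p2) + p2(1−p1).

    The probability that one allele drawn from each population differs;
    symmetric and bounded in [0, 1].
    """
    return p1 * (1.0 - p2) + p2 * (1.0 - p1)


def dxy_window(p1s: Sequence[float], p2s: Sequence[float], window: Window) -> float:
    """Sum of per-site d_XY over a window, per bp of window."""
    p1s = np.asarray(p1s, dtype=float)
    p2s = np.asarray(p2s, dtype=float)
    vals = p1s * (1.0 - p2s) + p2s * (1.0 - p1s)
    vals = vals[~np.isnan(vals)]
    return float(vals.sum() / window.length)


def window_stats(table: VariantTable, popmap: PopulationMap,
                 windows: Sequence[Window], *,
                 pop_pair: tuple[str, str] | None = None,
                 pi_denominator: str = "bp",
                 clamp_negative_fst: bool = False) -> pd.DataFrame:
    """Compute the full per-window statistic set for a two-population panel.

    For each window and population: segregating-site count S, π, θ_W and
    Tajima's D (with n fixed at twice the population sample count); for the
    population pair: weighted Weir-Cockerham F_ST and per-bp d_XY.  Sites
    where either population has fewer than one called diploid individual are
    excluded from F_ST/d_XY but still contribute to the other population's π.

    Returns a DataFrame with one row per window; undefined statistics are
    NaN.
    """
    pops = list(pop_pair) if pop_pair else popmap.populations
    if len(pops) != 2:
        raise ValueError("window_stats requires exactly two populations")
    counts = allele_counts(table, popmap)
    for pop in pops:
        if pop not in counts.n:
            raise ValueError(f"population {pop!r} absent from population map")
        if len(popmap.samples_for(pop)) < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 samples")

    pA, pB = pops
    nA, nB = counts.n[pA], counts.n[pB]
    cA, cB = counts.alt[pA], counts.alt[pB]
    with np.errstate(divide="ignore", invalid="ignore"):
        freqA = np.where(nA > 0, cA / np.maximum(nA, 1), np.nan)
        freqB = np.where(nB > 0, cB / np.maximum(nB, 1), np.nan)
        hA = np.where(counts.n_ind[pA] > 0,
                      counts.het[pA] / np.maximum(counts.n_ind[pA], 1), np.nan)
        hB = np.where(counts.n_ind[pB] > 0,
                      counts.het[pB] / np.maximum(counts.n_ind[pB], 1), np.nan)
    piA = _site_pi_vec(nA, cA)
    piB = _site_pi_vec(nB, cB)
    segA = (cA > 0) & (cA < nA)
    segB = (cB > 0) & (cB < nB)
    a_comp, b_comp, c_comp = _wc_components_vec(
        counts.n_ind[pA], freqA, hA, counts.n_ind[pB], freqB, hB)
    pair_ok = (nA >= 2) & (nB >= 2)
    dxy_vals = np.where(pair_ok, freqA * (1 - freqB) + freqB * (1 - freqA), np.nan)

    chrom_arr = table.sites["chrom"].to_numpy()
    pos_arr = table.sites["pos"].to_numpy()
    n_hapA = 2 * len(popmap.samples_for(pA))
    n_hapB = 2 * len(popmap.samples_for(pB))

    rows = []
    for w in windows:
        in_w = (chrom_arr == w.chrom) & (pos_arr >= w.start) & (pos_arr <= w.end)
        idx = np.flatnonzero(in_w)
        row: dict = {"chrom": w.chrom, "start": w.start, "end": w.end,
                     "n_snps": len(idx)}
        for pop, pi_vals, seg, n_hap in ((pA, piA, segA, n_hapA),
                                         (pB, piB, segB, n_hapB)):
            pv = pi_vals[idx]
            pv = pv[~np.isnan(pv)]
            S = int(seg[idx].sum())
            pi_sum = float(pv.sum())
            if pi_denominator == "bp":
                row[f"pi_{pop}"] = pi_sum / w.length
            else:
                row[f"pi_{pop}"] = float(pv.mean()) if len(pv) else 0.0
            row[f"S_{pop}"] = S
            row[f"theta_w_{pop}"] = watterson_theta(S, n_hap, w.length)
            row[f"tajima_d_{pop}"] = (tajimas_d(S, pi_sum, n_hap)
                                      if n_hap >= 4 else math.nan)
        tot = a_comp[idx] + b_comp[idx] + c_comp[idx]
        contrib = ~np.isnan(tot) & (tot != 0.0)
        fst_num = float(a_comp[idx][contrib].sum())
        fst_den = float(tot[contrib].sum())
        fst = fst_num / fst_den if fst_den != 0.0 else math.nan
        if clamp_negative_fst and not math.isnan(fst):
            fst = max(fst, 0.0)
        row["fst_num"] = fst_num
        row["fst_den"] = fst_den
        row["fst"] = fst
        dv = dxy_vals[idx]
        dv = dv[~np.isnan(dv)]
        row["dxy"] = float(dv.sum() / w.length)
        rows.append(row)
    return pd.DataFrame(rows)


def genome_fst(table: VariantTable, popmap: PopulationMap,
               pop_pair: tuple[str, str] | None = None) -> float:
    """Genome-wide weighted Weir-Cockerham F_ST over all sites."""
    pops = list(pop_pair) if pop_pair else popmap.populations
    if len(pops) != 2:
        raise ValueError("genome_fst requires exactly two populations")
    counts = allele_counts(table, popmap)
    pA, pB = pops
    with np.errstate(divide="ignore", invalid="ignore"):
        freqA = counts.alt[pA] / np.maximum(counts.n[pA], 1)
        freqB = counts.alt[pB] / np.maximum(counts.n[pB], 1)
        hA = counts.het[pA] / np.maximum(counts.n_ind[pA], 1)
        hB = counts.het[pB] / np.maximum(counts.n_ind[pB], 1)
    a, b, c = _wc_components_vec(counts.n_ind[pA], freqA, hA,
                                 counts.n_ind[pB], freqB, hB)
    tot = a + b + c
    contrib = ~np.isnan(tot) & (tot != 0.0)
    den = float(tot[contrib].sum())
    if den == 0.0:
        return math.nan
    return float(a[contrib].sum() / den)
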