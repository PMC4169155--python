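"""Windowed population-genetic summary statistics.

Estimators are missing-data aware: every per-site term uses that site's own
valid (non-N) sample size ``n_i``.  Diversity (θπ), Watterson's θW and
divergence to the outgroup (Dxy) are reported per site; Tajima's D uses the
window totals.  FST between two samples follows the normalized-heterozygosity
form FST = (H_B − H̄_W) / H_B with H_B the mean between-population pairwise
difference and H̄_W the mean of the two within-population diversities,
aggregated over the window.

Sites with status ``excluded`` or ``multiallelic`` never contribute; they are
removed from both numerators and the valid-site count L_valid.  Monomorphic
sites contribute 0 to numerators and 1 to L_valid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alignment import (
    AlignedSampleSet,
    OutgroupSequence,
    SiteFilterConfig,
    SiteRecord,
    WindowInterval,
    iter_windows,
    site_table,
)

USABLE = ("monomorphic", "biallelic")


@dataclass
class WindowStats:
    interval: WindowInterval
    theta_pi: float
    theta_w: float
    dxy: float
    tajima_d: float  # NaN when undefined (no segregating sites)
    n_valid_sites: int
    n_seg_sites: int
    low_confidence: bool = False


@dataclass
class PairwiseFstRecord:
    interval: WindowInterval
    pop_a: str
    pop_b: str
    fst: float  # NaN when H_B == 0
    clipped: bool = False  # True when the raw value was negative


def harmonic(m: int) -> float:
    """a(m) = sum_{k=1}^{m-1} 1/k."""
    return sum(1.0 / k for k in range(1, m))


def _pop_counts(rec: SiteRecord, pop: str) -> tuple[dict[str, int], int]:
    counts = rec.allele_counts.get(pop, {})
    return counts, rec.n_valid.get(pop, 0)


def _minor_count(counts: dict[str, int]) -> tuple[int, int]:
    """(minor allele count, total) for a site with <= 2 observed alleles."""
    vals = sorted(counts.values())
    total = sum(vals)
    if len(vals) <= 1:
        return 0, total
    return vals[0], total


def theta_pi_window(
    sites: Sequence[SiteRecord], pop: str, extra_invariant_sites: int = 0
) -> tuple[float, int]:
    """Per-site nucleotide diversity; returns (θπ, L_valid).

    π_i = 2 x (n_i − x) / (n_i (n_i − 1)) per site; sites with fewer than two
    valid calls are dropped from L_valid.  ``extra_invariant_sites`` lets
    simulated variant-only data account for monomorphic positions.
    """
    total = 0.0
    l_valid = extra_invariant_sites
    for rec in sites:
        if rec.status not in USABLE:
            continue
        counts, n_i = _pop_counts(rec, pop)
        if n_i < 2:
            continue
        l_valid += 1
        x, _ = _minor_count(counts)
        if x > 0:
            total += 2.0 * x * (n_i - x) / (n_i * (n_i - 1))
    if l_valid == 0:
        return math.nan, 0
    return total / l_valid, l_valid


def theta_w_window(
    sites: Sequence[SiteRecord], pop: str, extra_invariant_sites: int = 0
) -> tuple[float, int]:
    """Watterson's estimator with each site's own valid sample size."""
    total = 0.0
    l_valid = extra_invariant_sites
    for rec in sites:
        if rec.status not in USABLE:
            continue
        counts, n_i = _pop_counts(rec, pop)
        if n_i < 2:
            continue
        l_valid += 1
        x, _ = _minor_count(counts)
        if 0 < x < n_i:
            total += 1.0 / harmonic(n_i)
    if l_valid == 0:
        return math.nan, 0
    return total / l_valid, l_valid


def dxy_window(
    sites: Sequence[SiteRecord], pop: str, extra_invariant_sites: int = 0
) -> tuple[float, int]:
    """Mean per-site divergence of the sample to the outgroup.

    Each site contributes (number of sample alleles differing from the
    outgroup base) / n_i; sites where the outgroup is N are dropped from both
    the numerator and L_valid.  Sites polymorphic within the sample are
    included with fractional weight.
    """
    total = 0.0
    l_valid = extra_invariant_sites
    for rec in sites:
        if rec.status not in USABLE or rec.outgroup_base == "N":
            continue
        counts, n_i = _pop_counts(rec, pop)
        if n_i < 1:
            continue
        l_valid += 1
        diff = sum(c for base, c in counts.items() if base != rec.outgroup_base)
        total += diff / n_i
    if l_valid == 0:
        return math.nan, 0
    return total / l_valid, l_valid


def tajima_constants(n: int) -> dict[str, float]:
    """Standard normalizing constants of the D statistic for sample size n."""
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    a1 = sum(1.0 / k for k in range(1, n))
    a2 = sum(1.0 / k**2 for k in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d_window(
    sites: Sequence[SiteRecord], pop: str, effective_n: str = "median"
) -> float:
    """Tajima's D from window totals Θπ and S.

    Missing data leave no single sample size; the constants use the median
    (default) or mean per-site n_i over the window's segregating sites,
    rounded down.  Returns NaN when S = 0 or the effective n < 4.
    """
    pi_total = 0.0
    seg_n: list[int] = []
    for rec in sites:
        if rec.status not in USABLE:
            continue
        counts, n_i = _pop_counts(rec, pop)
        if n_i < 2:
            continue
        x, _ = _minor_count(counts)
        if 0 < x < n_i:
            seg_n.append(n_i)
            pi_total += 2.0 * x * (n_i - x) / (n_i * (n_i - 1))
    s = len(seg_n)
    if s == 0:
        return math.nan
    if effective_n == "median":
        n_eff = int(np.floor(np.median(seg_n)))
    elif effective_n == "mean":
        n_eff = int(np.floor(np.mean(seg_n)))
    else:
        raise ValueError("effective_n must be 'median' or 'mean'")
    if n_eff < 4:
        return math.nan
    k = tajima_constants(n_eff)
    theta_w_total = s / k["a1"]
    var = k["e1"] * s + k["e2"] * s * (s - 1)
    if var <= 0:
        return math.nan
    return (pi_total - theta_w_total) / math.sqrt(var)


def fst_nei_window(
    sites: Sequence[SiteRecord],
    pop_a: str,
    pop_b: str,
    interval: WindowInterval | None = None,
) -> PairwiseFstRecord:
    """Hudson-style FST = (H_B − H̄_W) / H_B aggregated over the window."""
    hb_total = 0.0
    hw_a_total = 0.0
    hw_b_total = 0.0
    n_sites = 0
    for rec in sites:
        if rec.status not in USABLE:
            continue
        counts_a, n_a = _pop_counts(rec, pop_a)
        counts_b, n_b = _pop_counts(rec, pop_b)
        if n_a < 2 or n_b < 2:
            continue
        n_sites += 1
        bases = set(counts_a) | set(counts_b)
        # mean pairwise difference, one sequence from each population
        p_a = {b: counts_a.get(b, 0) / n_a for b in bases}
        p_b = {b: counts_b.get(b, 0) / n_b for b in bases}
        hb_total += 1.0 - sum(p_a[b] * p_b[b] for b in bases)
        x_a, _ = _minor_count(counts_a)
        x_b, _ = _minor_count(counts_b)
        hw_a_total += 2.0 * x_a * (n_a - x_a) / (n_a * (n_a - 1))
        hw_b_total += 2.0 * x_b * (n_b - x_b) / (n_b * (n_b - 1))
    interval = interval or WindowInterval(
        min((r.coord for r in sites), default=1), max((r.coord for r in sites), default=1)
    )
    if n_sites == 0 or hb_total == 0.0:
        return PairwiseFstRecord(interval, pop_a, pop_b, math.nan)
    hw_mean = 0.5 * (hw_a_total + hw_b_total)
    fst = (hb_total - hw_mean) / hb_total
    return PairwiseFstRecord(interval, pop_a, pop_b, fst, clipped=fst < 0)


def window_statistics(
    sites: Sequence[SiteRecord],
    pop: str,
    interval: WindowInterval,
    effective_n: str = "median",
) -> WindowStats:
    """All single-population statistics for the sites inside one window."""
    in_win = [r for r in sites if interval.contains(r.coord)]
    theta_pi, l_valid = theta_pi_window(in_win, pop)
    theta_w, _ = theta_w_window(in_win, pop)
    dxy, _ = dxy_window(in_win, pop)
    d = tajima_d_window(in_win, pop, effective_n=effective_n)
    n_seg = sum(
        1
        for r in in_win
        if r.status == "biallelic" and 0 < _minor_count(r.allele_counts.get(pop, {}))[0]
    )
    return WindowStats(
        interval=interval,
        theta_pi=theta_pi,
        theta_w=theta_w,
        dxy=dxy,
        tajima_d=d,
        n_valid_sites=l_valid,
        n_seg_sites=n_seg,
        low_confidence=l_valid < 0.5 * interval.length,
    )


def scan_alignment(
    aln: AlignedSampleSet,
    outgroup: OutgroupSequence | None,
    cfg: SiteFilterConfig,
    window_len: int = 2000,
    pop: str | None = None,
) -> list[WindowStats]:
    """Classify sites then compute window statistics along the alignment."""
    pop = pop or aln.population[0]
    sites = site_table(aln, outgroup, cfg)
    return [window_statistics(sites, pop, w) for w in iter_windows(aln, window_len)]
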