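"""Site frequency spectra: construction, projection and the sweep transform.

A spectrum over derived-allele classes is the object the composite
likelihood machinery manipulates.  Classes run 1..n−1 for an ordinary
(polymorphic-only) spectrum; an *extended* spectrum additionally carries the
invariant classes 0 and n.  In the scan these extra classes hold sites that
are monomorphic in the focal (European) sample but polymorphic in a
reference (Rwandan) sample — exactly the sites a recent sweep converts from
polymorphic to invariant, which is why carrying them boosts power.

The sweep transform implements the classic star-like sweep approximation:
each of the n sampled lineages escapes the sweeping haplotype independently
with probability p_e (p_e = 1 − exp(−α·d) at distance d from the sweep for
intensity α); the lineages that do not escape coalesce into a single
ancestral lineage, so a pre-sweep sample of B escapees has effective size
B + 1, whose derived-allele count follows the background spectrum projected
down by hypergeometric sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import binom, hypergeom

from .alignment import SiteRecord

_SUM_TOL = 1e-9


@dataclass
class SFSpectrum:
    """Probability per derived-allele class for haploid sample size n.

    ``probs`` always has length n+1 (classes 0..n); a non-extended spectrum
    has zero mass at classes 0 and n.  ``n_sites`` records how many sites the
    probabilities were estimated from (needed when the spectrum is later
    extended with invariant-class counts).
    """

    n: int
    probs: np.ndarray
    extended: bool = False
    source: str = ""
    n_sites: int = 0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (self.n + 1,):
            raise ValueError(f"probs must have length n+1={self.n + 1}")
        if np.any(self.probs < -1e-15):
            raise ValueError("spectrum probabilities must be non-negative")
        self.probs = np.clip(self.probs, 0.0, None)
        total = self.probs.sum()
        if not np.isclose(total, 1.0, atol=_SUM_TOL):
            raise ValueError(f"spectrum probabilities must sum to 1 (got {total})")
        if not self.extended and (self.probs[0] > 0 or self.probs[self.n] > 0):
            raise ValueError("non-extended spectrum cannot carry classes 0 or n")

    @classmethod
    def from_class_dict(
        cls, n: int, classes: dict[int, float], extended: bool = False, **kw
    ) -> "SFSpectrum":
        probs = np.zeros(n + 1)
        for j, p in classes.items():
            probs[j] = p
        probs /= probs.sum()
        return cls(n, probs, extended=extended, **kw)

    @classmethod
    def neutral(cls, n: int) -> "SFSpectrum":
        """Standard neutral polymorphic spectrum, p(j) ∝ 1/j."""
        probs = np.zeros(n + 1)
        probs[1:n] = 1.0 / np.arange(1, n)
        probs /= probs.sum()
        return cls(n, probs, extended=False, source="neutral")


def projection_matrix(n: int, m: int) -> np.ndarray:
    """Hypergeometric projection: entry (i, j) = P(i derived in m | j in n)."""
    i = np.arange(m + 1)[:, None]
    j = np.arange(n + 1)[None, :]
    return hypergeom.pmf(i, n, j, m)


def downsample_sfs(sfs: SFSpectrum, m: int, keep_invariant: bool | None = None) -> SFSpectrum:
    """Project a spectrum to a smaller sample size m.

    q_m(i) = Σ_j p_n(j) · H(i; m, j, n).  For a non-extended spectrum the
    projected mass falling on classes 0 and m is dropped and the rest
    renormalized; an extended spectrum keeps all classes.
    """
    if not 1 <= m <= sfs.n:
        raise ValueError(f"target size m={m} must lie in [1, n={sfs.n}]")
    keep = sfs.extended if keep_invariant is None else keep_invariant
    q = projection_matrix(sfs.n, m) @ sfs.probs
    if not keep:
        q[0] = 0.0
        q[m] = 0.0
    total = q.sum()
    if total <= 0:
        raise ValueError("projection left no probability mass")
    return SFSpectrum(m, q / total, extended=keep, source=sfs.source, n_sites=sfs.n_sites)


def derived_count(rec: SiteRecord) -> int | None:
    """Pooled derived-allele count, polarized by the outgroup base.

    Returns None when the site cannot be polarized (outgroup N, or outgroup
    base matching neither observed allele).
    """
    if rec.outgroup_base == "N":
        return None
    pooled = rec.pooled_counts
    if rec.outgroup_base not in pooled and rec.status != "monomorphic":
        return None
    if rec.status == "monomorphic":
        if not pooled:
            return None
        (base, count), = pooled.items()
        return 0 if base == rec.outgroup_base else count
    return sum(c for b, c in pooled.items() if b != rec.outgroup_base)


def build_sfs(
    sites: Sequence[SiteRecord],
    target_n: int,
    extended: bool = False,
    source: str = "background",
) -> tuple[SFSpectrum, dict[str, int]]:
    """Polarized sample frequency spectrum from classified sites.

    Sites with valid sample size above ``target_n`` are projected down by
    hypergeometric sampling; smaller sites are dropped.  A non-extended
    spectrum keeps only classes 1..n−1 (projection mass reaching the
    invariant classes is discarded before normalization).  Diagnostics count
    polarization failures and drops.
    """
    counts = np.zeros(target_n + 1)
    diag = {"used": 0, "polarization_failed": 0, "too_small": 0, "skipped": 0}
    proj_cache: dict[int, np.ndarray] = {}
    for rec in sites:
        if rec.status in ("excluded", "multiallelic"):
            diag["skipped"] += 1
            continue
        if rec.status == "monomorphic" and not extended:
            diag["skipped"] += 1
            continue
        n_i = sum(rec.n_valid.values())
        if n_i < target_n:
            diag["too_small"] += 1
            continue
        j = derived_count(rec)
        if j is None:
            diag["polarization_failed"] += 1
            continue
        if n_i == target_n:
            counts[j] += 1.0
        else:
            if n_i not in proj_cache:
                proj_cache[n_i] = projection_matrix(n_i, target_n)
            counts += proj_cache[n_i][:, j]
        diag["used"] += 1
    if not extended:
        counts[0] = 0.0
        counts[target_n] = 0.0
    total = counts.sum()
    if total <= 0:
        raise ValueError("no usable sites for spectrum construction")
    return (
        SFSpectrum(target_n, counts / total, extended=extended, source=source,
                   n_sites=diag["used"]),
        diag,
    )


def _is_polymorphic(rec: SiteRecord) -> bool:
    return rec.status == "biallelic"


def extend_sfs_invariant_classes(
    sfs: SFSpectrum,
    focal_sites: Sequence[SiteRecord] | None,
    reference_sites: Sequence[SiteRecord] | None,
) -> SFSpectrum:
    """Add invariant classes 0 and n from reference-conditioned sites.

    Classes 0 (monomorphic ancestral in the focal sample) and n (monomorphic
    derived) are populated ONLY by sites monomorphic in the focal sample and
    polymorphic in the reference sample, per coordinate match.  Without a
    reference the input is returned unchanged.
    """
    if reference_sites is None or focal_sites is None:
        return sfs
    ref_poly = {rec.coord for rec in reference_sites if _is_polymorphic(rec)}
    c0 = 0
    cn = 0
    for rec in focal_sites:
        if rec.status != "monomorphic" or rec.coord not in ref_poly:
            continue
        j = derived_count(rec)
        if j is None:
            continue
        if j == 0:
            c0 += 1
        else:
            cn += 1
    if c0 == 0 and cn == 0:
        warnings.warn("no qualifying invariant sites; extended classes have zero mass")
    n_poly = max(sfs.n_sites, 1)
    counts = sfs.probs * n_poly
    counts[0] += c0
    counts[sfs.n] += cn
    return SFSpectrum(
        sfs.n, counts / counts.sum(), extended=True, source=sfs.source,
        n_sites=n_poly + c0 + cn,
    )


class SweepTransform:
    """Cached sweep-spectrum transform for one extended background spectrum.

    ``spectrum_at(p_escape)`` returns the expected post-sweep class
    probabilities; ``matrix(pe_array)`` evaluates many escape probabilities
    at once (used by the scan's interpolation table).
    """

    def __init__(self, bg: SFSpectrum):
        if not bg.extended:
            raise ValueError("sweep transform requires an extended background spectrum")
        self.bg = bg
        n = bg.n
        # per pre-sweep size m = B+1: projected spectrum and the two
        # deterministic redistribution vectors (representative derived / not)
        self._contrib = np.zeros((n + 1, n + 1))  # row B -> class distribution
        for b in range(n):
            m = b + 1
            q = projection_matrix(n, m) @ bg.probs  # length m+1, invariant kept
            row = np.zeros(n + 1)
            for i in range(m + 1):
                if q[i] <= 0:
                    continue
                p_rep = i / m
                if p_rep > 0:
                    row[i - 1 + n - b] += q[i] * p_rep
                if p_rep < 1:
                    row[i] += q[i] * (1 - p_rep)
            self._contrib[b] = row
        self._contrib[n] = bg.probs

    def matrix(self, pe: np.ndarray) -> np.ndarray:
        """Post-sweep spectra, one row per escape probability."""
        pe = np.asarray(pe, dtype=float)
        n = self.bg.n
        w = binom.pmf(np.arange(n + 1)[None, :], n, pe[:, None])  # (P, n+1)
        out = w @ self._contrib
        return out / out.sum(axis=1, keepdims=True)

    def spectrum_at(self, p_escape: float) -> SFSpectrum:
        if not 0.0 <= p_escape <= 1.0:
            raise ValueError("p_escape must lie in [0, 1]")
        probs = self.matrix(np.array([p_escape]))[0]
        return SFSpectrum(self.bg.n, probs, extended=True, source="sweep")


def sweep_transform_sfs(bg: SFSpectrum, p_escape: float) -> SFSpectrum:
    """Expected post-sweep spectrum for lineage escape probability p_escape."""
    return SweepTransform(bg).spectrum_at(p_escape)


def write_sfs_text(sfs: SFSpectrum, path) -> None:
    """Write a spectrum as two-column text (class, probability)."""
    with open(path, "w") as fh:
        for j, p in enumerate(sfs.probs):
            if p > 0 or (sfs.extended and j in (0, sfs.n)):
                fh.write(f"{j}\t{p:.12g}\n")


def read_sfs_text(path, n: int | None = None, source: str = "background") -> SFSpectrum:
    """Read a two-column (class, probability) spectrum file.

    The sample size defaults to the largest class listed; the spectrum is
    extended iff class 0 or n carries probability.
    """
    classes: dict[int, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            j, p = line.split()
            classes[int(j)] = float(p)
    if not classes:
        raise ValueError(f"no spectrum classes in {path}")
    n = n if n is not None else max(classes)
    extended = classes.get(0, 0.0) > 0 or classes.get(n, 0.0) > 0
    return SFSpectrum.from_class_dict(n, classes, extended=extended, source=source)
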