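"""Per-SNP multi-population differentiation scan and cline regression.

The scan retains biallelic SNPs where every population has at least 50% of
its base calls, computes a global FST per SNP as the normalized
heterozygosity deficit (H_T − H̄_S) / H_T, and flags the empirical upper
quantile as outliers.  A model-based Bayesian decomposition (locus effects
and q-values) is deliberately not reimplemented: the empirical-quantile
flagging is a direct, data-internal replacement, not an equivalence claim.

Latitudinal clines are fitted by ordinary least squares of haplotype or
allele frequency on absolute latitude, separately for the hemispheres north
and south of the equator (two antiparallel clines share an equatorial
anchor).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .alignment import SiteRecord


@dataclass
class SnpPanel:
    """Retained biallelic SNPs with per-population counts.

    ``table`` columns: coord, plus per population ``{pop}_x`` (count of the
    first allele) and ``{pop}_n`` (valid calls).  ``exclusions`` maps reason
    -> count; reasons partition the excluded sites.
    """

    table: pd.DataFrame
    populations: list[str]
    sample_sizes: dict[str, int]
    exclusions: dict[str, int] = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return len(self.table)


@dataclass
class ClineDataset:
    populations: list[str]
    latitude: np.ndarray  # signed degrees
    freq: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.latitude = np.asarray(self.latitude, dtype=float)
        self.freq = np.asarray(self.freq, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if np.any((self.freq < 0) | (self.freq > 1)):
            raise ValueError("frequencies must lie in [0, 1]")


@dataclass
class ClineFit:
    hemisphere: str
    slope: float
    intercept: float
    p_value: float
    n_points: int


def snp_exclusion_filter(
    sites: list[SiteRecord],
    sample_sizes: dict[str, int],
    min_call_frac: float = 0.5,
) -> SnpPanel:
    """Retain biallelic SNPs with >= ``min_call_frac`` calls in every population."""
    pops = list(sample_sizes)
    rows = []
    exclusions = {"multiallelic": 0, "low_calls": 0, "not_polymorphic": 0, "filtered": 0}
    for rec in sites:
        if rec.status == "excluded":
            exclusions["filtered"] += 1
            continue
        if rec.status == "multiallelic":
            exclusions["multiallelic"] += 1
            continue
        if rec.status != "biallelic":
            exclusions["not_polymorphic"] += 1
            continue
        if any(rec.n_valid.get(p, 0) < min_call_frac * sample_sizes[p] for p in pops):
            exclusions["low_calls"] += 1
            continue
        allele = rec.alleles[0]
        row = {"coord": rec.coord}
        for p in pops:
            row[f"{p}_x"] = rec.allele_counts.get(p, {}).get(allele, 0)
            row[f"{p}_n"] = rec.n_valid.get(p, 0)
        rows.append(row)
    table = pd.DataFrame(rows, columns=["coord"] + [f"{p}_{s}" for p in pops for s in ("x", "n")])
    return SnpPanel(table=table, populations=pops, sample_sizes=dict(sample_sizes),
                    exclusions=exclusions)


def per_snp_fst(panel: SnpPanel) -> pd.DataFrame:
    """Global multi-population FST per SNP, (H_T − H̄_S) / H_T.

    H_T is the expected heterozygosity of the sample-size-weighted pooled
    allele frequency; H̄_S the unweighted mean within-population expected
    heterozygosity.  SNPs monomorphic overall get fst = NaN (flagged).
    """
    pops = panel.populations
    x = panel.table[[f"{p}_x" for p in pops]].to_numpy(dtype=float)
    n = panel.table[[f"{p}_n" for p in pops]].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(n > 0, x / n, np.nan)
        p_bar = np.nansum(x, axis=1) / np.nansum(n, axis=1)
        h_t = 2.0 * p_bar * (1.0 - p_bar)
        h_s = np.nanmean(2.0 * freqs * (1.0 - freqs), axis=1)
        fst = np.where(h_t > 0, (h_t - h_s) / np.where(h_t > 0, h_t, 1.0), np.nan)
    out = pd.DataFrame({"coord": panel.table["coord"], "fst": fst})
    out["undefined"] = ~np.isfinite(fst)
    return out


def flag_outliers(records: pd.DataFrame, fdr_quantile: float = 0.05) -> pd.DataFrame:
    """Flag SNPs above the (1 − q) empirical FST quantile (ties inclusive)."""
    out = records.copy()
    finite = out["fst"].to_numpy(dtype=float)
    mask = np.isfinite(finite)
    n_ok = int(mask.sum())
    out["rank_quantile"] = np.nan
    out["outlier"] = False
    if n_ok < 20:
        warnings.warn("fewer than 20 SNPs with defined FST; no outliers flagged")
        return out
    vals = finite[mask]
    ranks = pd.Series(vals).rank(method="average").to_numpy()
    out.loc[mask, "rank_quantile"] = ranks / n_ok
    cutoff = np.quantile(vals, 1.0 - fdr_quantile)
    out.loc[mask, "outlier"] = vals >= cutoff
    return out


def cline_regression(cline: ClineDataset, split_equator: bool = True) -> list[ClineFit]:
    """OLS of frequency on |latitude|, hemisphere-split by default.

    Populations at latitude 0 anchor both hemisphere fits.  Hemispheres with
    fewer than 3 populations are skipped with a warning.  With
    ``split_equator=False`` a single signed-latitude fit is returned.
    """
    fits: list[ClineFit] = []
    if split_equator:
        groups = [
            ("north", cline.latitude >= 0, np.abs(cline.latitude)),
            ("south", cline.latitude <= 0, np.abs(cline.latitude)),
        ]
    else:
        groups = [("joint", np.ones_like(cline.latitude, dtype=bool), cline.latitude)]
    for name, mask, xvals in groups:
        if mask.sum() < 3:
            warnings.warn(f"{name}: fewer than 3 populations; fit skipped")
            continue
        y = cline.freq[mask]
        if np.allclose(y, y.mean(), atol=1e-12):
            # constant frequencies: no cline, not "undefined"
            fits.append(ClineFit(name, 0.0, float(y.mean()), 1.0, int(mask.sum())))
            continue
        x = sm.add_constant(xvals[mask])
        model = sm.OLS(y, x).fit()
        slope = float(model.params[1])
        p_value = float(model.pvalues[1])
        fits.append(
            ClineFit(
                hemisphere=name,
                slope=slope,
                intercept=float(model.params[0]),
                p_value=p_value,
                n_points=int(mask.sum()),
            )
        )
    return fits
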