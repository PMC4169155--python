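"""qPCR relative expression: calibrated normalized relative quantities.

The CNRQ pipeline (after Hellemans' qBase framework) proceeds in three
steps, all on one long-format Cq table:

1. ``cq_to_rq`` — technical replicates are averaged on the Cq scale, then
   relative quantities RQ = E^(ΔCq) are formed against a per-gene calibrator
   group using each gene's own amplification efficiency E;
2. ``normalize_nrq`` — RQs are divided by the geometric mean RQ of the
   reference genes in the same sample (pool), removing loading differences;
3. ``calibrate_cnrq`` — NRQs are rescaled so the calibration group (e.g. the
   tropical-population control) has geometric mean 1 per gene.

Confidence intervals propagate the technical-replicate SD on the log scale.
Contrasts are screened by a fold-change threshold derived from the technical
variance (below it, expression differences are indistinguishable from
pipetting noise and are not tested), then tested with Welch two-sample
t-tests on log CNRQ and corrected by Benjamini-Hochberg.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

GROUP_COLS = ["population", "treatment"]
SAMPLE_COLS = ["gene", "pool_id", "population", "treatment"]


class QpcrDataError(ValueError):
    """Raised on missing efficiencies, calibrators or invalid quantities."""


def _geometric_mean(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise QpcrDataError("geometric mean requires positive values")
    return float(np.exp(np.mean(np.log(values))))


def validate_efficiencies(efficiencies: dict[str, float]) -> None:
    for gene, eff in efficiencies.items():
        if not 1.0 < eff <= 2.0:
            raise QpcrDataError(f"efficiency for {gene} must lie in (1, 2]")


def cq_to_rq(
    cq: pd.DataFrame,
    efficiencies: dict[str, float],
    calibrator: tuple[str, str],
) -> pd.DataFrame:
    """Relative quantities per (gene, pool, treatment).

    Technical replicates are averaged on the Cq scale first; then
    RQ = E^(mean Cq of the calibrator group − sample mean Cq).  The
    calibrator is a (population, treatment) pair that must be present for
    every gene.
    """
    validate_efficiencies(efficiencies)
    missing = set(cq["gene"]) - set(efficiencies)
    if missing:
        raise QpcrDataError(f"no efficiency for genes: {sorted(missing)}")
    agg = (
        cq.groupby(SAMPLE_COLS, as_index=False)
        .agg(cq_mean=("cq", "mean"), cq_sd=("cq", "std"), n_tech=("cq", "size"))
    )
    agg["cq_sd"] = agg["cq_sd"].fillna(0.0)
    out_rows = []
    for gene, sub in agg.groupby("gene"):
        eff = efficiencies[gene]
        cal = sub[(sub["population"] == calibrator[0]) & (sub["treatment"] == calibrator[1])]
        if cal.empty:
            raise QpcrDataError(f"calibrator group {calibrator} absent for gene {gene}")
        cal_mean = float(cal["cq_mean"].mean())
        sub = sub.copy()
        sub["efficiency"] = eff
        sub["rq"] = eff ** (cal_mean - sub["cq_mean"])
        out_rows.append(sub)
    return pd.concat(out_rows, ignore_index=True)


def normalize_nrq(rq: pd.DataFrame, reference_genes: list[str]) -> pd.DataFrame:
    """NRQ = RQ / geometric mean of the reference-gene RQs per sample."""
    refs = [g for g in reference_genes if g in set(rq["gene"])]
    if not refs:
        raise QpcrDataError("no reference gene present in the RQ table")
    ref_table = rq[rq["gene"].isin(refs)]
    divisors = {}
    for pool, sub in ref_table.groupby("pool_id"):
        divisors[pool] = _geometric_mean(sub["rq"].to_numpy())
    out = rq.copy()
    missing = set(out["pool_id"]) - set(divisors)
    if missing:
        raise QpcrDataError(f"pools without reference-gene RQs: {sorted(missing)}")
    out["nrq"] = out.apply(lambda r: r["rq"] / divisors[r["pool_id"]], axis=1)
    return out


def calibrate_cnrq(
    nrq: pd.DataFrame,
    calibration_group: tuple[str, str],
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Rescale NRQs so the calibration group has geometric mean 1 per gene.

    Confidence bounds come from the technical-replicate SD of the mean Cq on
    the log scale (Student t with n_tech − 1 df), rescaled identically.
    """
    out_rows = []
    for gene, sub in nrq.groupby("gene"):
        cal = sub[
            (sub["population"] == calibration_group[0])
            & (sub["treatment"] == calibration_group[1])
        ]
        if cal.empty:
            raise QpcrDataError(f"calibration group {calibration_group} absent for gene {gene}")
        denom = _geometric_mean(cal["nrq"].to_numpy())
        sub = sub.copy()
        sub["cnrq"] = sub["nrq"] / denom
        log2_eff = np.log2(sub["efficiency"].to_numpy())
        se_log2 = sub["cq_sd"].to_numpy() / np.sqrt(sub["n_tech"].to_numpy()) * log2_eff
        dof = np.maximum(sub["n_tech"].to_numpy() - 1, 1)
        tcrit = stats.t.ppf(0.5 + ci_level / 2.0, dof)
        sub["ci_low"] = sub["cnrq"] * 2.0 ** (-tcrit * se_log2)
        sub["ci_high"] = sub["cnrq"] * 2.0 ** (tcrit * se_log2)
        out_rows.append(sub)
    return pd.concat(out_rows, ignore_index=True)


def cnrq_pipeline(
    cq: pd.DataFrame,
    efficiencies: dict[str, float],
    reference_genes: list[str],
    calibrator: tuple[str, str],
) -> pd.DataFrame:
    """Full Cq -> CNRQ conversion (RQ, reference normalization, calibration)."""
    rq = cq_to_rq(cq, efficiencies, calibrator)
    nrq = normalize_nrq(rq, reference_genes)
    return calibrate_cnrq(nrq, calibrator)


def technical_log2_sd(cnrq: pd.DataFrame) -> dict[str, float]:
    """Pooled technical-replicate SD of log2 quantities, per gene."""
    out = {}
    for gene, sub in cnrq.groupby("gene"):
        log2_eff = np.log2(sub["efficiency"].to_numpy())
        sds = sub["cq_sd"].to_numpy() * log2_eff
        out[gene] = float(np.sqrt(np.mean(sds**2)))
    return out


@dataclass
class ContrastResult:
    gene: str
    group_a: tuple[str, str]
    group_b: tuple[str, str]
    log2_fold: float
    screened_in: bool
    p_raw: float = math.nan
    p_adj: float = math.nan
    tier: str = ""


def screen_and_test(
    cnrq: pd.DataFrame,
    contrasts: list[tuple[tuple[str, str], tuple[str, str]]],
    screen_k: float = 2.0,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Fold-change screen then Welch tests with Benjamini-Hochberg correction.

    A contrast is tested only when its |log2 fold difference| exceeds
    ``screen_k`` times the gene's technical log2 SD; untested contrasts are
    reported with screened_in = False.  Adjusted p-values map to display
    tiers * / ** / *** at 0.05 / 0.01 / 0.001.
    """
    tech_sd = technical_log2_sd(cnrq)
    genes = genes or sorted(cnrq["gene"].unique())
    results: list[ContrastResult] = []
    for gene in genes:
        sub = cnrq[cnrq["gene"] == gene]
        threshold = screen_k * tech_sd.get(gene, 0.0)
        for ga, gb in contrasts:
            va = sub[(sub["population"] == ga[0]) & (sub["treatment"] == ga[1])]["cnrq"]
            vb = sub[(sub["population"] == gb[0]) & (sub["treatment"] == gb[1])]["cnrq"]
            if len(va) < 2 or len(vb) < 2:
                warnings.warn(f"contrast {ga} vs {gb} for {gene}: group size < 2, skipped")
                continue
            la = np.log2(va.to_numpy())
            lb = np.log2(vb.to_numpy())
            fold = float(la.mean() - lb.mean())
            if abs(fold) <= threshold:
                results.append(ContrastResult(gene, ga, gb, fold, screened_in=False))
                continue
            t = stats.ttest_ind(la, lb, equal_var=False)
            results.append(
                ContrastResult(gene, ga, gb, fold, screened_in=True, p_raw=float(t.pvalue))
            )
    tested = [r for r in results if r.screened_in]
    if tested:
        adj = multipletests([r.p_raw for r in tested], method="fdr_bh")[1]
        for r, p in zip(tested, adj):
            r.p_adj = float(p)
            r.tier = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "group_a": [f"{r.group_a[0]}-{r.group_a[1]}" for r in results],
            "group_b": [f"{r.group_b[0]}-{r.group_b[1]}" for r in results],
            "log2_fold": [r.log2_fold for r in results],
            "screened_in": [r.screened_in for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
            "tier": [r.tier for r in results],
        }
    )
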