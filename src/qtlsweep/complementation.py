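"""Quantitative complementation tests on chromosomal deletions.

A deficiency (deletion) chromosome is crossed against two candidate X
chromosomes (a temperate "E" and a tropical "A" line); the four resulting
genotype classes (E/def, A/def, E/bal, A/bal) are scored for chill-coma
recovery time (CCRT, whole minutes).  A two-way fixed-effects ANOVA on
log CCRT tests the line effect (L), the genomic-background effect (G,
deletion vs balancer) and their interaction (L × G).  Failure to complement
requires significant L and L × G effects *and* the right direction: the
CCRT difference between lines must be larger over the deletion than over
the balancer, with E/def recovering faster than A/def.

Unbalanced cell counts use Type-II sums of squares; with per-fly raw data
unavailable for published designs, printed P-values are not reproduction
targets — only the decision rule and the delta arithmetic are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

CELLS = [("E", "def"), ("A", "def"), ("E", "bal"), ("A", "bal")]


class DesignError(ValueError):
    """Raised when the 2x2 genotype design is incomplete."""


@dataclass
class ComplementationResult:
    deletion_id: str
    means: dict[tuple[str, str], float]
    sds: dict[tuple[str, str], float]
    delta_def: float
    delta_bal: float
    p_L: float
    p_G: float
    p_LxG: float
    call: str | None = None  # complement | fail_marginal | fail_high
    bonferroni_m: int = 1
    degenerate: bool = False


def two_way_anova_log(obs: pd.DataFrame) -> ComplementationResult:
    """Two-way fixed-effects ANOVA on natural-log CCRT.

    Expects columns line (E/A), background (def/bal), ccrt_minutes and
    optionally deletion_id.  Returns Type-II F-test p-values for L, G and
    L × G plus cell means/SDs on the original minutes scale.
    """
    for cell in CELLS:
        sub = obs[(obs["line"] == cell[0]) & (obs["background"] == cell[1])]
        if len(sub) < 2:
            raise DesignError(f"genotype cell {cell} needs >= 2 observations")
    df = obs.copy()
    df["log_ccrt"] = np.log(df["ccrt_minutes"].astype(float))
    degenerate = df["log_ccrt"].var() == 0
    if degenerate:
        p_l = p_g = p_lxg = np.nan
    else:
        model = smf.ols("log_ccrt ~ C(line) * C(background)", data=df).fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            table = sm.stats.anova_lm(model, typ=2)
        p_l = float(table.loc["C(line)", "PR(>F)"])
        p_g = float(table.loc["C(background)", "PR(>F)"])
        p_lxg = float(table.loc["C(line):C(background)", "PR(>F)"])
    means = {}
    sds = {}
    for line, background in CELLS:
        sub = df[(df["line"] == line) & (df["background"] == background)]["ccrt_minutes"]
        means[(line, background)] = float(sub.mean())
        sds[(line, background)] = float(sub.std(ddof=1))
    d_def, d_bal = deltas(means)
    deletion_id = str(obs["deletion_id"].iloc[0]) if "deletion_id" in obs else "NA"
    return ComplementationResult(
        deletion_id=deletion_id,
        means=means,
        sds=sds,
        delta_def=d_def,
        delta_bal=d_bal,
        p_L=p_l,
        p_G=p_g,
        p_LxG=p_lxg,
        degenerate=degenerate,
    )


def deltas(means: dict[tuple[str, str], float]) -> tuple[float, float]:
    """Δdef = mean(E/def) − mean(A/def); Δbal = mean(E/bal) − mean(A/bal)."""
    d_def = means[("E", "def")] - means[("A", "def")]
    d_bal = means[("E", "bal")] - means[("A", "bal")]
    return d_def, d_bal


def call_complementation(
    res: ComplementationResult,
    alpha: float = 0.05,
    high: float = 0.01,
    m: int = 1,
) -> str:
    """Categorical complementation call with Bonferroni adjustment over m tests.

    ``fail_high``: adjusted p_L and p_LxG both below ``high`` and the
    direction conditions hold (|Δdef| > |Δbal|, Δdef < 0);
    ``fail_marginal``: both below ``alpha`` with direction; else
    ``complement``.
    """
    if np.isnan(res.p_L) or np.isnan(res.p_LxG):
        raise ValueError("p-values must be populated before calling")
    p_l = min(res.p_L * m, 1.0)
    p_lxg = min(res.p_LxG * m, 1.0)
    direction = abs(res.delta_def) > abs(res.delta_bal) and res.delta_def < 0
    if direction and p_l < high and p_lxg < high:
        call = "fail_high"
    elif direction and p_l < alpha and p_lxg < alpha:
        call = "fail_marginal"
    else:
        call = "complement"
    res.call = call
    res.bonferroni_m = m
    return call


def analyze_deficiency(
    obs: pd.DataFrame, alpha: float = 0.05, high: float = 0.01, m: int = 1
) -> ComplementationResult:
    """ANOVA, deltas and the complementation call for one deletion."""
    res = two_way_anova_log(obs)
    call_complementation(res, alpha=alpha, high=high, m=m)
    return res


def results_table(results: list[ComplementationResult]) -> pd.DataFrame:
    """Per-deletion summary mirroring the published table layout."""
    rows = []
    for r in results:
        rows.append(
            {
                "deletion_id": r.deletion_id,
                "mean_E_def": r.means[("E", "def")],
                "mean_E_bal": r.means[("E", "bal")],
                "mean_A_def": r.means[("A", "def")],
                "mean_A_bal": r.means[("A", "bal")],
                "delta_def": r.delta_def,
                "delta_bal": r.delta_bal,
                "p_L": r.p_L,
                "p_G": r.p_G,
                "p_LxG": r.p_LxG,
                "call": r.call,
            }
        )
    return pd.DataFrame(rows)
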