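"""Published deficiency- and P-element-test summaries, as analysis inputs.

The per-fly raw scores behind the published complementation tests are not
deposited; the printed per-genotype means, SDs, deltas and ANOVA p-values
are.  These summaries are shipped as package data so the delta arithmetic
and the failure-to-complement decision rule can be applied to them directly.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .complementation import ComplementationResult, call_complementation


def _load(name: str) -> pd.DataFrame:
    with resources.files("qtlsweep.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_deficiency_tests() -> pd.DataFrame:
    """Summary of the 26 published deletion complementation tests."""
    return _load("deficiency_tests.tsv")


def load_pelement_tests() -> pd.DataFrame:
    """Summary of the two published P-element insertion tests."""
    return _load("pelement_tests.tsv")


def row_to_result(row: pd.Series, id_col: str = "deletion") -> ComplementationResult:
    """Build a ComplementationResult from one printed summary row.

    Deltas are recomputed from the printed genotype means, not copied from
    the printed delta columns.
    """
    means = {
        ("E", "def"): float(row["mean_E_def"]),
        ("E", "bal"): float(row["mean_E_bal"]),
        ("A", "def"): float(row["mean_A_def"]),
        ("A", "bal"): float(row["mean_A_bal"]),
    }
    sds = {
        ("E", "def"): float(row["sd_E_def"]),
        ("E", "bal"): float(row["sd_E_bal"]),
        ("A", "def"): float(row["sd_A_def"]),
        ("A", "bal"): float(row["sd_A_bal"]),
    }
    return ComplementationResult(
        deletion_id=str(row[id_col]),
        means=means,
        sds=sds,
        delta_def=means[("E", "def")] - means[("A", "def")],
        delta_bal=means[("E", "bal")] - means[("A", "bal")],
        p_L=float(row["p_L"]),
        p_G=float(row["p_G"]),
        p_LxG=float(row["p_LxG"]),
    )


def call_published_tests(
    table: pd.DataFrame, id_col: str = "deletion", alpha: float = 0.05, high: float = 0.01
) -> list[ComplementationResult]:
    """Apply the complementation decision rule to every printed row."""
    results = []
    for _, row in table.iterrows():
        res = row_to_result(row, id_col=id_col)
        call_complementation(res, alpha=alpha, high=high)
        results.append(res)
    return results
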