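"""Delta-Ct relative gene-expression quantification from qPCR Ct tables.

Replicate threshold-cycle (Ct) values per sample and gene are averaged
arithmetically; relative expression of a target gene against a
housekeeping gene (GAPDH by default) is

    delta_Ct = mean Ct(target) - mean Ct(housekeeping)
    relative expression = 2 ** (-delta_Ct)

so equal Ct means expression 1, and each extra cycle of the target
halves it. Group comparisons delegate to the two-sided Mann-Whitney
rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HOUSEKEEPING_DEFAULT",
    "CT_COLUMNS",
    "ExpressionResult",
    "GroupComparison",
    "relative_expression",
    "compare_groups",
]

HOUSEKEEPING_DEFAULT = "GAPDH"

#: Required columns of a Ct table.
CT_COLUMNS = ("sample", "group", "gene", "replicate", "ct")


@dataclass(frozen=True)
class ExpressionResult:
    """Per-sample delta-Ct and relative expression for one target gene.

    ``per_sample`` columns: sample, group, mean_ct_target,
    mean_ct_housekeeping, delta_ct, rel_expr. ``per_group`` columns:
    group, mean, sd, n (of rel_expr).
    """

    target: str
    housekeeping: str
    per_sample: pd.DataFrame
    per_group: pd.DataFrame


class GroupComparison(NamedTuple):
    statistic: float
    pvalue: float
    groups: tuple[str, str]
    n: tuple[int, int]


def _validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return table


def relative_expression(
    table: pd.DataFrame,
    housekeeping: str = HOUSEKEEPING_DEFAULT,
    target: str | None = None,
) -> ExpressionResult:
    """Delta-Ct relative expression of ``target`` against ``housekeeping``.

    Replicates are averaged per sample and gene; every sample must carry
    both genes (a sample lacking the housekeeping gene is an error
    naming that sample).
    """
    table = _validate_ct_table(table)
    if target is None:
        raise ValueError("a target gene must be named")
    if target == housekeeping:
        raise ValueError("target and housekeeping genes must differ")
    mean_ct = (
        table.groupby(["sample", "group", "gene"], sort=True)["ct"]
        .mean()
        .reset_index()
    )
    wide = mean_ct.pivot_table(index=["sample", "group"], columns="gene", values="ct")
    for gene in (housekeeping, target):
        if gene not in wide.columns:
            raise ValueError(f"gene {gene!r} absent from the Ct table")
        bad = wide.index[wide[gene].isna()]
        if len(bad):
            sample = bad[0][0]
            raise ValueError(f"sample {sample!r} lacks gene {gene!r}")
    per_sample = wide.reset_index()[["sample", "group"]].copy()
    per_sample["mean_ct_target"] = wide[target].to_numpy()
    per_sample["mean_ct_housekeeping"] = wide[housekeeping].to_numpy()
    per_sample["delta_ct"] = per_sample["mean_ct_target"] - per_sample["mean_ct_housekeeping"]
    per_sample["rel_expr"] = np.power(2.0, -per_sample["delta_ct"])
    per_group = (
        per_sample.groupby("group", sort=True)["rel_expr"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    return ExpressionResult(
        target=target,
        housekeeping=housekeeping,
        per_sample=per_sample,
        per_group=per_group,
    )


def compare_groups(
    result: ExpressionResult, gene: str | None = None
) -> GroupComparison:
    """Two-sided Mann-Whitney U test on relative expression between groups.

    ``gene``, if given, must match the result's target (the result holds
    a single gene). Requires exactly two nonempty groups.
    """
    if gene is not None and gene != result.target:
        raise ValueError(
            f"result is for gene {result.target!r}, not {gene!r}"
        )
    groups = sorted(result.per_sample["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    x = result.per_sample.loc[result.per_sample["group"] == groups[0], "rel_expr"]
    y = result.per_sample.loc[result.per_sample["group"] == groups[1], "rel_expr"]
    if x.empty or y.empty:
        raise ValueError("both groups must be nonempty")
    mw = stats.mannwhitneyu(x, y, alternative="two-sided")
    return GroupComparison(
        statistic=float(mw.statistic),
        pvalue=float(mw.pvalue),
        groups=(groups[0], groups[1]),
        n=(int(x.size), int(y.size)),
    )
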