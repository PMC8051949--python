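"""Expression statistics: Livak fold changes, Holm-Sidak correction, group tests.

The qPCR fold-change estimator is 2**(-ddCt) with
dCt = Ct_gene - Ct_housekeeping per replicate and
ddCt = dCt - mean(dCt over the reference condition).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "delta_delta_ct",
    "summarize_fold_changes",
    "holm_sidak",
    "group_tests",
]

CT_COLUMNS = ("sample_id", "condition", "gene", "ct")


def _validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if not np.all(np.isfinite(table["ct"])):
        raise ValueError("Ct values must be finite")
    return table


def delta_delta_ct(
    table: pd.DataFrame,
    housekeeping: str,
    reference_condition: str,
) -> pd.DataFrame:
    """Per-replicate Livak fold changes relative to a reference condition.

    Input rows: (sample_id, condition, gene, ct[, replicate]).  Samples
    lacking a housekeeping Ct are dropped with a warning; a target gene
    absent from the reference condition is an error.  Returns one row per
    (sample, target gene) with delta_ct, delta_delta_ct and fold_change.
    """
    table = _validate_ct_table(table)
    hk = table[table["gene"] == housekeeping].set_index("sample_id")["ct"]
    if hk.index.has_duplicates:
        hk = hk.groupby(level=0).mean()
    targets = table[table["gene"] != housekeeping].copy()
    if targets.empty:
        raise ValueError("no target genes in table")
    has_hk = targets["sample_id"].isin(hk.index)
    if not has_hk.all():
        dropped = sorted(targets.loc[~has_hk, "sample_id"].unique())
        warnings.warn(f"samples without housekeeping Ct dropped: {dropped}")
        targets = targets[has_hk]
    if targets.empty:
        raise ValueError(f"no sample carries housekeeping gene {housekeeping!r}")

    targets["delta_ct"] = targets["ct"].to_numpy() - hk.loc[targets["sample_id"]].to_numpy()

    ref = targets[targets["condition"] == reference_condition]
    if ref.empty:
        raise ValueError(f"reference condition {reference_condition!r} absent")
    ref_mean = ref.groupby("gene")["delta_ct"].mean()
    missing_ref = set(targets["gene"]) - set(ref_mean.index)
    if missing_ref:
        raise ValueError(
            f"genes absent from reference condition: {sorted(missing_ref)}"
        )
    targets["delta_delta_ct"] = (
        targets["delta_ct"].to_numpy() - ref_mean.loc[targets["gene"]].to_numpy()
    )
    targets["fold_change"] = 2.0 ** (-targets["delta_delta_ct"])
    return targets.reset_index(drop=True)


def summarize_fold_changes(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD fold change per (gene, condition)."""
    return (
        per_replicate.groupby(["gene", "condition"])["fold_change"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )


def holm_sidak(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Sidak ("Holm-Sidak") adjusted p-values and reject flags.

    Sorted ascending, adjusted p_(i) = max_{j<=i} 1 - (1 - p_(j))**(m - j),
    clipped to 1 (j 0-based); rejection proceeds stepwise while the adjusted
    value is <= alpha.  Results are returned in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    reject_sorted = np.zeros(m, dtype=bool)
    for i in range(m):
        if adj_sorted[i] <= alpha:
            reject_sorted[i] = True
        else:
            break
    adjusted = np.empty(m)
    reject = np.empty(m, dtype=bool)
    adjusted[order] = adj_sorted
    reject[order] = reject_sorted
    return adjusted, reject


def group_tests(groups: list, kind: str = "t_test") -> tuple[float, float]:
    """Two-sided group comparison: pooled t, Welch t, or one-way ANOVA.

    ``groups`` is a list of value sequences.  Groups of identical constant
    values yield (0, 1) rather than NaN.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs >= 2 values")
    if kind == "t_test" or kind == "welch_t":
        if len(arrays) != 2:
            raise ValueError(f"{kind} requires exactly 2 groups")
        with np.errstate(invalid="ignore", divide="ignore"):
            res = sps.ttest_ind(arrays[0], arrays[1], equal_var=(kind == "t_test"))
        stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(stat) and np.isclose(arrays[0].mean(), arrays[1].mean()):
            stat, p = 0.0, 1.0  # zero variance, equal means
        return stat, p
    if kind == "anova_oneway":
        with np.errstate(invalid="ignore", divide="ignore"):
            res = sps.f_oneway(*arrays)
        stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(stat) and len({a.mean() for a in arrays}) == 1:
            stat, p = 0.0, 1.0
        return stat, p
    raise ValueError(f"unknown test kind: {kind!r}")
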