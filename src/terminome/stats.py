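"""Quantitative peptide statistics across conditions.

Per-condition summaries (mean, sample sd, CV), pairwise fold changes
(numerator = first-listed condition), two-sample t-tests (pooled variance
by default) or one-way ANOVA for more than two conditions, multiple-testing
correction (step-up FDR by default; corrected values are written to the
table but figure cutoffs use raw p-values), empirical-quantile tail
significance on the log2 fold-change distribution, and the putative
substrate filter cascade.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .ingest import ConditionDesign

logger = logging.getLogger("terminome")

DEFAULT_P_CUTOFF = 0.05
DEFAULT_LOG2FC_CUTOFF = 1.0
DEFAULT_TAIL_FRACTION = 0.05


def to_numeric(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Convert quant columns to numeric; non-numeric cells become missing."""
    for c in columns:
        table[c] = pd.to_numeric(table[c], errors="coerce")
    return table


def fill_missing(table: pd.DataFrame, columns: list[str],
                 policy: float | str) -> pd.DataFrame:
    """Handle missing quant cells: fill with a value, or drop the row.

    ``policy`` is either a number (fill) or the string ``"drop"``.
    """
    if policy == "drop":
        before = len(table)
        table = table.dropna(subset=columns).reset_index(drop=True)
        logger.info("fill_missing: dropped %d rows with missing quant values",
                    before - len(table))
        return table
    value = float(policy)
    table[columns] = table[columns].fillna(value)
    return table


def summarize(values) -> tuple[float, float, float | None]:
    """Mean, sample sd (n-1 denominator) and CV of one condition's values.

    CV is undefined (None) when the mean is zero.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("summarize needs at least one value")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    if mean == 0:
        logger.info("summarize: mean is zero, CV undefined")
        return mean, sd, None
    return mean, sd, sd / mean


def condition_summaries(table: pd.DataFrame,
                        design: ConditionDesign) -> pd.DataFrame:
    """Append mean_<cond>, sd_<cond>, cv_<cond> columns."""
    for cond, cols in design.resolved.items():
        values = table[cols].to_numpy(float)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(values, axis=1)
            sd = np.nanstd(values, axis=1, ddof=1)
        cv = np.where(mean != 0, sd / mean, np.nan)
        table[f"mean_{cond}"] = mean
        table[f"sd_{cond}"] = sd
        table[f"cv_{cond}"] = cv
    return table


def condition_pairs(design: ConditionDesign) -> list[tuple[str, str]]:
    """All ordered pairs in condition-file order (first = numerator)."""
    return list(itertools.combinations(design.resolved.keys(), 2))


def fold_changes(table: pd.DataFrame, design: ConditionDesign) -> pd.DataFrame:
    """Append fold_change and log2_fc columns for every condition pair.

    FC(A, B) = mean_A / mean_B with the first-listed condition as
    numerator; rows with a zero or negative mean get empty values.
    """
    for a, b in condition_pairs(design):
        mean_a = table[f"mean_{a}"].to_numpy(float)
        mean_b = table[f"mean_{b}"].to_numpy(float)
        valid = (mean_a > 0) & (mean_b > 0)
        fc = np.where(valid, mean_a / np.where(mean_b > 0, mean_b, 1.0), np.nan)
        table[f"fold_change_{a}_vs_{b}"] = fc
        with np.errstate(invalid="ignore"):
            table[f"log2_fc_{a}_vs_{b}"] = np.log2(fc)
    return table


def _row_ttest(x: np.ndarray, y: np.ndarray, equal_var: bool) -> float | None:
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        return None
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(res.pvalue)


def test_differential(
    table: pd.DataFrame,
    design: ConditionDesign,
    method: str = "auto",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Append p-value columns per row.

    Two conditions → two-sample t-test (``p_value_<A>_vs_<B>``). More than
    two → one-way ANOVA by default (``p_value_anova``) or all pairwise
    t-tests with ``method="pairwise_ttest"``. Rows whose groups have fewer
    than two values get empty p-values rather than errors.
    """
    conds = list(design.resolved)
    if len(conds) < 2:
        raise ValueError("statistics need at least two conditions")
    if method == "auto":
        method = "ttest" if len(conds) == 2 else "anova"
    if method == "ttest" and len(conds) > 2:
        method = "pairwise_ttest"

    if method in ("ttest", "pairwise_ttest"):
        for a, b in condition_pairs(design):
            xa = table[design.resolved[a]].to_numpy(float)
            xb = table[design.resolved[b]].to_numpy(float)
            table[f"p_value_{a}_vs_{b}"] = [
                _row_ttest(xa[i], xb[i], equal_var) for i in range(len(table))]
    elif method == "anova":
        groups = [table[design.resolved[c]].to_numpy(float) for c in conds]
        pvals = []
        for i in range(len(table)):
            samples = [g[i][~np.isnan(g[i])] for g in groups]
            if any(s.size < 2 for s in samples):
                pvals.append(None)
            else:
                pvals.append(float(sps.f_oneway(*samples).pvalue))
        table["p_value_anova"] = pvals
    else:
        raise ValueError(f"unknown test method {method!r}")
    return table


def adjust_pvalues(pvalues, method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing correction (step-up FDR by default).

    Missing entries are passed through; adjusted values are clipped to
    [0, 1]. Raises on p-values outside [0, 1].
    """
    arr = np.asarray(pvalues, dtype=float)
    mask = ~np.isnan(arr)
    if np.any((arr[mask] < 0) | (arr[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(arr.shape, np.nan)
    if mask.sum():
        out[mask] = np.clip(multipletests(arr[mask], method=method)[1],
                            0.0, 1.0)
    return out


def adjust_table(table: pd.DataFrame, method: str = "fdr_bh") -> pd.DataFrame:
    """Adjust every p_value_* column jointly (one family across all tests)."""
    pcols = [c for c in table.columns if c.startswith("p_value_")]
    if not pcols:
        return table
    stacked = np.concatenate([table[c].to_numpy(float) for c in pcols])
    logger.info("multiple-testing family size: %d tests across %d columns",
                int(np.sum(~np.isnan(stacked))), len(pcols))
    adjusted = adjust_pvalues(stacked, method=method)
    n = len(table)
    for k, c in enumerate(pcols):
        table[c.replace("p_value_", "p_adjusted_")] = adjusted[k * n:(k + 1) * n]
    return table


def tail_significance(log2_fc,
                      tail_fraction: float = DEFAULT_TAIL_FRACTION) -> list[str]:
    """Label the tails of the empirical log2 fold-change distribution.

    Values at or above the (1 - f) quantile are ``significant_high``, at or
    below the f quantile ``significant_low``, the rest ``none``; each tail
    holds a fraction f of the distribution. Degenerate distributions (all
    values equal, or f <= 0) label nothing.
    """
    arr = np.asarray(log2_fc, dtype=float)
    finite = arr[np.isfinite(arr)]
    labels = ["none"] * len(arr)
    if tail_fraction <= 0 or finite.size == 0:
        return labels
    if finite.size < 20:
        logger.warning("tail_significance on only %d finite values; "
                       "quantile labels are unstable", finite.size)
    lo = float(np.quantile(finite, tail_fraction))
    hi = float(np.quantile(finite, 1.0 - tail_fraction))
    if not hi > lo:
        return labels  # degenerate distribution
    for i, v in enumerate(arr):
        if not np.isfinite(v):
            continue
        if v >= hi:
            labels[i] = "significant_high"
        elif v <= lo:
            labels[i] = "significant_low"
    return labels


def volcano_flags(table: pd.DataFrame, pair: tuple[str, str],
                  p_cutoff: float = DEFAULT_P_CUTOFF,
                  log2fc_cutoff: float = DEFAULT_LOG2FC_CUTOFF) -> pd.Series:
    """Rows passing both raw-p and |log2FC| cutoffs for one pair."""
    a, b = pair
    p = table[f"p_value_{a}_vs_{b}"].astype(float)
    lfc = table[f"log2_fc_{a}_vs_{b}"].astype(float)
    return (p < p_cutoff) & (lfc.abs() > log2fc_cutoff)


def run_statistics(
    table: pd.DataFrame,
    design: ConditionDesign,
    method: str = "auto",
    mt_method: str = "fdr_bh",
    p_cutoff: float = DEFAULT_P_CUTOFF,
    log2fc_cutoff: float = DEFAULT_LOG2FC_CUTOFF,
    tail_fraction: float = DEFAULT_TAIL_FRACTION,
    fill_policy: float | str | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Full statistics stage: summaries, FC, tests, correction, flags."""
    quant_cols = [c for cols in design.resolved.values() for c in cols]
    table = to_numeric(table, quant_cols)
    if fill_policy is not None:
        table = fill_missing(table, quant_cols, fill_policy)
    table = condition_summaries(table, design)
    table = fold_changes(table, design)
    table = test_differential(table, design, method=method, equal_var=equal_var)
    table = adjust_table(table, method=mt_method)
    for a, b in condition_pairs(design):
        lfc_col = f"log2_fc_{a}_vs_{b}"
        table[f"tail_label_{a}_vs_{b}"] = tail_significance(
            table[lfc_col].to_numpy(float), tail_fraction)
        if f"p_value_{a}_vs_{b}" in table:
            table[f"volcano_significant_{a}_vs_{b}"] = volcano_flags(
                table, (a, b), p_cutoff, log2fc_cutoff)
    return table


def substrate_filter(
    table: pd.DataFrame,
    p_column: str,
    fc_column: str,
    p_cutoff: float = 0.01,
    fc_cutoff: float = 3.0,
    require_nterm_label: bool = True,
    exclude_known_merops_id: str | None = None,
) -> pd.DataFrame:
    """Filter cascade for putative protease substrates.

    Keeps rows with p < ``p_cutoff`` and fold change > ``fc_cutoff``; with
    ``require_nterm_label`` additionally requires a labeled neo-N-terminus
    (label_state = labeled, category = internal). Rows whose P1 matches a
    known cleavage of ``exclude_known_merops_id`` are removed, so the
    remaining list contains only previously unattributed cleavages.
    """
    if table.empty:
        return table
    p = pd.to_numeric(table[p_column], errors="coerce")
    fc = pd.to_numeric(table[fc_column], errors="coerce")
    mask = (p < p_cutoff) & (fc > fc_cutoff)
    if require_nterm_label:
        mask &= (table["label_state"] == "labeled") & \
                (table["category"] == "internal")
    if exclude_known_merops_id is not None:
        known = table.get("known_proteases")
        if known is not None:
            attributed = known.fillna("").str.contains(
                exclude_known_merops_id, regex=False)
            mask &= ~attributed
    result = table[mask.fillna(False)].copy()
    logger.info("substrate filter kept %d/%d rows", len(result), len(table))
    return result
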