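"""Filtering, normalization and differential-expression summaries.

Counts are depth-normalized with the median-of-ratios size-factor
estimator: for sample j,

    s_j = median_i { k_ij / (prod_j k_ij)^(1/m) }

taken over features i with strictly positive counts in every sample.
Unlike TPM/RPKM this needs no transcript length, which cannot be defined
for repetitive elements whose effective transcribed length varies between
conditions — the reason repeat expression is compared on normalized counts
rather than length-normalized units.

Differential calls follow the dual-threshold rule used throughout the
figure summaries: a feature is significant when its fold-change between
group means is at least ``fold_threshold`` (either direction) AND the
two-sided Welch t-test on log2(normalized + 1) gives p < ``alpha``. No
multiple-testing correction enters the call; a Benjamini-Hochberg q-value
column is emitted for information.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "drop_unexpressed",
    "size_factors",
    "normalize",
    "zscores",
    "differential",
    "summarize_by_class",
]


def drop_unexpressed(matrix: pd.DataFrame) -> pd.DataFrame:
    """Discard features with no assigned reads in any sample.

    Row order of the surviving features is preserved.
    """
    keep = matrix.sum(axis=1) > 0
    return matrix.loc[keep]


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    Only features counted in every sample enter the estimate; raises if
    none exist (filter or deepen sequencing first).
    """
    values = matrix.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no feature has positive counts in every sample; size factors "
            "are undefined — drop samples or features (e.g. drop_unexpressed "
            "plus a prevalence filter) before normalizing")
    ref = values[all_positive]
    log_geomean = np.log(ref).mean(axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(ref) - log_geomean, axis=0))
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def normalize(matrix: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    factors = factors.reindex(matrix.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("size factors must be positive and cover all samples")
    return matrix / factors


def zscores(matrix: pd.DataFrame, transform: str = "log2p1") -> pd.DataFrame:
    """Standardize each feature across samples.

    Each row becomes (x - mean) / sd with the sample (ddof=1) standard
    deviation, computed after log2(x + 1) by default (``transform="none"``
    standardizes the normalized counts directly). Constant rows map to
    all-zero by convention. Requires at least two samples.
    """
    if matrix.shape[1] < 2:
        raise ValueError("z-scores need at least two samples")
    if transform == "log2p1":
        values = np.log2(matrix + 1.0)
    elif transform == "none":
        values = matrix.astype(float)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    z = values.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


def differential(
    normalized: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fold_threshold: float = 2.0,
    alpha: float = 0.05,
    classes: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-group differential expression on normalized counts.

    ``group_a`` is the reference (e.g. resting cells) and ``group_b`` the
    condition; the log2 fold-change is ``log2((mean_b + 1)/(mean_a + 1))``
    (pseudocount 1). p-values come from a two-sided Welch t-test on
    log2(normalized + 1); features constant in both groups get p = 1.

    Returns a table with columns mean_a, mean_b, log2_fc, p_value,
    q_value (BH, informational only), significant, direction and class.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups must not overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least two samples per group")
    missing = (set(group_a) | set(group_b)) - set(normalized.columns)
    if missing:
        raise KeyError(f"samples not in matrix: {sorted(missing)}")

    a = normalized[group_a].to_numpy(dtype=float)
    b = normalized[group_b].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2_fc = np.log2(mean_b + 1.0) - np.log2(mean_a + 1.0)

    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        # constant rows trip scipy's precision warning; they get p = 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = sps.ttest_ind(np.log2(b + 1.0), np.log2(a + 1.0),
                             axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero variance, equal means
    q = multipletests(p, method="fdr_bh")[1]

    significant = (np.abs(log2_fc) >= np.log2(fold_threshold)) & (p < alpha)
    direction = np.where(log2_fc > 0, "up", np.where(log2_fc < 0, "down", "none"))
    table = pd.DataFrame({
        "mean_a": mean_a,
        "mean_b": mean_b,
        "log2_fc": log2_fc,
        "p_value": p,
        "q_value": q,
        "significant": significant,
        "direction": direction,
    }, index=normalized.index)
    table["class"] = (classes.reindex(normalized.index)
                      if classes is not None else "other")
    return table


def summarize_by_class(table: pd.DataFrame) -> pd.DataFrame:
    """Tally significant calls per feature class.

    Returns per class: up, down, total (= up + down among significant
    rows) and percent_up = 100 * up / (up + down) (NaN when no calls) —
    the shape of the per-class differential-expression bar summaries.
    """
    sig = table[table["significant"]]
    rows = []
    for cls in sorted(table["class"].dropna().unique()):
        sub = sig[sig["class"] == cls]
        up = int((sub["direction"] == "up").sum())
        down = int((sub["direction"] == "down").sum())
        total = up + down
        rows.append({
            "class": cls,
            "up": up,
            "down": down,
            "total": total,
            "percent_up": 100.0 * up / total if total else float("nan"),
        })
    return pd.DataFrame(rows, columns=["class", "up", "down", "total",
                                       "percent_up"])
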