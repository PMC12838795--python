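"""Clinical/demographic comparison battery between response groups.

Categorical variables are compared with the exact conditional test on r×2
contingency tables (the 2×2 Fisher exact test and its Freeman–Halton
generalization to more rows, computed by exhaustive enumeration of tables with
the observed margins). Continuous variables use the Mann–Whitney U test
(unpaired) or the Wilcoxon signed-rank test (paired), with the usual
conventions declared explicitly: midranks for ties, zero differences dropped,
exact enumeration for small tie-free samples and the continuity-corrected
normal approximation otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = ["ContingencyTable", "fisher_exact_rxc", "mann_whitney_u",
           "wilcoxon_signed_rank", "clinical_comparison_table",
           "describe_median_iqr"]

#: Enumeration bound for the exact r×2 test (total table count).
ENUMERATION_BOUND = 10_000


@dataclass(frozen=True)
class ContingencyTable:
    """r×2 non-negative integer counts (columns are the SR/OR groups)."""

    counts: tuple  # tuple of (int, int) rows
    row_labels: tuple = ()
    col_labels: tuple = ("SR", "OR")

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
            raise ValueError("contingency table must be r×2 with r >= 2")
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if (arr.sum(axis=0) == 0).any():
            raise ValueError("each column needs at least one positive margin")

    def to_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


def _log_factorial(n):
    return gammaln(np.asarray(n, dtype=float) + 1.0)


def fisher_exact_rxc(table) -> float:
    """Freeman–Halton exact test for an r×2 table.

    p is the sum of the point probabilities of every table with the observed
    margins whose probability does not exceed the observed table's (within a
    1e-9 relative tolerance for floating-point ties). Computed by exhaustive
    enumeration; tables with more than ``ENUMERATION_BOUND`` total counts are
    rejected (a Monte-Carlo mode is not implemented). Zero rows do not change
    the p-value. For 2×2 tables this reduces exactly to the two-sided Fisher
    test of :func:`rvpathrx.carrier_burden.fisher_2x2`.
    """
    if isinstance(table, ContingencyTable):
        arr = table.to_array()
    else:
        arr = np.asarray(table, dtype=np.int64)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("table must be r×2")
    arr = arr[arr.sum(axis=1) > 0]  # zero rows carry no information
    if arr.shape[0] < 1:
        raise ValueError("table has no non-empty rows")
    if arr.shape[0] == 1:
        return 1.0
    total = int(arr.sum())
    if total > ENUMERATION_BOUND:
        raise ValueError(
            f"table total {total} exceeds the enumeration bound {ENUMERATION_BOUND}"
        )
    row_sums = arr.sum(axis=1)
    col1 = int(arr[:, 0].sum())

    # log point probability = log[ prod(r_i!) c_1! c_2! / (N! prod cells!) ]
    log_const = (_log_factorial(row_sums).sum()
                 + _log_factorial(col1) + _log_factorial(total - col1)
                 - _log_factorial(total))

    def log_prob(x: np.ndarray) -> float:
        return float(log_const - _log_factorial(x).sum()
                     - _log_factorial(row_sums - x).sum())

    obs = log_prob(arr[:, 0])

    # enumerate all first-column vectors x with 0 <= x_i <= r_i, sum = col1
    r = len(row_sums)
    p_total = 0.0
    x = np.zeros(r, dtype=np.int64)

    def recurse(i: int, remaining: int):
        nonlocal p_total
        if i == r - 1:
            if 0 <= remaining <= row_sums[i]:
                x[i] = remaining
                lp = log_prob(x)
                if lp <= obs + 1e-9:
                    p_total += math.exp(lp)
            return
        tail_capacity = int(row_sums[i + 1:].sum())
        lo = max(0, remaining - tail_capacity)
        hi = min(int(row_sums[i]), remaining)
        for v in range(lo, hi + 1):
            x[i] = v
            recurse(i + 1, remaining - v)

    recurse(0, col1)
    return min(p_total, 1.0)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]):
    """Mann–Whitney U test for two unpaired samples.

    Returns ``(U, p_two_sided)`` with U computed for ``x`` from midranks.
    The p-value is exact (full enumeration) when n_x + n_y <= 20 and the
    pooled data contain no ties, otherwise the normal approximation with
    tie-corrected variance and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(before: Sequence[float], after: Sequence[float]):
    """Wilcoxon signed-rank test for paired data.

    Differences ``after − before`` equal to zero are dropped (Wilcoxon
    convention); |d| receives midranks. Returns ``(W, p_two_sided)`` where W
    is the smaller of the positive/negative rank sums. Exact when n <= 15
    without ties in |d|, else normal approximation with continuity correction.
    All-zero differences yield ``(0, 1.0)`` with a warning.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired samples must have equal length")
    d = after - before
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    abs_ties = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= 15 and not abs_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                         correction=(method == "approx"), method=method)
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    return min(w_pos, w_neg), float(res.pvalue)


def clinical_comparison_table(df: pd.DataFrame) -> pd.DataFrame:
    """Group-comparison table over a phenotype frame.

    ``df`` needs ``group`` ('SR'/'OR'), ``sex`` and ``age`` columns; any other
    numeric column is compared between groups with the Mann–Whitney U test,
    and ``<name>_baseline`` / ``<name>_week14`` pairs are additionally
    compared within each group with the Wilcoxon signed-rank test. Output
    rows carry median [IQR] descriptives per group and the test p-value.
    """
    is_sr = df["group"] == "SR"
    rows = []

    def fmt(values):
        d = describe_median_iqr(values)
        if d["n"] == 0:
            return "."
        return f"{d['median']:g} [{d['q1']:g}-{d['q3']:g}]"

    sex_counts = [[int(((df["sex"] == s) & is_sr).sum()),
                   int(((df["sex"] == s) & ~is_sr).sum())]
                  for s in ("male", "female")]
    rows.append({"variable": "sex (male/female)",
                 "sr": f"{sex_counts[0][0]}/{sex_counts[1][0]}",
                 "or": f"{sex_counts[0][1]}/{sex_counts[1][1]}",
                 "test": "fisher_exact",
                 "p": fisher_exact_rxc(sex_counts)})

    numeric = [c for c in df.columns
               if c not in ("sample_id", "group", "sex")
               and pd.api.types.is_numeric_dtype(pd.to_numeric(df[c], errors="coerce"))]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        x = vals[is_sr].dropna().to_numpy()
        y = vals[~is_sr].dropna().to_numpy()
        if len(x) == 0 or len(y) == 0:
            continue
        _, p = mann_whitney_u(x, y)
        rows.append({"variable": col, "sr": fmt(x), "or": fmt(y),
                     "test": "mann_whitney_u", "p": p})

    # paired before/after comparisons within each group
    for col in numeric:
        if not col.endswith("_baseline"):
            continue
        partner = col.replace("_baseline", "_week14")
        if partner not in df.columns:
            continue
        for label, mask in (("SR", is_sr), ("OR", ~is_sr)):
            sub = df.loc[mask, [col, partner]].apply(pd.to_numeric, errors="coerce")
            sub = sub.dropna()
            if len(sub) < 2:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, p = wilcoxon_signed_rank(sub[col].to_numpy(),
                                            sub[partner].to_numpy())
            rows.append({"variable": f"{col.replace('_baseline', '')} "
                                     f"baseline vs week14 ({label})",
                         "sr": fmt(sub[col]) if label == "SR" else ".",
                         "or": fmt(sub[col]) if label == "OR" else ".",
                         "test": "wilcoxon_signed_rank", "p": p})
    return pd.DataFrame(rows)


def describe_median_iqr(values: Sequence[float]) -> dict:
    """Median and interquartile range descriptives for table output."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return {"n": 0, "median": float("nan"), "q1": float("nan"),
                "q3": float("nan"), "min": float("nan"), "max": float("nan")}
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"n": int(v.size), "median": float(med), "q1": float(q1),
            "q3": float(q3), "min": float(v.min()), "max": float(v.max())}
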