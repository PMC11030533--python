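"""Cohort-level frequency tables, exact tests and correlations.

Operates on a per-sample cohort table (pandas DataFrame; one row per
sample with ancestry label, assay, deletion call, zygosity, loss
estimate, SPOP status and any signature/scar measures). Tests report
unadjusted p-values by default; Benjamini-Hochberg correction is opt-in.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats


def fisher_exact_2x2(table, alternative: str = "greater") -> float:
    """Fisher exact test on a 2x2 count table.

    One-sided tails are exact hypergeometric; the two-sided p sums the
    probabilities of all tables (fixed margins) no more probable than
    the observed one. A zero margin makes every table equally likely:
    p = 1 with a warning.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)) or np.any(t < 0):
            raise ValueError("cells must be non-negative integers")
        t = t.astype(np.int64)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("zero margin in 2x2 table; p = 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(t, alternative=alternative).pvalue)


def frequency_summary(cohort: pd.DataFrame, group_col: str = "ancestry",
                      call_col: str = "deleted") -> pd.DataFrame:
    """Per-group deletion counts and percentages (one decimal place)."""
    rows = []
    for group, grp in cohort.groupby(group_col, sort=True):
        n = len(grp)
        k = int(grp[call_col].astype(bool).sum())
        pct = round(100.0 * k / n, 1) if n else 0.0
        rows.append({group_col: group, "n": n, "n_deleted": k, "pct_deleted": pct})
    return pd.DataFrame(rows)


def overlap_summary(cohort: pd.DataFrame, aberration_a: str, aberration_b: str) -> dict:
    """Co-occurrence of two per-sample boolean aberrations."""
    a = cohort[aberration_a].astype(bool)
    b = cohort[aberration_b].astype(bool)
    n_a, n_b = int(a.sum()), int(b.sum())
    n_both = int((a & b).sum())
    return {
        "n_a": n_a, "n_b": n_b, "n_both": n_both,
        "pct_of_a": round(100.0 * n_both / n_a, 1) if n_a else 0.0,
        "pct_of_b": round(100.0 * n_both / n_b, 1) if n_b else 0.0,
    }


def group_compare(cohort: pd.DataFrame, measure: str, group_col: str = "group",
                  adjust: bool = False) -> pd.DataFrame:
    """Pairwise two-sample Mann-Whitney rank-sum tests between groups.

    Exact null distribution when both groups have n <= 20 and no ties;
    otherwise the normal approximation with tie correction. With
    ``adjust`` the p-values are Benjamini-Hochberg corrected.
    """
    groups = {g: grp[measure].dropna().to_numpy() for g, grp in cohort.groupby(group_col)}
    rows = []
    for (g1, x1), (g2, x2) in itertools.combinations(sorted(groups.items()), 2):
        if len(x1) == 0 or len(x2) == 0:
            continue
        ties = len(np.unique(np.concatenate([x1, x2]))) < len(x1) + len(x2)
        method = "exact" if (max(len(x1), len(x2)) <= 20 and not ties) else "asymptotic"
        res = stats.mannwhitneyu(x1, x2, alternative="two-sided", method=method)
        rows.append({"group_a": g1, "group_b": g2, "n_a": len(x1), "n_b": len(x2),
                     "statistic": float(res.statistic), "p": float(res.pvalue),
                     "method": method})
    out = pd.DataFrame(rows)
    if adjust and len(out):
        out["p_adjusted"] = _benjamini_hochberg(out["p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def loss_fraction_correlation(x, y) -> dict:
    """Pearson correlation with its standard error and two-sided t-test p.

    SE = sqrt((1 - r^2) / (n - 2)); undefined for n <= 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n <= 2:
        raise ValueError("correlation SE undefined for n <= 2")
    r, p = stats.pearsonr(x, y)
    se = float(np.sqrt((1.0 - r**2) / (n - 2)))
    return {"r": float(r), "se": se, "p": float(p), "n": n}


def cohort_from_counts(group_sizes: dict[str, int],
                       deleted_counts: dict[str, int],
                       group_col: str = "ancestry") -> pd.DataFrame:
    """Expand printed per-group (total, deleted) counts into a per-sample
    table, so summary statistics are recomputed rather than transcribed."""
    rows = []
    for group, n in group_sizes.items():
        k = deleted_counts.get(group, 0)
        if k > n:
            raise ValueError(f"{group}: more deleted than total")
        for i in range(n):
            rows.append({"sample_id": f"{group}_{i:04d}", group_col: group,
                         "deleted": i < k})
    return pd.DataFrame(rows)
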