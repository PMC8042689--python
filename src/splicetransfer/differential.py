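"""Feature screens and two-group statistics.

Kruskal-Wallis screens define the differential expression / splicing
feature sets; Wilcoxon rank-sum backs every boxplot comparison; Fisher's
exact test quantifies overlap of feature sets; the CD44/CD24 log2 ratio
is a stemness score.  Screens use raw p-value thresholds by design (that
is how the feature sets were defined); an optional Benjamini-Hochberg
correction is available but off by default.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "kruskal_wallis_screen",
    "wilcoxon_rank_sum",
    "overlap_fisher",
    "cd44_cd24_score",
    "zscore_rows",
]


def kruskal_wallis_screen(
    matrix: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    alpha: float,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Tie-corrected Kruskal-Wallis H per feature (row) across >= 2 groups.

    ``alpha`` is deliberately a required argument: the screens in this
    analysis family were run at different raw thresholds (1e-3 for the
    displayed heatmaps, 1e-5 in general, 1e-9 for RNA-binding proteins)
    and no silent default is appropriate.

    Features with fewer than 2 non-missing values in any group are
    skipped (``tested = False``, NaN statistics).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    group_cols = {name: list(cols) for name, cols in groups.items()}
    for name, cols in group_cols.items():
        unknown = [c for c in cols if c not in matrix.columns]
        if unknown:
            raise KeyError(f"unknown samples in group '{name}': {unknown}")

    stat = np.full(len(matrix), np.nan)
    pval = np.full(len(matrix), np.nan)
    tested = np.zeros(len(matrix), dtype=bool)
    for i in range(len(matrix)):
        row = matrix.iloc[i]
        vals = [row[cols].dropna().to_numpy(dtype=float) for cols in group_cols.values()]
        if any(len(v) < 2 for v in vals):
            continue
        if all(np.all(v == vals[0][0]) for v in vals):  # all values identical: H undefined
            continue
        h, p = stats.kruskal(*vals)
        stat[i], pval[i], tested[i] = h, p, True

    out = pd.DataFrame(
        {"statistic": stat, "p_value": pval, "tested": tested}, index=matrix.index
    )
    if bh_correct:
        adj = np.full(len(out), np.nan)
        mask = tested & ~np.isnan(pval)
        adj[mask] = stats.false_discovery_control(pval[mask], method="bh")
        out["p_adjusted"] = adj
        out["selected"] = tested & (adj < alpha)
    else:
        out["selected"] = tested & (pval < alpha)
    return out


def _rank_sum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided permutation p of the rank-sum statistic (handles ties)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n, nx = len(pooled), len(x)
    w_obs = ranks[:nx].sum()
    mu = nx * (n + 1) / 2.0
    dev_obs = abs(w_obs - mu)
    count = total = 0
    for idx in combinations(range(n), nx):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mu) >= dev_obs - 1e-9:
            count += 1
    return count / total


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact permutation enumeration when min(n) <= 8 (valid under ties);
    tie-corrected normal approximation otherwise.  Returns
    (rank-sum statistic of ``x``, p-value).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: len(x)].sum())
    if min(len(x), len(y)) <= 8:
        return w, _rank_sum_exact_p(x, y)
    n, nx, ny = len(pooled), len(x), len(y)
    mu = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    # tie-corrected variance of the rank-sum statistic
    var = nx * ny * (n + 1) / 12.0 - nx * ny * (tie_counts ** 3 - tie_counts).sum() / (12.0 * n * (n - 1))
    if var <= 0:
        return w, 1.0
    z = (w - mu) / np.sqrt(var)
    return w, float(2.0 * stats.norm.sf(abs(z)))


def overlap_fisher(
    set_a: Sequence[str], set_b: Sequence[str], universe: Sequence[str]
) -> tuple[float, float]:
    """Two-tailed Fisher's exact test for overlap of two feature sets.

    Returns (odds_ratio, p_value); the odds ratio is NaN when a margin
    is empty (degenerate table, p = 1).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    a, b = set(set_a), set(set_b)
    if not a <= uni or not b <= uni:
        raise ValueError("sets must be subsets of the universe")
    n11 = len(a & b)
    n12 = len(a - b)
    n21 = len(b - a)
    n22 = len(uni) - n11 - n12 - n21
    if len(a) == 0 or len(b) == 0 or len(a) == len(uni) or len(b) == len(uni):
        return float("nan"), 1.0
    odds, p = stats.fisher_exact([[n11, n12], [n21, n22]], alternative="two-sided")
    return float(odds), float(p)


def cd44_cd24_score(
    expression: pd.DataFrame,
    pseudocount: float = 1.0,
    cd44: str = "CD44",
    cd24: str = "CD24",
) -> pd.Series:
    """Per-sample stemness score log2((TPM_CD44 + pc) / (TPM_CD24 + pc))."""
    for g in (cd44, cd24):
        if g not in expression.index:
            raise KeyError(f"gene '{g}' absent from expression matrix")
    score = np.log2((expression.loc[cd44] + pseudocount) / (expression.loc[cd24] + pseudocount))
    score.name = "cd44_cd24_score"
    return score


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-score (subtract mean, divide by sample sd, ddof=1).

    Constant rows map to all-zero rows; NaNs are ignored in the moments
    and preserved in the output.
    """
    vals = matrix.to_numpy(dtype=float)
    mean = np.nanmean(vals, axis=1, keepdims=True)
    sd = np.nanstd(vals, axis=1, keepdims=True, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mean) / sd
    z[np.broadcast_to(~(sd > 0), z.shape) & ~np.isnan(vals)] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
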