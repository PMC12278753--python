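"""Association and stratification statistics.

Covers the nonparametric toolkit used to link cellular scores to clinical
outcomes: Spearman rank correlation with asymptotic p-values, Mann-Whitney U
group comparisons, within-group quintile assignment with ceil(n/5) focus
quintiles, odds ratios with Woolf (log-normal) confidence intervals and the
Haldane-Anscombe 0.5 continuity correction for zero cells, Fisher exact
p-values, LDL-C goal attainment, and the focus-quintile-vs-rest stratified
analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

Z_95 = 1.96  # conventional two-sided 95% normal quantile


def _paired_finite(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) with the asymptotic t-based p.

    Missing pairs are dropped; at least four complete pairs are required.
    A constant vector leaves rho undefined (NaN, with a warning).
    """
    x, y = _paired_finite(x, y)
    if len(x) < 4:
        raise ValueError("spearman needs at least 4 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: Spearman rho undefined", stacklevel=2)
        return math.nan, math.nan
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def r_squared(x, y) -> float:
    """Coefficient of determination: squared Pearson correlation of x and y."""
    x, y = _paired_finite(x, y)
    if len(x) < 3:
        raise ValueError("r_squared needs at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance: R^2 undefined", stacklevel=2)
        return math.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution for small samples without ties, tie-corrected
    normal approximation otherwise.  Returns (U of the first group, p).
    Completely tied data give p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return len(a) * len(b) / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(a), len(b)) <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def focus_quintile_size(n: int) -> int:
    """Number of subjects in the lowest (or highest) focus quintile: ceil(n/5)."""
    if n < 5:
        raise ValueError("quintiles need at least 5 subjects")
    return -(-n // 5)


def assign_quintiles(scores: pd.Series) -> pd.DataFrame:
    """Rank subjects and assign quintiles Q1 (lowest) .. Q5 (highest).

    The focus quintiles Q1 and Q5 each contain exactly ceil(n/5) subjects;
    the remainder is split as evenly as possible over Q2-Q4.  Ties are broken
    by stable input order.  Missing scores are not allowed here (drop them
    before calling).
    """
    s = pd.Series(scores)
    if s.isna().any():
        raise ValueError("scores contain missing values; drop them first")
    n = len(s)
    k = focus_quintile_size(n)
    order = np.argsort(s.to_numpy(), kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)

    mid = n - 2 * k
    mid_sizes = [mid // 3 + (1 if i < mid % 3 else 0) for i in range(3)]
    bounds = np.cumsum([k, *mid_sizes, k])
    quintile = np.searchsorted(bounds, rank, side="right") + 1
    return pd.DataFrame(
        {
            "score": s.to_numpy(),
            "rank": rank,
            "quintile": [f"Q{q}" for q in quintile],
            "is_lowest": rank < k,
            "is_highest": rank >= n - k,
        },
        index=s.index,
    )


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 table (rows: focus/rest, columns: outcome yes/no) with OR statistics.

    ``is_estimated`` marks the Haldane-Anscombe corrected odds ratio (0.5
    added to every cell because the raw table contains a zero); the Woolf CI
    is then computed on the corrected cells too.  The Fisher p always refers
    to the raw integer table.
    """

    table: tuple[tuple[int, int], tuple[int, int]]
    or_value: float
    is_estimated: bool
    ci95: tuple[float, float]
    fisher_p: float


def odds_ratio(table, z: float = Z_95) -> ContingencyResult:
    """Odds ratio with Woolf CI and two-sided Fisher exact p.

    OR = ad/bc; with any zero cell, all four cells get +0.5 first
    (Haldane-Anscombe) and the result is flagged as estimated.  The CI is
    exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)) on the cells actually
    used.  The Fisher p sums hypergeometric probabilities of tables no more
    probable than the observed one (probability-mass criterion).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("table must be a 2x2 array of non-negative integers")
    a, b, c, d = t.ravel()
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("odds ratio undefined: empty row or column")
    is_estimated = bool(np.any(t == 0))
    if is_estimated:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_value = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci = (math.exp(math.log(or_value) - z * se), math.exp(math.log(or_value) + z * se))
    int_table = tuple(tuple(int(v) for v in row) for row in t.astype(int))
    fisher_p = float(sps.fisher_exact(t.astype(int), alternative="two-sided").pvalue)
    return ContingencyResult(table=int_table, or_value=float(or_value),
                             is_estimated=is_estimated, ci95=ci, fisher_p=fisher_p)


def goal_attainment(ldl_c, threshold: float):
    """True where LDL-C is strictly below the treatment target (mmol/L)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    x = pd.Series(ldl_c, dtype=float) if not np.isscalar(ldl_c) else None
    if x is None:
        return bool(ldl_c < threshold) if not pd.isna(ldl_c) else pd.NA
    out = x < threshold
    return out.mask(x.isna())


def stratified_analysis(scores: pd.DataFrame, outcome: pd.Series,
                        groups: pd.Series,
                        score_names: list[str] | None = None) -> pd.DataFrame:
    """Focus-quintile-vs-rest odds ratios per group and score.

    Quintiles are assigned within each group separately.  For both the
    lowest and the highest focus quintile a 2x2 table (focus/rest x
    outcome yes/no) is built on subjects with non-missing score and outcome,
    and :func:`odds_ratio` is applied.  Returns one row per
    (group, score, focus) with the table cells, OR, estimation flag, Woolf
    CI, Fisher p and outcome percentages per stratum.
    """
    if score_names is None:
        score_names = list(scores.columns)
    outcome = pd.Series(outcome).reindex(scores.index)
    groups = pd.Series(groups).reindex(scores.index)
    rows = []
    for grp in pd.unique(groups.dropna()):
        g_mask = groups == grp
        for name in score_names:
            s = scores.loc[g_mask, name]
            y = outcome[g_mask]
            ok = s.notna() & y.notna()
            s, y = s[ok], y[ok].astype(bool)
            if len(s) < 5:
                continue
            q = assign_quintiles(s)
            for focus, flag in (("lowest", "is_lowest"), ("highest", "is_highest")):
                in_focus = q[flag]
                a = int((in_focus & y).sum())
                b = int((in_focus & ~y).sum())
                c = int((~in_focus & y).sum())
                d = int((~in_focus & ~y).sum())
                try:
                    res = odds_ratio([[a, b], [c, d]])
                except ValueError:
                    res = None
                rows.append(
                    {
                        "group": grp,
                        "score": name,
                        "focus": focus,
                        "n": len(s),
                        "n_focus": a + b,
                        "a": a, "b": b, "c": c, "d": d,
                        "or_value": res.or_value if res else math.nan,
                        "is_estimated": res.is_estimated if res else True,
                        "ci_low": res.ci95[0] if res else math.nan,
                        "ci_high": res.ci95[1] if res else math.nan,
                        "fisher_p": res.fisher_p if res else math.nan,
                        "pct_focus": 100.0 * a / (a + b) if a + b else math.nan,
                        "pct_rest": 100.0 * c / (c + d) if c + d else math.nan,
                        "pct_overall": 100.0 * (a + c) / len(s),
                    }
                )
    return pd.DataFrame(rows)
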