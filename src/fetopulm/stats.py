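"""Descriptive tables, group comparisons and the sample-size calculation.

Reproduces the study-style reporting: per-stratum ``mean +- SD`` for
continuous variables and ``n (%)`` for binary flags; two-group comparisons
with Student's t or Wilcoxon rank-sum (continuous) and chi-square with Yates
continuity correction or Fisher's exact test (categorical); optional
covariate adjustment through an ordinary linear model whose group
coefficient is reported; and the normal-approximation two-sample sample-size
formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class ComparisonResult:
    variable: str
    test: str
    groups: dict
    estimate: Optional[float]
    p_value: float
    covariates: tuple = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """Exact percentage recomputed from counts, rounded for display."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)


def summarize_groups(table: pd.DataFrame, stratifier: str,
                     variables: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-stratum ``mean +- SD`` / ``n (%)`` summary table.

    Binary 0/1 columns are summarised as count and percentage of the stratum
    size; other numeric columns as mean and SD.  Empty strata yield flagged
    (all-NaN) rows rather than division by zero.
    """
    if stratifier not in table.columns:
        raise KeyError(f"stratifier {stratifier!r} not in table")
    if table["subject_id"].duplicated().any() if "subject_id" in table else False:
        raise ValueError("duplicate subject ids in outcome table")
    cols = [c for c in (variables or table.columns)
            if c not in (stratifier, "subject_id")]
    rows = []
    for level, sub in table.groupby(stratifier, observed=True):
        n = len(sub)
        for c in cols:
            x = sub[c].dropna()
            if x.empty:
                rows.append({stratifier: level, "variable": c, "n": n,
                             "kind": "empty"})
                continue
            if set(np.unique(x)) <= {0, 1}:
                k = int(x.sum())
                rows.append({
                    stratifier: level, "variable": c, "n": n, "kind": "binary",
                    "count": k, "pct": percentage(k, n),
                })
            else:
                rows.append({
                    stratifier: level, "variable": c, "n": n,
                    "kind": "continuous", "mean": float(x.mean()),
                    "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
                })
    return pd.DataFrame(rows)


def _two_by_two(x: pd.Series, g: pd.Series, levels) -> np.ndarray:
    return np.array([
        [int(((g == lev) & (x == 1)).sum()), int(((g == lev) & (x == 0)).sum())]
        for lev in levels
    ])


def compare_groups(
    table: pd.DataFrame,
    variable: str,
    group_col: str,
    covariates: Sequence[str] = (),
    continuous_test: str = "t",
    categorical_test: str = "chi2",
) -> ComparisonResult:
    """Two-group comparison of one variable.

    Continuous: Student's t (``continuous_test="t"``) or Wilcoxon rank-sum
    with mid-rank ties (``"ranksum"``).  Binary: chi-square with Yates
    continuity correction (``categorical_test="chi2"``; automatic Fisher
    fallback when any expected cell < 1) or Fisher's exact test.  With
    covariates, an OLS model ``variable ~ group + covariates`` is fitted and
    the group-coefficient p-value reported.
    """
    sub = table[[variable, group_col, *covariates]].dropna()
    levels = sorted(sub[group_col].unique().tolist())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    x = sub[variable]
    binary = set(np.unique(x)) <= {0, 1}

    groups_summary = {}
    for lev in levels:
        xi = x[sub[group_col] == lev]
        if binary:
            groups_summary[lev] = {"n": len(xi), "count": int(xi.sum()),
                                   "pct": percentage(int(xi.sum()), len(xi))}
        else:
            groups_summary[lev] = {"n": len(xi), "mean": float(xi.mean()),
                                   "sd": float(xi.std(ddof=1))}

    if covariates:
        import statsmodels.api as sm

        gdum = (sub[group_col] == levels[1]).astype(float)
        design = sm.add_constant(
            pd.concat([gdum.rename("_group"), sub[list(covariates)]], axis=1))
        model = sm.OLS(x.astype(float), design).fit()
        return ComparisonResult(
            variable=variable, test="ols-adjusted", groups=groups_summary,
            estimate=float(model.params["_group"]),
            p_value=float(model.pvalues["_group"]),
            covariates=tuple(covariates),
        )

    if binary:
        tab = _two_by_two(x, sub[group_col], levels)
        if categorical_test == "fisher":
            _, p = sps.fisher_exact(tab)
            test = "fisher"
        else:
            chi2, p, _, expected = sps.chi2_contingency(tab, correction=True)
            test = "chi2-yates"
            if (expected < 1).any():
                _, p = sps.fisher_exact(tab)
                test = "fisher (expected cell < 1)"
        est = None
        return ComparisonResult(variable=variable, test=test,
                                groups=groups_summary, estimate=est, p_value=float(p))

    xa = x[sub[group_col] == levels[0]].to_numpy(dtype=float)
    xb = x[sub[group_col] == levels[1]].to_numpy(dtype=float)
    if continuous_test == "ranksum":
        res = sps.mannwhitneyu(xa, xb, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        test = "wilcoxon-ranksum"
        est = float(np.median(xb) - np.median(xa))
        p = float(res.pvalue)
    else:
        res = sps.ttest_ind(xa, xb)
        test = "t"
        est = float(xb.mean() - xa.mean())
        p = float(res.pvalue)
    return ComparisonResult(variable=variable, test=test, groups=groups_summary,
                            estimate=est, p_value=p)


def sample_size_two_means(
    alpha: float, power: float, mean: float, sd: float, pct_diff: float,
    allocation: float = 1.0,
) -> tuple:
    """Per-arm sample sizes to detect a relative difference in means.

    Normal-approximation two-sample formula with detectable difference
    ``delta = mean * pct_diff / 100``:

        n1 = ceil((z_{1-a/2} + z_{1-b})^2 * sigma^2 * (1 + 1/r) / delta^2),
        n2 = ceil(r * n1),

    for allocation ratio ``r = n2 / n1``.  Non-increasing in ``pct_diff``
    and in ``alpha``.
    """
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    if sd <= 0:
        raise ValueError("sd must be positive")
    if pct_diff <= 0:
        raise ValueError("pct_diff must be positive (delta = 0 gives infinite n)")
    if allocation <= 0:
        raise ValueError("allocation ratio must be positive")
    delta = abs(mean) * pct_diff / 100.0
    if delta == 0:
        raise ValueError("zero detectable difference")
    z = sps.norm.ppf(1.0 - alpha / 2.0) + sps.norm.ppf(power)
    n1_raw = (z ** 2) * (sd ** 2) * (1.0 + 1.0 / allocation) / delta ** 2
    n1 = max(int(math.ceil(n1_raw)), 1)
    n2 = max(int(math.ceil(allocation * n1_raw)), 1)
    return n1, n2


def outcome_table(cohort: list, clusters: Optional[dict] = None) -> pd.DataFrame:
    """One row per subject: group, cluster, outcome flags and continuous
    perinatal measures — the joined input of the report tables."""
    rows = []
    for s in cohort:
        row = {"subject_id": s.subject_id, "group": s.group,
               "reactivity": s.reactivity}
        row.update({k: v for k, v in s.outcomes.items()})
        row["ga_weeks"] = s.ga_weeks
        row["efw_g"] = s.efw_g
        if clusters is not None:
            row["cluster"] = clusters.get(s.subject_id)
        rows.append(row)
    df = pd.DataFrame(rows)
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject ids in cohort")
    return df
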