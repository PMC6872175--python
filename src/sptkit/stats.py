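"""Group-level summaries and pairwise distribution comparisons.

Diffusion metrics are heavy-tailed, so groups are summarized as median with
25-75% interquartile interval (linear-interpolation percentile convention)
and compared with distribution-free two-sided tests: Mann-Whitney U (tie
corrected, normal approximation for large samples, exact for small ones via
scipy) and the two-sample Kolmogorov-Smirnov test.  Significance is called
at alpha = 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_ALPHA = 0.01

TESTS = ("mann_whitney", "ks")


@dataclass(frozen=True)
class GroupSummary:
    label: str
    metric: str
    median: float
    q25: float
    q75: float
    n: int

    def as_row(self) -> dict:
        return {
            "group": self.label, "metric": self.metric, "median": self.median,
            "iqr_low": self.q25, "iqr_high": self.q75, "n": self.n,
        }


@dataclass(frozen=True)
class ComparisonResult:
    test: str
    group_a: str
    group_b: str
    p_value: float
    statistic: float
    alpha: float = DEFAULT_ALPHA

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)


def summarize_group(values, label: str, metric: str = "") -> GroupSummary:
    """Median and 25-75% interquartile interval of one metric for one group."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError(f"group {label!r}: no finite values to summarize")
    q25, med, q75 = np.percentile(values, [25, 50, 75])
    return GroupSummary(label=label, metric=metric, median=float(med),
                        q25=float(q25), q75=float(q75), n=int(values.size))


def compare_groups(a, b, test: str = "mann_whitney",
                   labels: tuple = ("a", "b"),
                   alpha: float = DEFAULT_ALPHA) -> ComparisonResult:
    """Two-sided distribution comparison of two samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if test == "mann_whitney":
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "ks":
        res = sps.ks_2samp(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}; expected one of {TESTS}")
    return ComparisonResult(test=test, group_a=labels[0], group_b=labels[1],
                            p_value=float(res.pvalue),
                            statistic=float(res.statistic), alpha=alpha)


def mannwhitney_exact_p(a, b) -> float:
    """Exact two-sided Mann-Whitney p-value by full enumeration.

    Enumerates all C(n_a + n_b, n_a) assignments of the pooled ranks;
    intended as an independent small-sample oracle (n_a + n_b <= ~16).
    Ties are handled by mid-ranks.
    """
    from itertools import combinations

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    na = len(a)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2.0
    mean_u = na * len(b) / 2.0
    obs_dev = abs(u_obs - mean_u)
    idx = range(len(pooled))
    count = total = 0
    for comb in combinations(idx, na):
        u = ranks[list(comb)].sum() - na * (na + 1) / 2.0
        total += 1
        if abs(u - mean_u) >= obs_dev - 1e-12:
            count += 1
    return count / total


def group_report(df: pd.DataFrame, group_col: str, metric_cols,
                 tests=TESTS, alpha: float = DEFAULT_ALPHA):
    """Summaries per (group, metric) plus all pairwise comparisons.

    Returns ``(summary_df, comparisons_df)`` mirroring a median/IQR/N table
    layout and a (pair, test, p) table.
    """
    from itertools import combinations

    groups = list(df[group_col].dropna().unique())
    summaries = []
    comparisons = []
    for metric in metric_cols:
        for g in groups:
            vals = df.loc[df[group_col] == g, metric].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size:
                summaries.append(summarize_group(vals, str(g), metric).as_row())
        for ga, gb in combinations(groups, 2):
            va = df.loc[df[group_col] == ga, metric].dropna()
            vb = df.loc[df[group_col] == gb, metric].dropna()
            if va.empty or vb.empty:
                continue
            for test in tests:
                r = compare_groups(va, vb, test=test, labels=(str(ga), str(gb)),
                                   alpha=alpha)
                comparisons.append({
                    "metric": metric, "group_a": r.group_a, "group_b": r.group_b,
                    "test": r.test, "p_value": r.p_value,
                    "significant": r.significant,
                })
    return pd.DataFrame(summaries), pd.DataFrame(comparisons)
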