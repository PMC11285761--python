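"""One-way ANOVA with Tukey-Kramer post hoc comparisons across tissue regions.

Used at two granularities, mirroring how the two modalities are sampled:
XRD metrics are compared per scan pixel, pSHG organization per acquisition
mean.  The Tukey-Kramer form of the studentized-range test allows unequal
group sizes; tail probabilities come from scipy's studentized_range
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Significance tiers and their conventional star annotations.
STAR_TIERS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p: float) -> str:
    for tier, stars in STAR_TIERS:
        if p < tier:
            return stars
    return "n.s."


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    ms_within: float
    group_means: dict
    group_sizes: dict


def _split_groups(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have the same length")
    keep = np.isfinite(values)
    values, groups = values[keep], groups[keep]
    labels = list(dict.fromkeys(groups))  # first-appearance order
    data = {lab: values[groups == lab] for lab in labels}
    return data


def one_way_anova(values, groups) -> AnovaResult:
    """Classical one-way ANOVA: F = MS_between / MS_within.

    Requires at least two groups with at least two values each; identical
    data in every cell (zero between- and within-group variance) is an
    undefined F and raises.
    """
    data = _split_groups(values, groups)
    if len(data) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for lab, v in data.items():
        if v.size < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 values")
    all_vals = np.concatenate(list(data.values()))
    grand = all_vals.mean()
    n_total = all_vals.size
    k = len(data)
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in data.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    df_b, df_w = k - 1, n_total - k
    ms_within = ss_within / df_w
    if ss_within == 0.0 and ss_between == 0.0:
        raise ValueError("zero between- and within-group variance: F undefined")
    if ms_within == 0.0:
        f = np.inf
        p = 0.0
    else:
        f = (ss_between / df_b) / ms_within
        p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(
        f_statistic=float(f),
        p_value=p,
        df_between=df_b,
        df_within=df_w,
        ms_within=float(ms_within),
        group_means={lab: float(v.mean()) for lab, v in data.items()},
        group_sizes={lab: int(v.size) for lab, v in data.items()},
    )


def tukey_kramer(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """All unordered pairwise comparisons after one-way ANOVA.

    q = |mean_i - mean_j| / sqrt(MS_within/2 * (1/n_i + 1/n_j)); adjusted p
    from the studentized-range distribution with k groups and N - k error
    degrees of freedom.  Pairs involving a singleton group are flagged
    untestable (NaN statistics).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    data = _split_groups(values, groups)
    if len(data) < 2:
        raise ValueError("need at least two groups")
    labels = list(data)
    sizes = {lab: v.size for lab, v in data.items()}
    means = {lab: v.mean() for lab, v in data.items()}
    k = len(labels)
    n_total = sum(sizes.values())
    df_w = n_total - k
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    ms_within = ss_within / df_w if df_w > 0 else np.nan

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = labels[i], labels[j]
            testable = sizes[a] > 1 and sizes[b] > 1 and np.isfinite(ms_within)
            diff = means[a] - means[b]
            if testable and ms_within > 0:
                se = np.sqrt(ms_within / 2.0 * (1.0 / sizes[a] + 1.0 / sizes[b]))
                q = abs(diff) / se
                p_adj = float(sps.studentized_range.sf(q, k, df_w))
            elif testable and ms_within == 0.0:
                se = 0.0
                q = np.inf if diff != 0 else 0.0
                p_adj = 0.0 if diff != 0 else 1.0
            else:
                se = q = p_adj = np.nan
            rows.append(
                dict(
                    group1=a,
                    group2=b,
                    mean_diff=float(diff),
                    se=float(se) if np.isfinite(se) else np.nan,
                    q=float(q) if np.isfinite(q) else q,
                    p_adj=p_adj,
                    significant=bool(p_adj < alpha) if np.isfinite(p_adj) else False,
                    stars=significance_stars(p_adj) if np.isfinite(p_adj) else "untestable",
                    testable=bool(testable),
                )
            )
    return pd.DataFrame(rows)


def compare_regions(
    df: pd.DataFrame, value_col: str, group_col: str = "label", alpha: float = 0.05
) -> dict:
    """ANOVA + Tukey-Kramer report for one metric column of a table."""
    sub = df[[value_col, group_col]].dropna()
    anova = one_way_anova(sub[value_col], sub[group_col])
    pairwise = tukey_kramer(sub[value_col], sub[group_col], alpha=alpha)
    return {
        "metric": value_col,
        "alpha": alpha,
        "f_statistic": anova.f_statistic,
        "anova_p": anova.p_value,
        "df": [anova.df_between, anova.df_within],
        "group_means": anova.group_means,
        "group_sizes": anova.group_sizes,
        "pairwise": pairwise,
    }
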