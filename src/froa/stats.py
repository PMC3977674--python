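"""Group-level inference: split-plot ANOVA, planned comparisons, two-sample tests.

The central analysis is a balanced split-plot (mixed) ANOVA with one
between-subjects factor (task group) and one within-subjects factor (ROI
model), computed from the closed-form sums of squares:

    SS_task           = n*b * sum_g (m_g.. - m...)^2
    SS_subj(group)    = b   * sum_gs (m_gs. - m_g..)^2     (between error)
    SS_model          = a*n * sum_m (m..m - m...)^2
    SS_task_x_model   = n   * sum_gm (m_g.m - m_g.. - m..m + m...)^2
    SS_within_error   = SS_total - all of the above        (model x subj(group))

with F(task) tested against subjects-within-groups, and F(model),
F(interaction) against the within error.  Partial eta squared is
SS_effect / (SS_effect + SS_error_used).  Unbalanced input is an error; no
imputation is done.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "mixed_anova",
    "planned_comparisons",
    "independent_ttest",
    "paired_ttest",
    "mann_whitney",
    "two_sample_tests",
]

_EPS = 1e-12


@dataclass
class ComparisonResult:
    """One contrast: label, statistic (t or U), df (if applicable), two-sided p."""

    label: str
    statistic: float
    df: float | None
    p: float
    kind: str = "t"
    note: str = ""


def _f_p(f: float, df1: int, df2: int) -> float:
    return float(sps.f.sf(f, df1, df2))


def mixed_anova(
    table: pd.DataFrame,
    dv: str = "mmc",
    within: str = "model",
    between: str = "group",
    subject: str = "participant",
) -> pd.DataFrame:
    """Balanced split-plot ANOVA.

    Returns a table with rows for the between effect, the within effect, the
    interaction and the two error strata; columns
    ``effect,SS,df,MS,F,p,pes``.  Zero-variance conventions: an effect with
    SS ~ 0 is reported as F = 0, p = 1; a non-zero effect over a zero error
    stratum as F = inf, p = 0.
    """
    df = table[[subject, between, within, dv]].dropna()
    wide = df.pivot_table(index=[subject, between], columns=within, values=dv, aggfunc="count")
    if wide.isna().any().any() or (wide != 1).any().any():
        raise ValueError("design must be complete: every subject needs each within level once")
    groups = sorted(df[between].unique())
    n_per = [df[df[between] == g][subject].nunique() for g in groups]
    if len(set(n_per)) != 1:
        raise ValueError(f"unbalanced design: participants per group {dict(zip(groups, n_per))}")
    a, n = len(groups), n_per[0]
    levels = sorted(df[within].unique())
    b = len(levels)
    if n < 2:
        raise ValueError("need >= 2 participants per group")

    y = df[dv].to_numpy()
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))
    m_g = df.groupby(between)[dv].mean()
    ss_task = n * b * float(np.sum((m_g - grand) ** 2))
    m_gs = df.groupby([between, subject])[dv].mean()
    ss_subj = b * float(np.sum((m_gs - m_gs.index.get_level_values(0).map(m_g)) ** 2))
    m_m = df.groupby(within)[dv].mean()
    ss_model = a * n * float(np.sum((m_m - grand) ** 2))
    m_gm = df.groupby([between, within])[dv].mean()
    dev = (
        m_gm
        - m_gm.index.get_level_values(0).map(m_g)
        - m_gm.index.get_level_values(1).map(m_m)
        + grand
    )
    ss_inter = n * float(np.sum(dev**2))
    ss_err_w = ss_total - ss_task - ss_subj - ss_model - ss_inter
    ss_err_w = max(ss_err_w, 0.0)

    df_task, df_subj = a - 1, a * (n - 1)
    df_model, df_inter = b - 1, (a - 1) * (b - 1)
    df_err_w = a * (n - 1) * (b - 1)

    def row(effect, ss, dfree, err_ss, err_df):
        ms = ss / dfree if dfree else np.nan
        err_ms = err_ss / err_df if err_df else np.nan
        if ss <= _EPS * max(ss_total, 1.0):
            f, p = 0.0, 1.0
        elif err_ms <= _EPS:
            f, p = math.inf, 0.0
        else:
            f = ms / err_ms
            p = _f_p(f, dfree, err_df)
        pes = ss / (ss + err_ss) if (ss + err_ss) > 0 else 0.0
        return dict(effect=effect, SS=ss, df=dfree, MS=ms, F=f, p=p, pes=pes)

    rows = [
        row(between, ss_task, df_task, ss_subj, df_subj),
        dict(
            effect=f"subjects({between})", SS=ss_subj, df=df_subj,
            MS=ss_subj / df_subj, F=np.nan, p=np.nan, pes=np.nan,
        ),
        row(within, ss_model, df_model, ss_err_w, df_err_w),
        row(f"{between} x {within}", ss_inter, df_inter, ss_err_w, df_err_w),
        dict(
            effect=f"{within} x subjects({between})", SS=ss_err_w, df=df_err_w,
            MS=ss_err_w / df_err_w if df_err_w else np.nan, F=np.nan, p=np.nan, pes=np.nan,
        ),
    ]
    return pd.DataFrame(rows)


def _finite_t(t: float, dfree: float) -> tuple[float, float, str]:
    if np.isnan(t):
        return 0.0, 1.0, "zero-variance: identical samples"
    if np.isinf(t):
        return t, 0.0, "zero-variance: constant non-zero difference"
    return t, 2 * float(sps.t.sf(abs(t), dfree)), ""


def paired_ttest(x: np.ndarray, y: np.ndarray, label: str = "paired") -> ComparisonResult:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("paired test needs two equal-length samples with n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    dfree = len(d) - 1
    if sd <= _EPS:
        t = 0.0 if abs(d.mean()) <= _EPS else math.copysign(math.inf, d.mean())
    else:
        t = d.mean() / (sd / math.sqrt(len(d)))
    t, p, note = _finite_t(t, dfree)
    return ComparisonResult(label, t, dfree, p, "t", note)


def independent_ttest(
    x: np.ndarray, y: np.ndarray, label: str = "independent", pooled: bool = True
) -> ComparisonResult:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("independent test needs n >= 2 per group")
    if pooled:
        n1, n2 = len(x), len(y)
        dfree = n1 + n2 - 2
        sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / dfree
        if sp2 <= _EPS:
            diff = x.mean() - y.mean()
            t = 0.0 if abs(diff) <= _EPS else math.copysign(math.inf, diff)
        else:
            t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        t, p, note = _finite_t(t, dfree)
        return ComparisonResult(label, t, dfree, p, "t", note)
    res = sps.ttest_ind(x, y, equal_var=False)
    return ComparisonResult(label, float(res.statistic), float(res.df), float(res.pvalue), "t")


def planned_comparisons(
    table: pd.DataFrame,
    dv: str = "mmc",
    within: str = "model",
    between: str = "group",
    subject: str = "participant",
    bonferroni: bool = False,
) -> list[ComparisonResult]:
    """Within-task paired t-tests between model pairs, and between-task
    independent t-tests for each model.  Two-sided, uncorrected by default."""
    wide = table.pivot_table(index=[between, subject], columns=within, values=dv)
    if wide.isna().any().any():
        raise ValueError("planned comparisons require a complete design")
    groups = sorted(table[between].unique())
    levels = sorted(table[within].unique())
    out: list[ComparisonResult] = []
    for g in groups:
        sub = wide.loc[g]
        for m1, m2 in combinations(levels, 2):
            out.append(paired_ttest(sub[m1], sub[m2], f"{g}: {m1} vs {m2}"))
    for m in levels:
        for g1, g2 in combinations(groups, 2):
            out.append(
                independent_ttest(wide.loc[g1][m], wide.loc[g2][m], f"{m}: {g1} vs {g2}")
            )
    if bonferroni:
        k = len(out)
        for r in out:
            r.p = min(1.0, r.p * k)
    return out


def _enumerate_mw_p(x: np.ndarray, y: np.ndarray, alternative: str) -> tuple[float, float]:
    """Exact Mann-Whitney p by full enumeration of group assignments (handles ties)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1, n2 = len(x), len(y)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    mu = n1 * n2 / 2
    count_ge = count_le = count_two = total = 0
    for idx in combinations(range(n1 + n2), n1):
        u = float(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
        total += 1
        count_ge += u >= u_obs
        count_le += u <= u_obs
        count_two += abs(u - mu) >= abs(u_obs - mu) - 1e-12
    if alternative == "greater":
        p = count_ge / total
    elif alternative == "less":
        p = count_le / total
    else:
        p = count_two / total
    return u_obs, min(p, 1.0)


def mann_whitney(
    x: np.ndarray, y: np.ndarray, label: str = "mann-whitney",
    alternative: str = "two-sided", exact_max_n: int = 12,
) -> ComparisonResult:
    """Mann-Whitney U with an exact p for small samples.

    The p-value is exact (scipy's recurrence) when there are no ties and
    min(n) <= ``exact_max_n``; with ties, full enumeration is used when the
    number of group assignments is modest; otherwise the tie-corrected normal
    approximation.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("mann_whitney needs n >= 2 per group")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    small = min(len(x), len(y)) <= exact_max_n
    if small and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative=alternative, method="exact")
        return ComparisonResult(label, float(res.statistic), None, float(res.pvalue), "U")
    if small and math.comb(len(x) + len(y), len(x)) <= 50_000:
        u, p = _enumerate_mw_p(x, y, alternative)
        return ComparisonResult(label, u, None, p, "U", "exact enumeration with ties")
    res = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return ComparisonResult(label, float(res.statistic), None, float(res.pvalue), "U",
                            "normal approximation")


def two_sample_tests(
    metrics_table: pd.DataFrame,
    group_col: str = "group",
    metric_cols: tuple[str, ...] = ("mean_amplitude_deg", "mean_dwell_ms"),
    nonparametric: tuple[str, ...] = (),
    pooled: bool = True,
) -> list[ComparisonResult]:
    """Between-group tests on per-participant metrics.

    Parametric metrics get independent-samples t-tests (pooled variance by
    default, Welch optional); metrics listed in ``nonparametric`` (accuracy,
    typically) get Mann-Whitney U tests.
    """
    groups = sorted(metrics_table[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    g1 = metrics_table[metrics_table[group_col] == groups[0]]
    g2 = metrics_table[metrics_table[group_col] == groups[1]]
    out = []
    for col in metric_cols:
        x, y = g1[col].dropna().to_numpy(), g2[col].dropna().to_numpy()
        label = f"{col}: {groups[0]} vs {groups[1]}"
        if col in nonparametric:
            out.append(mann_whitney(x, y, label))
        else:
            out.append(independent_ttest(x, y, label, pooled=pooled))
    return out
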