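"""Behavioural statistics: Group x Task mixed-design ANOVA with
Greenhouse-Geisser correction, simple main effects and Bonferroni
post hocs.

The ANOVA is authored here (rather than delegated wholesale) because the
sphericity correction must apply to the Group x Task interaction as well
as the Task main effect: epsilon is estimated once from the pooled
within-group covariance of the task conditions and multiplies the degrees
of freedom of every within-subject term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from dyadscan.core import DyadscanError

__all__ = [
    "rmanova_gg",
    "gg_epsilon",
    "simple_main_effects",
    "posthoc_bonferroni",
    "RmAnovaResult",
]


def _to_wide(
    data: pd.DataFrame, dv: str, within: str, between: str, subject: str
):
    """Pivot to (subjects x conditions); error on missing cells."""
    wide = data.pivot_table(
        index=[subject, between], columns=within, values=dv, aggfunc="mean"
    )
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise DyadscanError(f"missing within-subject cells for: {missing[:5]}")
    counts = data.groupby([subject, within]).size()
    if (counts != 1).any():
        raise DyadscanError("expected exactly one observation per subject x condition")
    return wide


def gg_epsilon(wide_values: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a (subjects x conditions) matrix.

    Computed from the doubly-centred sample covariance of the condition
    scores: eps = trace(M)^2 / ((k-1) trace(M M)) with M = C S C and C the
    k x k centring matrix. Bounded in [1/(k-1), 1]; equals 1 exactly for
    k = 2.
    """
    x = np.asarray(wide_values, dtype=float)
    n, k = x.shape
    if k < 2:
        raise DyadscanError("need at least two within-subject conditions")
    if n < 2:
        raise DyadscanError("need at least two subjects")
    s = np.cov(x, rowvar=False)
    c = np.eye(k) - np.ones((k, k)) / k
    m = c @ s @ c
    denom = (k - 1) * np.trace(m @ m)
    if denom <= 0:
        return 1.0
    eps = np.trace(m) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _pooled_gg_epsilon(wide: pd.DataFrame, between_level) -> float:
    """Epsilon from the within-group pooled covariance (group means
    removed so between-group separation cannot masquerade as
    non-sphericity)."""
    k = wide.shape[1]
    groups = wide.index.get_level_values(between_level)
    pooled = np.zeros((k, k))
    dof = 0
    for g in pd.unique(groups):
        block = wide.values[groups == g]
        if block.shape[0] < 2:
            continue
        pooled += (block.shape[0] - 1) * np.cov(block, rowvar=False)
        dof += block.shape[0] - 1
    if dof == 0:
        raise DyadscanError("every group needs at least two subjects")
    s = pooled / dof
    c = np.eye(k) - np.ones((k, k)) / k
    m = c @ s @ c
    denom = (k - 1) * np.trace(m @ m)
    if denom <= 0:
        return 1.0
    return float(np.clip(np.trace(m) ** 2 / denom, 1.0 / (k - 1), 1.0))


@dataclass
class RmAnovaResult:
    """Mixed-design ANOVA table plus the sphericity estimate."""

    table: pd.DataFrame
    epsilon: float
    cell_means: pd.DataFrame

    def effect(self, source: str) -> pd.Series:
        return self.table.set_index("source").loc[source]


def rmanova_gg(
    data: pd.DataFrame,
    dv: str = "accuracy",
    within: str = "condition",
    between: str = "group",
    subject: str = "subject",
) -> RmAnovaResult:
    """Two-way mixed ANOVA (between Group, within Task) with GG correction.

    Sums of squares follow the classical partition: between-subject
    variation splits into Group and subject-within-group error; within-
    subject variation splits into Task, Group x Task and the within error.
    Greenhouse-Geisser epsilon multiplies the df of Task and of the
    interaction; corrected p values never fall below the uncorrected ones.
    """
    wide = _to_wide(data, dv, within, between, subject)
    y = wide.values  # (N, k)
    n_total, k = y.shape
    groups = wide.index.get_level_values(between)
    group_levels = list(pd.unique(groups))
    n_g = np.array([(groups == g).sum() for g in group_levels])
    if len(group_levels) < 2:
        raise DyadscanError("need at least two groups")
    if (n_g < 2).any():
        raise DyadscanError("every group needs at least two subjects")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_means = np.array([subj_means[groups == g].mean() for g in group_levels])
    cond_means = y.mean(axis=0)
    cell = np.vstack([y[groups == g].mean(axis=0) for g in group_levels])

    ss_total = float(((y - grand) ** 2).sum())
    ss_between_subj = float(k * ((subj_means - grand) ** 2).sum())
    ss_group = float(k * (n_g * (group_means - grand) ** 2).sum())
    ss_subj_err = ss_between_subj - ss_group
    ss_within = ss_total - ss_between_subj
    ss_task = float(n_total * ((cond_means - grand) ** 2).sum())
    inter = cell - group_means[:, None] - cond_means[None, :] + grand
    ss_inter = float((n_g[:, None] * inter**2).sum())
    ss_err_within = ss_within - ss_task - ss_inter

    g = len(group_levels)
    df_group, df_subj = g - 1, n_total - g
    df_task, df_inter = k - 1, (g - 1) * (k - 1)
    df_errw = (n_total - g) * (k - 1)

    eps = _pooled_gg_epsilon(wide, between)

    def row(source, ss, df1, ss_err, df2, within_term):
        ms, ms_e = ss / df1, ss_err / df2
        f = ms / ms_e if ms_e > 0 else np.inf
        p = float(stats.f.sf(f, df1, df2))
        d1c, d2c = (df1 * eps, df2 * eps) if within_term else (df1, df2)
        p_gg = float(stats.f.sf(f, d1c, d2c))
        return {
            "source": source,
            "SS": ss,
            "df1": df1,
            "df2": df2,
            "MS": ms,
            "F": f,
            "p_unc": p,
            "eps": eps if within_term else np.nan,
            "df1_gg": d1c if within_term else df1,
            "df2_gg": d2c if within_term else df2,
            "p_gg": p_gg if within_term else p,
        }

    table = pd.DataFrame(
        [
            row(between, ss_group, df_group, ss_subj_err, df_subj, False),
            row(within, ss_task, df_task, ss_err_within, df_errw, True),
            row(
                f"{between} x {within}",
                ss_inter,
                df_inter,
                ss_err_within,
                df_errw,
                True,
            ),
        ]
    )
    cell_means = pd.DataFrame(cell, index=group_levels, columns=wide.columns)
    return RmAnovaResult(table=table, epsilon=eps, cell_means=cell_means)


def simple_main_effects(
    data: pd.DataFrame,
    dv: str = "accuracy",
    within: str = "condition",
    between: str = "group",
) -> pd.DataFrame:
    """One-way Group ANOVA separately for each task condition.

    This is the follow-up run when the Group x Task interaction is
    present: it localises which conditions carry the group difference.
    """
    rows = []
    for cond, grp in data.groupby(within, sort=False):
        samples = [g[dv].values for _, g in grp.groupby(between)]
        if len(samples) < 2:
            raise DyadscanError("need at least two groups")
        if any(len(s) < 2 for s in samples):
            raise DyadscanError(f"{cond}: every group needs >= 2 subjects")
        f, p = stats.f_oneway(*samples)
        df1 = len(samples) - 1
        df2 = sum(len(s) for s in samples) - len(samples)
        rows.append({"condition": cond, "F": float(f), "df1": df1, "df2": df2, "p": float(p)})
    return pd.DataFrame(rows)


def posthoc_bonferroni(
    data: pd.DataFrame,
    condition,
    dv: str = "accuracy",
    within: str = "condition",
    between: str = "group",
) -> pd.DataFrame:
    """Pairwise group comparisons within one condition, Bonferroni
    adjusted: p_adj = min(1, m p) over the m pairwise tests. Returns a
    symmetric matrix of adjusted p values (NaN diagonal)."""
    grp = data[data[within] == condition]
    if grp.empty:
        raise DyadscanError(f"no rows for condition {condition!r}")
    levels = list(pd.unique(grp[between]))
    m = len(levels) * (len(levels) - 1) // 2
    out = pd.DataFrame(np.nan, index=levels, columns=levels)
    for i, g1 in enumerate(levels):
        for g2 in levels[i + 1 :]:
            a = grp.loc[grp[between] == g1, dv].values
            b = grp.loc[grp[between] == g2, dv].values
            _, p = stats.ttest_ind(a, b)
            p_adj = min(1.0, m * float(p))
            out.loc[g1, g2] = p_adj
            out.loc[g2, g1] = p_adj
    return out
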