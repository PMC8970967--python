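"""Dispatched statistics layer.

Two-group comparisons are dispatched by a normality check per group
(Shapiro-Wilk, a reproducible surrogate for visual QQ inspection): if both
groups look normal, an F test on the variances decides between Student's and
Welch's unpaired t test; otherwise the Mann-Whitney U test is used.
Multi-group comparisons use one-way or two-way ANOVA followed by Tukey's
multiple-comparison test.  Summaries are mean +/- SEM with fold change
against a named control group.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .datatypes import GroupComparison, GroupSummary

__all__ = ["compare_two_groups", "compare_multi_groups", "summarize_groups"]


def _shapiro_p(x: np.ndarray) -> float:
    """Shapiro-Wilk p-value; constant samples count as non-normal."""
    if np.ptp(x) == 0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(x).pvalue)


def _f_test_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F test for equality of variances."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if vb == 0 and va == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    cdf = sps.f.cdf(f, dfa, dfb)
    return float(2 * min(cdf, 1 - cdf))


def compare_two_groups(
    a, b, alpha: float = 0.05, name_a: str = "a", name_b: str = "b",
    normality_alpha: float = 0.01,
) -> GroupComparison:
    """Normality-dispatched two-group comparison with full trace.

    Dispatch: Shapiro-Wilk per group at ``normality_alpha``; both normal ->
    F test on variances at ``alpha`` chooses Student's vs Welch's t;
    otherwise Mann-Whitney U (two-sided).  The normality pre-test runs at a
    stricter default level (0.01) than the comparison itself: at 0.05 per
    group, one in ten genuinely normal comparisons would be misrouted to the
    rank test, which both dilutes the intended parametric branch and
    inflates its realized type-I error; 0.01 keeps near-unit power against
    clearly skewed data.  Two zero-variance groups with equal means return
    p = 1 by convention.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs n >= 3")
    trace: dict = dict(alpha=alpha, n_a=len(x), n_b=len(y),
                       normality_test="shapiro_wilk",
                       normality_alpha=normality_alpha)

    if np.ptp(x) == 0 and np.ptp(y) == 0:
        equal = x[0] == y[0]
        trace["degenerate"] = "both groups constant"
        return GroupComparison(
            group_a=name_a, group_b=name_b, test="student_t",
            statistic=0.0 if equal else float("inf"),
            p_value=1.0 if equal else 0.0, alpha=alpha, trace=trace,
        )

    p_na, p_nb = _shapiro_p(x), _shapiro_p(y)
    trace["normality_p_a"] = p_na
    trace["normality_p_b"] = p_nb
    if p_na > normality_alpha and p_nb > normality_alpha:
        p_var = _f_test_p(x, y)
        trace["variance_test"] = "f_test"
        trace["variance_p"] = p_var
        equal_var = p_var > alpha
        res = sps.ttest_ind(x, y, equal_var=equal_var)
        test = "student_t" if equal_var else "welch_t"
        stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(stat):  # identical constant-free degenerate case
            stat, p = 0.0, 1.0
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
        test = "mann_whitney"
        stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        group_a=name_a, group_b=name_b, test=test,
        statistic=stat, p_value=min(max(p, 0.0), 1.0), alpha=alpha, trace=trace,
    )


def compare_multi_groups(
    table: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    design: str = "one_way",
    factors: tuple[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ANOVA followed by Tukey's multiple-comparison test.

    ``design="one_way"`` groups by ``group``; ``design="two_way"`` fits a
    balanced factorial with interaction on ``factors`` and rejects
    unbalanced designs rather than silently refitting.  Returns the ANOVA
    table and the Tukey pairwise table (adjusted p-values).
    """
    if design == "one_way":
        groups = [g[value].to_numpy(dtype=float) for _, g in table.groupby(group)]
        if len(groups) < 2:
            raise ValueError("need at least 2 groups")
        f, p = sps.f_oneway(*groups)
        anova = pd.DataFrame(
            dict(source=["group"], F=[float(f)], p_value=[float(p)])
        )
        tuk = pairwise_tukeyhsd(
            table[value].to_numpy(dtype=float), table[group].to_numpy(), alpha=0.05
        )
        tukey = pd.DataFrame(
            tuk.summary().data[1:], columns=tuk.summary().data[0]
        )
        return anova, tukey
    if design == "two_way":
        if factors is None or len(factors) != 2:
            raise ValueError("two_way design requires two factor column names")
        f1, f2 = factors
        cells = table.groupby([f1, f2]).size()
        n1, n2 = table[f1].nunique(), table[f2].nunique()
        if len(cells) != n1 * n2 or cells.nunique() != 1:
            raise ValueError(
                "two-way ANOVA here requires a complete balanced factorial; "
                "unbalanced designs are not supported"
            )
        model = ols(f"{value} ~ C({f1}) * C({f2})", data=table).fit()
        anova = anova_lm(model, typ=2).reset_index(names="source")
        combo = (table[f1].astype(str) + ":" + table[f2].astype(str)).to_numpy()
        tuk = pairwise_tukeyhsd(table[value].to_numpy(dtype=float), combo, alpha=0.05)
        tukey = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])
        return anova, tukey
    raise ValueError(f"unknown design {design!r}")


def summarize_groups(
    table: pd.DataFrame,
    control: str,
    value: str = "value",
    group: str = "group",
) -> list[GroupSummary]:
    """Per-group n, mean, SEM (sample SD / sqrt(n)), fold change vs control.

    A zero control mean leaves fold changes undefined
    (``fold_change_defined=False``) rather than raising.
    """
    if control not in set(table[group]):
        raise ValueError(f"control group {control!r} not present")
    out: list[GroupSummary] = []
    means = table.groupby(group)[value].mean()
    ctrl_mean = float(means[control])
    for g, sub in table.groupby(group):
        vals = sub[value].to_numpy(dtype=float)
        if len(vals) == 0:
            raise ValueError(f"empty group {g!r}")
        n = len(vals)
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        defined = ctrl_mean != 0.0
        out.append(
            GroupSummary(
                group=str(g), n=n, mean=float(np.mean(vals)), sem=sem,
                fold_change=float(np.mean(vals)) / ctrl_mean if defined else None,
                fold_change_defined=defined,
            )
        )
    return out
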