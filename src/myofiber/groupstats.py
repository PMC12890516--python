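"""Group comparisons at fiber level and subject-average level.

Cohort readouts (P1, P2, T1, T2, ATP score) are reported twice: once pooling
individual fibers and once after averaging fibers within each subject, so
that both the fiber-to-fiber spread and the per-subject effect are visible.
Two groups are compared with Welch's unequal-variance t-test; three or more
with one-way ANOVA plus Tukey HSD; factorial designs (genotype x treatment)
with two-way ANOVA (type-II sums of squares) plus Tukey HSD on cell means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .exceptions import InvalidInputError

#: Default significance threshold.
ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one group comparison.

    For one-factor tests ``statistic``/``df``/``p_value`` are scalars (df is a
    pair for ANOVA); for two-way ANOVA they are dicts keyed by effect
    (``factor_a``, ``factor_b``, ``interaction``).  ``pairwise`` holds
    Tukey-adjusted p-values per group pair when a post hoc was run.
    """

    statistic: float | dict
    df: float | tuple | dict
    p_value: float | dict
    pairwise: list[tuple[tuple[str, str], float]] | None = None


def _check_groups(groups: dict[str, np.ndarray], min_n: int = 2) -> None:
    for name, vals in groups.items():
        if len(vals) < min_n:
            raise InvalidInputError(
                f"group {name!r} has n={len(vals)} < {min_n}"
            )


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> ComparisonResult:
    """Two-sided unpaired t-test with Welch's correction.

    Uses the Welch-Satterthwaite degrees of freedom; requires n >= 2 per
    group and nonzero variance in at least one group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_groups({"a": a, "b": b})
    if np.var(a) == 0 and np.var(b) == 0:
        raise InvalidInputError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
    )


def anova_tukey(values: Sequence[float], group: Sequence[str]) -> ComparisonResult:
    """One-way ANOVA with Tukey HSD post hoc on all group pairs."""
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) < 2:
        raise InvalidInputError("one-way ANOVA needs at least 2 groups")
    arrays = {str(g): values[group == g] for g in levels}
    _check_groups(arrays)
    f_stat, p = stats.f_oneway(*arrays.values())
    tukey = pairwise_tukeyhsd(values, group)
    pairs = [
        ((str(g1), str(g2)), float(padj))
        for (g1, g2), padj in zip(
            [(r[0], r[1]) for r in tukey.summary().data[1:]], tukey.pvalues
        )
    ]
    k, n = len(levels), len(values)
    return ComparisonResult(
        statistic=float(f_stat),
        df=(float(k - 1), float(n - k)),
        p_value=float(p),
        pairwise=pairs,
    )


def two_way_anova_tukey(
    values: Sequence[float],
    factor_a: Sequence[str],
    factor_b: Sequence[str],
) -> ComparisonResult:
    """Two-way ANOVA (type-II SS) with Tukey HSD on the cell means.

    Intended for balanced or near-balanced layouts (genotype x treatment),
    where type-II and type-I sums of squares coincide.  Every cell must have
    n >= 2.
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "a": np.asarray(factor_a).astype(str),
            "b": np.asarray(factor_b).astype(str),
        }
    )
    cells = df.groupby(["a", "b"]).size()
    full = len(df["a"].unique()) * len(df["b"].unique())
    if len(cells) < full or (cells < 2).any():
        raise InvalidInputError("every factor cell must contain n >= 2 values")
    model = ols("value ~ C(a) * C(b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    eff = {"factor_a": "C(a)", "factor_b": "C(b)", "interaction": "C(a):C(b)"}
    df_resid = float(table.loc["Residual", "df"])
    stat = {k: float(table.loc[v, "F"]) for k, v in eff.items()}
    pval = {k: float(table.loc[v, "PR(>F)"]) for k, v in eff.items()}
    dof = {k: (float(table.loc[v, "df"]), df_resid) for k, v in eff.items()}
    cell_label = df["a"] + ":" + df["b"]
    tukey = pairwise_tukeyhsd(df["value"].to_numpy(), cell_label.to_numpy())
    pairs = [
        ((str(r[0]), str(r[1])), float(padj))
        for r, padj in zip(tukey.summary().data[1:], tukey.pvalues)
    ]
    return ComparisonResult(statistic=stat, df=dof, p_value=pval, pairwise=pairs)


def aggregate_by_subject(
    fiber_values: pd.DataFrame,
    value_cols: Sequence[str] | None = None,
    subject_col: str = "subject_id",
    carry_cols: Sequence[str] = ("group", "treatment"),
) -> pd.DataFrame:
    """Average fiber-level values within each subject.

    Returns one row per subject with the mean of every value column, the
    fiber count ``n_fibers``, and any carried label columns (which must be
    constant within subject).
    """
    if fiber_values.empty:
        return pd.DataFrame(columns=[subject_col, "n_fibers"])
    if subject_col not in fiber_values.columns:
        raise InvalidInputError(f"missing subject column {subject_col!r}")
    if value_cols is None:
        value_cols = [
            c
            for c in fiber_values.select_dtypes("number").columns
            if c != subject_col
        ]
    carry = [c for c in carry_cols if c in fiber_values.columns]
    grouped = fiber_values.groupby(subject_col, sort=True)
    out = grouped[list(value_cols)].mean()
    out["n_fibers"] = grouped.size()
    for c in carry:
        first = grouped[c].first()
        if (grouped[c].nunique() > 1).any():
            raise InvalidInputError(f"column {c!r} is not constant within subject")
        out[c] = first
    return out.reset_index()


def comparisons_table(
    fits: pd.DataFrame,
    value_cols: Sequence[str] = ("p1", "p2", "t1", "t2", "atp_corrected"),
    group_col: str = "group",
    subject_col: str = "subject_id",
) -> pd.DataFrame:
    """Tidy fiber-level and subject-level comparison results for a fit table.

    For each variable, runs Welch's t-test (two groups) or one-way ANOVA with
    Tukey HSD (more) at both levels.  Columns: variable, level, contrast,
    statistic, p, p_adj (Tukey-adjusted when applicable).
    """
    levels = {"fiber": fits}
    if subject_col in fits.columns and fits[subject_col].astype(bool).any():
        levels["subject"] = aggregate_by_subject(
            fits, value_cols=value_cols, subject_col=subject_col
        )
    rows = []
    for level_name, table in levels.items():
        groups = pd.unique(table[group_col])
        for var in value_cols:
            if var not in table.columns:
                continue
            clean = table.dropna(subset=[var])
            if len(groups) == 2:
                g1, g2 = groups
                res = welch_t_test(
                    clean.loc[clean[group_col] == g1, var],
                    clean.loc[clean[group_col] == g2, var],
                )
                rows.append(
                    {
                        "variable": var,
                        "level": level_name,
                        "contrast": f"{g1} vs {g2}",
                        "test": "welch_t",
                        "statistic": res.statistic,
                        "p": res.p_value,
                        "p_adj": np.nan,
                    }
                )
            else:
                res = anova_tukey(clean[var], clean[group_col])
                rows.append(
                    {
                        "variable": var,
                        "level": level_name,
                        "contrast": "omnibus",
                        "test": "anova_f",
                        "statistic": res.statistic,
                        "p": res.p_value,
                        "p_adj": np.nan,
                    }
                )
                for (g1, g2), padj in res.pairwise or []:
                    rows.append(
                        {
                            "variable": var,
                            "level": level_name,
                            "contrast": f"{g1} vs {g2}",
                            "test": "tukey_hsd",
                            "statistic": np.nan,
                            "p": np.nan,
                            "p_adj": padj,
                        }
                    )
    return pd.DataFrame(rows)
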