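"""Statistical linkage of mechanics indices, morphometry and grade.

Three analyses connect the pipeline outputs:

* simple (univariate) linear regression / correlation between tissue
  fraction and a log-scaled mechanics index (Pearson r, Spearman r_s, r^2,
  95% confidence band of the mean response);
* group comparisons: two-way ANOVA (Type-II sums of squares for the
  unbalanced cohort) with Bonferroni-adjusted pairwise contrasts, or
  one-way ANOVA with a Tukey-Kramer post hoc test;
* ordinal grade vs index correlation: Pearson on log10 of the index,
  Spearman on the raw index (rank-invariant to the log transform).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "StatsError",
    "CorrelationResult",
    "GroupComparisonResult",
    "correlate",
    "compare_groups",
    "repeated_compare_groups",
    "grade_correlation",
]


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationResult:
    r: float                 # Pearson (on the possibly log-transformed y)
    r_s: float               # Spearman rank coefficient (raw y)
    r2: float                # OLS coefficient of determination
    slope: float
    intercept: float
    n: int
    p_values: dict
    log_y: bool = False
    ci_x: np.ndarray | None = None        # grid for the confidence band
    ci_low: np.ndarray | None = None      # 95% CI of the mean response
    ci_high: np.ndarray | None = None

    def __post_init__(self):
        assert -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12
        assert -1.0 - 1e-12 <= self.r_s <= 1.0 + 1e-12


def correlate(x, y, log_y: bool = False) -> CorrelationResult:
    """Pearson/Spearman correlation and simple linear regression of y on x.

    With ``log_y`` the Pearson coefficient and the regression use
    log10(y) (y must be positive); Spearman always uses the raw values
    with average-rank tie handling.  For a simple regression r^2 equals the
    squared Pearson coefficient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise StatsError("x and y length mismatch")
    if len(x) < 3:
        raise StatsError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("zero variance in x or y")
    if log_y:
        if np.any(y <= 0):
            raise StatsError("log scale requires positive y")
        yy = np.log10(y)
    else:
        yy = y

    pear = sps.pearsonr(x, yy)
    spear = sps.spearmanr(x, y)
    res = sm.OLS(yy, sm.add_constant(x)).fit()
    grid = np.linspace(x.min(), x.max(), 50)
    pred = res.get_prediction(sm.add_constant(grid)).conf_int(alpha=0.05)
    return CorrelationResult(
        r=float(pear.statistic),
        r_s=float(spear.statistic),
        r2=float(res.rsquared),
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        n=len(x),
        p_values={
            "pearson": float(pear.pvalue),
            "spearman": float(spear.pvalue),
            "slope": float(res.pvalues[1]),
        },
        log_y=log_y,
        ci_x=grid,
        ci_low=pred[:, 0],
        ci_high=pred[:, 1],
    )


@dataclass(frozen=True)
class GroupComparisonResult:
    anova: pd.DataFrame          # F statistics per effect
    pairwise: pd.DataFrame       # raw and adjusted pairwise p-values
    group_stats: pd.DataFrame    # mean +/- sample SD per cell
    method: str
    n_comparisons: int


def _bonferroni_pairs(df, value, factor, within=None) -> pd.DataFrame:
    """Pooled-variance pairwise t tests with Bonferroni adjustment.

    When ``within`` is given, contrasts of ``factor`` are formed separately
    at each level of the second factor and the adjustment spans all of them.
    """
    rows = []
    levels_within = [None] if within is None else sorted(df[within].unique())
    for lw in levels_within:
        sub = df if lw is None else df[df[within] == lw]
        groups = sorted(sub[factor].unique())
        for a, b in combinations(groups, 2):
            xa = sub.loc[sub[factor] == a, value].to_numpy()
            xb = sub.loc[sub[factor] == b, value].to_numpy()
            if len(xa) < 2 or len(xb) < 2:
                continue
            t, p = sps.ttest_ind(xa, xb, equal_var=True)
            rows.append(
                {"level": lw, "group1": a, "group2": b, "t": float(t), "p_raw": float(p)}
            )
    out = pd.DataFrame(rows)
    m = len(out)
    if m:
        out["p_adj"] = np.minimum(1.0, out["p_raw"] * m)
    return out


def compare_groups(
    table: pd.DataFrame,
    value: str,
    factors,
    method: str = "bonferroni",
) -> GroupComparisonResult:
    """ANOVA with post hoc contrasts on a tidy table.

    ``factors`` is one or two column names.  Two factors: Type-II two-way
    ANOVA with interaction and Bonferroni pairwise contrasts of the first
    factor within each level of the second.  One factor: one-way ANOVA with
    either Bonferroni contrasts or a Tukey-Kramer test
    (``method="tukey"``, studentized-range based).
    """
    if isinstance(factors, str):
        factors = (factors,)
    factors = tuple(factors)
    df = table.copy()
    for f in factors + (value,):
        if f not in df.columns:
            raise StatsError(f"column {f!r} missing from table")

    if len(factors) == 2:
        f1, f2 = factors
        cells = df.groupby([f1, f2], observed=True)[value].count()
        if (cells < 1).any() or cells.empty:
            raise StatsError("each factor cell needs at least one observation")
        model = ols(f"{value} ~ C({f1}) * C({f2})", data=df).fit()
        anova = anova_lm(model, typ=2)
        pairwise = _bonferroni_pairs(df, value, f1, within=f2)
        stats = (
            df.groupby([f1, f2], observed=True)[value]
            .agg(mean="mean", sd=lambda v: np.std(v, ddof=1), n="count")
            .reset_index()
        )
        used = "bonferroni"
    else:
        (f1,) = factors
        model = ols(f"{value} ~ C({f1})", data=df).fit()
        anova = anova_lm(model, typ=2)
        if method == "tukey":
            tk = pairwise_tukeyhsd(df[value].to_numpy(), df[f1].to_numpy())
            pairwise = pd.DataFrame(
                tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
            )
            pairwise = pairwise.rename(columns={"p-adj": "p_adj"})
            used = "tukey-kramer"
        else:
            pairwise = _bonferroni_pairs(df, value, f1)
            used = "bonferroni"
        stats = (
            df.groupby(f1, observed=True)[value]
            .agg(mean="mean", sd=lambda v: np.std(v, ddof=1), n="count")
            .reset_index()
        )
    return GroupComparisonResult(
        anova=anova,
        pairwise=pairwise,
        group_stats=stats,
        method=used,
        n_comparisons=len(pairwise),
    )


def repeated_compare_groups(
    table: pd.DataFrame,
    value: str,
    subject: str,
    within: str,
    between: str,
) -> GroupComparisonResult:
    """Split-plot (repeated-measures) two-way ANOVA.

    Every subject is measured at every level of the ``within`` factor
    (frequency or PEEP) and belongs to one level of the ``between`` factor
    (grade group).  The between effect is tested on subject means against
    subjects-within-groups error; the within effect and the
    within-by-between interaction are tested against the residual after
    removing fixed subject blocks.
    """
    df = table.copy()
    for col in (value, subject, within, between):
        if col not in df.columns:
            raise StatsError(f"column {col!r} missing from table")
    const = df.groupby(subject)[between].nunique()
    if (const > 1).any():
        raise StatsError("the between factor must be constant within subject")

    means = df.groupby([subject, between], observed=True)[value].mean().reset_index()
    between_tab = anova_lm(ols(f"{value} ~ C({between})", data=means).fit(), typ=2)

    # within stratum: nested model comparisons after removing subject
    # blocks; the within factor is fully crossed with subjects, so the
    # sequential decomposition is exact
    m0 = ols(f"{value} ~ C({subject})", data=df).fit()
    m1 = ols(f"{value} ~ C({subject}) + C({within})", data=df).fit()
    m2 = ols(
        f"{value} ~ C({subject}) + C({within}) + C({within}):C({between})", data=df
    ).fit()
    cmp_f = anova_lm(m0, m1)
    cmp_int = anova_lm(m1, m2)

    def _row(cmp_tab, label):
        r = cmp_tab.iloc[1]
        return pd.DataFrame(
            {
                "sum_sq": [r["ss_diff"]],
                "df": [r["df_diff"]],
                "F": [r["F"]],
                "PR(>F)": [r["Pr(>F)"]],
            },
            index=[label],
        )

    anova = pd.concat(
        [
            between_tab.iloc[:1],
            _row(cmp_f, f"C({within})"),
            _row(cmp_int, f"C({within}):C({between})"),
        ]
    )
    pairwise = _bonferroni_pairs(df, value, between, within=within)
    stats = (
        df.groupby([between, within], observed=True)[value]
        .agg(mean="mean", sd=lambda v: np.std(v, ddof=1), n="count")
        .reset_index()
    )
    return GroupComparisonResult(
        anova=anova, pairwise=pairwise, group_stats=stats,
        method="split-plot+bonferroni", n_comparisons=len(pairwise),
    )


def grade_correlation(
    index_table: pd.DataFrame,
    grade_col: str = "grade",
    value_col: str = "e_het",
) -> CorrelationResult:
    """Ordinal grade (A0=0..A3=3) vs a positive mechanics index.

    Pearson is computed against log10 of the index (the index spans orders
    of magnitude across grades); Spearman uses the raw index.
    """
    g = index_table[grade_col].to_numpy(dtype=float)
    v = index_table[value_col].to_numpy(dtype=float)
    if len(np.unique(g)) < 2:
        raise StatsError("need at least two distinct grades")
    if np.any(v <= 0):
        raise StatsError("index values must be positive for the log scale")
    return correlate(g, v, log_y=True)
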