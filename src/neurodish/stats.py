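"""Two-group and factorial statistics used across all assays.

Provides the pooled-variance two-sample t-test (from raw samples or from
published mean/SEM/n summaries), fixed-effects two-way ANOVA, the
Mann-Whitney U test, and Benjamini-Hochberg FDR control.  The summary-input
t-test mode exists so that group comparisons reported only as mean +/- SEM
with group sizes can be recomputed exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupSummary",
    "TestResult",
    "FactorialResult",
    "FDRResult",
    "pooled_t",
    "two_way_anova",
    "mann_whitney_u",
    "bh_fdr",
]


@dataclass
class GroupSummary:
    """Published group summary: mean +/- SEM with group size."""

    mean: float
    sem: float
    n: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sem < 0:
            raise ValueError("SEM must be >= 0")

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)


@dataclass
class TestResult:
    statistic_name: str
    value: float
    df: float
    p_two_sided: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_two_sided <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class FactorialResult:
    """Two-way ANOVA table: per-term F, (df_num, df_den), p, sums of squares."""

    terms: dict
    ss: dict
    table: pd.DataFrame

    def f(self, term: str) -> float:
        return self.terms[term][0]

    def p(self, term: str) -> float:
        return self.terms[term][2]


@dataclass
class FDRResult:
    p_values: np.ndarray
    q: float
    significant: np.ndarray
    adjusted: np.ndarray
    meta: dict = field(default_factory=dict)


def _as_summary(g) -> GroupSummary:
    if isinstance(g, GroupSummary):
        return g
    x = np.asarray(g, dtype=float)
    return GroupSummary(mean=float(x.mean()),
                        sem=float(x.std(ddof=1) / np.sqrt(x.size)),
                        n=int(x.size))


def pooled_t(group1, group2, welch: bool = False) -> TestResult:
    """Two-sample t-test from raw values or mean/SEM/n summaries.

    Pooled-variance by default (df = n1 + n2 - 2); Welch by flag.  From
    summaries, each group SD is recovered as sem * sqrt(n).  Two-sided p.
    """
    s1, s2 = _as_summary(group1), _as_summary(group2)
    if s1.n + s2.n < 4:
        raise ValueError("need n1 + n2 >= 4")
    scale = max(abs(s1.mean), abs(s2.mean), 1e-300)
    if s1.sd <= 1e-12 * scale and s2.sd <= 1e-12 * scale:
        if abs(s1.mean - s2.mean) <= 1e-12 * scale:
            return TestResult("t", 0.0, s1.n + s2.n - 2, 1.0)
        raise ValueError("zero variance with unequal means: t undefined")
    t, p = sps.ttest_ind_from_stats(s1.mean, s1.sd, s1.n,
                                    s2.mean, s2.sd, s2.n,
                                    equal_var=not welch)
    if welch:
        v1, v2 = s1.sd ** 2 / s1.n, s2.sd ** 2 / s2.n
        df = (v1 + v2) ** 2 / (v1 ** 2 / (s1.n - 1) + v2 ** 2 / (s2.n - 1))
    else:
        df = s1.n + s2.n - 2
    return TestResult("t", float(t), float(df), float(p))


def two_way_anova(table: pd.DataFrame, value: str = "value",
                  factor_a: str = "A", factor_b: str = "B") -> FactorialResult:
    """Fixed-effects two-way ANOVA with interaction when replicated.

    Type I sums of squares on balanced designs (orders agree when
    balanced); unbalanced designs fall back to Type II with a warning.
    Designs without within-cell replication use the additive model.
    """
    df = table[[value, factor_a, factor_b]].dropna().copy()
    counts = df.groupby([factor_a, factor_b], observed=True)[value].count()
    levels_a = df[factor_a].nunique()
    levels_b = df[factor_b].nunique()
    if levels_a < 2 or levels_b < 2:
        raise ValueError("need >= 2 levels per factor")
    full_cells = levels_a * levels_b
    if len(counts) < full_cells:
        have = set(counts.index)
        missing = [(a, b) for a in df[factor_a].unique()
                   for b in df[factor_b].unique() if (a, b) not in have]
        raise ValueError(f"empty design cells: {missing}")
    replicated = (counts > 1).any()
    balanced = counts.nunique() == 1
    interaction = f"C(Q('{factor_a}')):C(Q('{factor_b}'))"
    rhs = f"C(Q('{factor_a}')) + C(Q('{factor_b}'))"
    if replicated:
        rhs += " + " + interaction
    model = smf.ols(f"Q('{value}') ~ {rhs}", data=df).fit()
    if balanced:
        typ = 1
    else:
        warnings.warn("unbalanced design: using Type II sums of squares",
                      UserWarning, stacklevel=2)
        typ = 2
    with warnings.catch_warnings():
        # silence scipy's 0/0 F warnings on degenerate (zero-MSE) designs
        warnings.simplefilter("ignore", RuntimeWarning)
        aov = sm.stats.anova_lm(model, typ=typ)
    df_resid = float(aov.loc["Residual", "df"])
    mse = float(aov.loc["Residual", "sum_sq"]) / max(df_resid, 1.0)
    # numerical floor: sums of squares below rounding noise of the data are
    # exact zeros (degenerate designs otherwise give garbage F ratios)
    tol = 1e-10 * max(float((df[value] ** 2).sum()), 1e-300)
    rename = {f"C(Q('{factor_a}'))": factor_a,
              f"C(Q('{factor_b}'))": factor_b,
              interaction: f"{factor_a}:{factor_b}"}
    terms, ss = {}, {}
    for row_name, row in aov.iterrows():
        name = rename.get(row_name, row_name)
        ss[name] = float(row["sum_sq"])
        if name != "Residual":
            f_val, p_val = float(row["F"]), float(row["PR(>F)"])
            if ss[name] <= tol:
                # zero-MSE limit: a null term has F = 0
                f_val, p_val = 0.0, 1.0
            elif mse <= tol:
                # real effect with zero residual variance diverges
                f_val, p_val = np.inf, 0.0
            terms[name] = (f_val, (float(row["df"]), df_resid), p_val)
    return FactorialResult(terms=terms, ss=ss, table=aov)


def mann_whitney_u(group1, group2, exact_below: int = 20) -> TestResult:
    """Mann-Whitney U with exact p for small tie-free samples.

    U is the statistic for group1 (0 when every group1 value is below every
    group2 value; n1*n2 in the opposite orientation).  Exact enumeration is
    used when n1 + n2 <= exact_below and there are no ties; otherwise the
    normal approximation with tie correction.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("groups must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    small = x.size + y.size <= exact_below
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=(method == "asymptotic"))
    return TestResult("U", float(res.statistic), float(x.size * y.size),
                      float(min(res.pvalue, 1.0)))


def bh_fdr(p_values, q: float = 0.05) -> FDRResult:
    """Benjamini-Hochberg step-up FDR control at level q.

    Flags every p <= p_(k) where k = max{i : p_(i) <= i q / m}; adjusted
    values are the standard monotone transform (min over j >= i of
    m p_(j) / j, capped at 1).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    flags, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return FDRResult(p_values=p, q=q, significant=flags, adjusted=adjusted,
                     meta={"method": "fdr_bh", "m": int(p.size)})
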