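"""Group statistics: KS normality check on standardized samples, two-group
t-tests, one-way ANOVA with Tukey–Kramer pairwise comparisons, and two-way
ANOVA for longitudinal (group x day) well data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .core import DegenerateSampleError, InvalidParameterError, p_to_stars

__all__ = ["TestResult", "ks_normality", "two_group_test",
           "one_way_anova_multcompare", "two_way_anova", "p_to_stars"]

GROUPS = ("affected", "cotwin", "control")


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    df: float | tuple = float("nan")
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    effects: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise InvalidParameterError(f"p-value {self.p_value} outside [0,1]")

    @property
    def stars(self) -> str:
        return p_to_stars(self.p_value)


def ks_normality(sample) -> TestResult:
    """One-sample KS test of the standardized sample against N(0, 1).

    The sample is centred by its mean and scaled by its SD first; the
    resulting test is anti-conservative (parameters estimated from the data),
    which is accepted here as the reference behaviour.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise InvalidParameterError("need n >= 5 for the normality check")
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise DegenerateSampleError("zero-variance sample")
    z = (x - np.mean(x)) / sd
    stat, p = sps.kstest(z, "norm")
    return TestResult(test="ks_normality", statistic=float(stat),
                      p_value=float(p), df=x.size)


def two_group_test(a, b, equal_var: bool = False) -> TestResult:
    """Two-sample t-test (Welch by default; ``equal_var=True`` for the
    classic pooled-variance form)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(test="welch_t" if not equal_var else "student_t",
                      statistic=float(res.statistic),
                      p_value=float(res.pvalue), df=float(res.df))


def one_way_anova_multcompare(table: pd.DataFrame, variable: str | None = None,
                              value_col: str = "value",
                              group_col: str = "group") -> TestResult:
    """Omnibus one-way ANOVA plus Tukey–Kramer adjusted pairwise p-values."""
    df = table
    if variable is not None and "variable" in df.columns:
        df = df[df["variable"] == variable]
    groups = [g[value_col].to_numpy(dtype=float)
              for _, g in df.groupby(group_col)]
    labels = [str(name) for name, _ in df.groupby(group_col)]
    if len(groups) < 2:
        raise InvalidParameterError("one-way ANOVA needs >= 2 groups")
    f_stat, p = sps.f_oneway(*groups)
    k = len(groups)
    n = sum(g.size for g in groups)
    result = TestResult(test="one_way_anova", statistic=float(f_stat),
                        p_value=float(p), df=(k - 1, n - k))
    if k >= 2:
        tuk = sps.tukey_hsd(*groups)
        for i in range(k):
            for j in range(i + 1, k):
                result.pairwise[(labels[i], labels[j])] = float(
                    tuk.pvalue[i, j])
    return result


def two_way_anova(table: pd.DataFrame, value_col: str = "value",
                  group_col: str = "group", day_col: str = "day",
                  interaction: bool = True) -> TestResult:
    """Two-way ANOVA (type II) on well means keyed by group x day.

    Main-effect and interaction F/p land in ``effects``; the headline
    statistic/p is the group main effect.
    """
    df = table.rename(columns={value_col: "value", group_col: "group",
                               day_col: "day"}).copy()
    df["group"] = df["group"].astype(str)
    df["day"] = df["day"].astype(str)
    if df["group"].nunique() < 2 or df["day"].nunique() < 2:
        raise InvalidParameterError("two-way ANOVA needs >= 2 levels per factor")
    formula = "value ~ C(group) + C(day)"
    if interaction and len(df) > df["group"].nunique() * df["day"].nunique():
        formula += " + C(group):C(day)"
    model = ols(formula, data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    effects = {}
    rename = {"C(group)": "group", "C(day)": "day",
              "C(group):C(day)": "interaction"}
    for row, label in rename.items():
        if row in aov.index:
            effects[label] = (float(aov.loc[row, "F"]),
                              float(aov.loc[row, "PR(>F)"]))
    f_g, p_g = effects["group"]
    res = TestResult(test="two_way_anova", statistic=f_g, p_value=p_g,
                     df=(float(aov.loc["C(group)", "df"]),
                         float(aov.loc["Residual", "df"])))
    res.effects = effects
    return res
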