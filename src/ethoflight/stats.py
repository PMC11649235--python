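"""The statistical battery applied to behavioral metric tables.

Pairwise comparisons use the unpaired t-test with Welch's correction;
omnibus comparisons use ordinary one-way and two-way fixed-effects
ANOVA with Tukey's post-hoc multiple comparisons.  Unbalanced two-way
designs are decomposed with Type II sums of squares (stated in output).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError

__all__ = ["TestResult", "welch_t", "anova_oneway", "anova_twoway",
           "shapiro_screen"]


@dataclass(frozen=True)
class TestResult:
    """One statistical test: statistic, degrees of freedom, p value."""

    test: str
    statistic: float
    df: float | tuple[float, float]
    p: float
    comparisons: tuple[tuple[str, float], ...] = ()
    notes: str = ""


def welch_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided unpaired t-test with Welch's correction.

    Degrees of freedom follow the Welch-Satterthwaite combination and
    never exceed ``n1 + n2 - 2``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("each sample needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return TestResult("welch_t", 0.0, float(len(a) + len(b) - 2), 1.0)
        raise InputError("both samples have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult("welch_t", float(res.statistic), float(res.df),
                      float(res.pvalue))


def anova_oneway(groups: Sequence[Sequence[float]], tukey: bool = False,
                 labels: Sequence[str] | None = None) -> TestResult:
    """Ordinary one-way ANOVA, optionally with Tukey's HSD post hoc.

    Tukey adjusted pairwise p values come from the studentized-range
    distribution and are attached as ``comparisons``.
    """
    if len(groups) < 2:
        raise InputError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise InputError("every group needs n >= 2")
    k = len(arrays)
    n_total = sum(len(g) for g in arrays)
    if all(np.ptp(g) == 0 for g in arrays) and \
            len({float(g[0]) for g in arrays}) == 1:
        return TestResult("anova1", 0.0, (float(k - 1), float(n_total - k)),
                          1.0)
    f, p = sps.f_oneway(*arrays)
    comparisons: tuple[tuple[str, float], ...] = ()
    if tukey:
        labels = list(labels) if labels is not None else \
            [f"g{i}" for i in range(k)]
        hsd = sps.tukey_hsd(*arrays)
        comparisons = tuple(
            (f"{labels[i]} vs {labels[j]}", float(hsd.pvalue[i, j]))
            for i in range(k) for j in range(i + 1, k))
    return TestResult("anova1", float(f), (float(k - 1), float(n_total - k)),
                      float(p), comparisons=comparisons)


def anova_twoway(data: pd.DataFrame, value: str = "value",
                 factor_a: str = "trial",
                 factor_b: str = "group") -> dict[str, TestResult]:
    """Fixed-effects two-way ANOVA: both main effects and the interaction.

    ``data`` is a tidy table with one observation per row.  Every
    ``(factor_a, factor_b)`` cell must be non-empty.  Unbalanced designs
    use Type II sums of squares (noted on each result).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for col in (value, factor_a, factor_b):
        if col not in data.columns:
            raise InputError(f"data lacks column {col!r}")
    counts = data.groupby([factor_a, factor_b], observed=True).size()
    levels_a = data[factor_a].unique()
    levels_b = data[factor_b].unique()
    for la in levels_a:
        for lb in levels_b:
            if (la, lb) not in counts.index:
                raise InputError(f"empty cell ({factor_a}={la}, "
                                 f"{factor_b}={lb})")
    df = data.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    if np.ptp(df["_y"].to_numpy()) == 0:
        zero = {}
        n = len(df)
        ka, kb = len(levels_a), len(levels_b)
        dfe = n - ka * kb
        for name, d1 in (("main_" + factor_a, ka - 1),
                         ("main_" + factor_b, kb - 1),
                         ("interaction", (ka - 1) * (kb - 1))):
            zero[name] = TestResult("anova2", 0.0, (float(d1), float(dfe)),
                                    1.0, notes="type II SS")
        return zero
    model = smf.ols("_y ~ C(_a) * C(_b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    dfe = float(table.loc["Residual", "df"])
    out = {}
    for row, name in (("C(_a)", "main_" + factor_a),
                      ("C(_b)", "main_" + factor_b),
                      ("C(_a):C(_b)", "interaction")):
        out[name] = TestResult(
            "anova2", float(table.loc[row, "F"]),
            (float(table.loc[row, "df"]), dfe),
            float(table.loc[row, "PR(>F)"]), notes="type II SS")
    return out


def shapiro_screen(samples: dict[str, Sequence[float]],
                   alpha: float = 0.05) -> pd.DataFrame:
    """Shapiro-Wilk normality screen, reported (not acted upon)."""
    rows = []
    for name, x in samples.items():
        w, p = sps.shapiro(np.asarray(x, dtype=float))
        rows.append({"sample": name, "W": w, "p": p, "normal": p >= alpha})
    return pd.DataFrame(rows)
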