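"""Summary tables, statistical reports, and simple figures.

``make_report`` turns a tidy metrics table (one row per animal, session,
trial, period) into per-figure summary tables (group mean ± SEM per
trial and period), test-result tables for a configured list of
comparisons, and simple trial-course plots.  Output is deterministic
given identical inputs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import InputError
from .stats import anova_oneway, anova_twoway, welch_t

__all__ = ["summarize", "run_comparisons", "make_report"]

_KNOWN_COMPARISONS = ("welch_t", "anova1", "anova2")


def summarize(metrics: pd.DataFrame,
              value: str = "percent_freezing") -> pd.DataFrame:
    """Group mean ± SEM of one metric per (session, period, trial)."""
    grouped = metrics.groupby(["group", "session", "period", "trial_index"],
                              observed=True)[value]
    out = grouped.agg(["mean", "sem", "count"]).reset_index()
    out.insert(0, "metric", value)
    return out


def _animal_means(metrics: pd.DataFrame, value: str, period: str,
                  group: str) -> np.ndarray:
    sel = metrics[(metrics["period"] == period)
                  & (metrics["group"] == group)]
    if sel.empty:
        raise InputError(f"no rows for group={group!r} period={period!r}")
    return sel.groupby("animal_id", observed=True)[value].mean().to_numpy()


def run_comparisons(metrics: pd.DataFrame,
                    comparisons: Sequence[Mapping]) -> pd.DataFrame:
    """Execute a configured list of statistical comparisons.

    Each comparison is a mapping with ``test`` (``welch_t``, ``anova1``
    or ``anova2``), ``value`` (metric column), ``period``, and ``groups``
    (the group labels to compare).  Per-animal means over trials are the
    units of analysis for ``welch_t``/``anova1``; ``anova2`` uses the
    per-trial values with trial and group as factors.
    """
    rows = []
    for comp in comparisons:
        test = comp.get("test")
        if test not in _KNOWN_COMPARISONS:
            raise InputError(f"unknown comparison test {test!r}")
        value, period = comp["value"], comp["period"]
        groups = list(comp["groups"])
        name = comp.get("name", f"{test}:{value}:{period}:" + "/".join(groups))
        if test == "welch_t":
            res = welch_t(_animal_means(metrics, value, period, groups[0]),
                          _animal_means(metrics, value, period, groups[1]))
            results = {name: res}
        elif test == "anova1":
            res = anova_oneway(
                [_animal_means(metrics, value, period, g) for g in groups],
                tukey=comp.get("tukey", False), labels=groups)
            results = {name: res}
        else:
            sel = metrics[(metrics["period"] == period)
                          & (metrics["group"].isin(groups))]
            results = {f"{name}:{k}": v for k, v in
                       anova_twoway(sel, value=value, factor_a="trial_index",
                                    factor_b="group").items()}
        for rname, res in results.items():
            df1, df2 = (res.df if isinstance(res.df, tuple)
                        else (res.df, np.nan))
            rows.append({"comparison": rname, "test": res.test,
                         "statistic": res.statistic, "df1": df1, "df2": df2,
                         "p": res.p, "notes": res.notes})
            for pair, p_adj in res.comparisons:
                rows.append({"comparison": f"{rname} [{pair}]",
                             "test": "tukey", "statistic": np.nan,
                             "df1": np.nan, "df2": np.nan, "p": p_adj,
                             "notes": "Tukey HSD adjusted"})
    return pd.DataFrame(rows)


def _trial_course_plot(metrics: pd.DataFrame, value: str, period: str,
                       path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    sel = metrics[metrics["period"] == period]
    for group, gdf in sel.groupby("group", observed=True):
        by_trial = gdf.groupby("trial_index", observed=True)[value]
        mean, sem = by_trial.mean(), by_trial.sem()
        ax.errorbar(mean.index, mean.to_numpy(), yerr=sem.to_numpy(),
                    marker="o", capsize=2, label=group)
    ax.set_xlabel("trial")
    ax.set_ylabel(value.replace("_", " "))
    ax.set_title(f"{value} during {period}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def make_report(metrics: pd.DataFrame, comparisons: Sequence[Mapping] = (),
                outdir: str | Path = "report",
                values: Sequence[str] = ("percent_freezing",
                                         "activity_index"),
                periods: Sequence[str] = ("tone", "wn")) -> dict[str, Path]:
    """Write summary tables, test tables, and trial-course figures.

    Returns a mapping of artifact names to file paths.  Rerunning on
    identical inputs reproduces identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    for value in values:
        summary = summarize(metrics, value=value)
        path = outdir / f"summary_{value}.csv"
        summary.to_csv(path, index=False, float_format="%.6g")
        artifacts[f"summary_{value}"] = path
        for period in periods:
            if (metrics["period"] == period).any():
                fig_path = outdir / f"{value}_{period}_by_trial.png"
                _trial_course_plot(metrics, value, period, fig_path)
                artifacts[f"fig_{value}_{period}"] = fig_path
    if comparisons:
        tests = run_comparisons(metrics, comparisons)
        path = outdir / "test_results.csv"
        tests.to_csv(path, index=False, float_format="%.6g")
        artifacts["test_results"] = path
    return artifacts
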