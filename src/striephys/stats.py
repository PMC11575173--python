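"""Group-comparison statistics used by the reporting stage.

Thin wrappers around scipy/statsmodels routines: Welch's t-test,
Kolmogorov-Smirnov, Kruskal-Wallis, two-way ANOVA (group x pulse) for
evoked-train profiles, empirical CDFs, and optional Benjamini-Hochberg
correction.  Results are returned as a uniform record so the pipeline
can tabulate them.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multitest import multipletests

__all__ = ["ComparisonResult", "compare_groups", "compare_train_profiles",
           "cumulative_distribution", "bh_adjust"]

ALPHA = 0.05


@dataclass
class ComparisonResult:
    """One statistical comparison between two groups."""

    statistic_name: str
    statistic: float
    p_value: float
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    n_a: int
    n_b: int
    measure: str = ""
    window: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def to_dict(self) -> dict:
        return {"measure": self.measure, "window": self.window,
                "test": self.statistic_name, "statistic": self.statistic,
                "p_value": self.p_value, "significant": self.significant,
                "mean_a": self.mean_a, "sem_a": self.sem_a,
                "mean_b": self.mean_b, "sem_b": self.sem_b,
                "n_a": self.n_a, "n_b": self.n_b}


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")


def compare_groups(values_a, values_b, test: str = "welch_t",
                   measure: str = "", window: str = "") -> ComparisonResult:
    """Two-sample comparison with the named test.

    ``test`` is one of ``welch_t``, ``ks``, ``kruskal_wallis``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per group")
    if test == "welch_t":
        res = sps.ttest_ind(a, b, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "ks":
        res = sps.ks_2samp(a, b)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "kruskal_wallis":
        res = sps.kruskal(a, b)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return ComparisonResult(test, stat, p, float(a.mean()), _sem(a),
                            float(b.mean()), _sem(b), a.size, b.size,
                            measure=measure, window=window)


def compare_train_profiles(profiles_a: np.ndarray, profiles_b: np.ndarray,
                           measure: str = "", window: str = "") -> ComparisonResult:
    """Two-way ANOVA (group x pulse index) on normalized train amplitudes.

    ``profiles_*`` are (n_cells, n_pulses) arrays of normalized per-pulse
    amplitudes.  The reported statistic and p-value are the group main
    effect; means/SEMs summarize each group's pulse-2..n average.
    """
    pa = np.atleast_2d(np.asarray(profiles_a, dtype=float))
    pb = np.atleast_2d(np.asarray(profiles_b, dtype=float))
    if pa.shape[0] < 2 or pb.shape[0] < 2:
        raise ValueError("need >= 2 cells per group")
    rows = []
    for label, arr in (("a", pa), ("b", pb)):
        for cell, prof in enumerate(arr):
            for pulse, v in enumerate(prof, start=1):
                rows.append({"group": label, "pulse": pulse, "value": v})
    df = pd.DataFrame(rows)
    fit = ols("value ~ C(group) * C(pulse)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    f = float(table.loc["C(group)", "F"])
    p = float(table.loc["C(group)", "PR(>F)"])
    la = pa[:, 1:].mean(axis=1)
    lb = pb[:, 1:].mean(axis=1)
    return ComparisonResult("two_way_anova", f, p, float(la.mean()), _sem(la),
                            float(lb.mean()), _sem(lb), pa.shape[0], pb.shape[0],
                            measure=measure, window=window)


def cumulative_distribution(values) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF: (sorted values, step heights in (0, 1])."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    s = np.sort(v)
    return s, np.arange(1, v.size + 1) / v.size


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; off by default
    in the pipeline, which reports unadjusted per-window tests)."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
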