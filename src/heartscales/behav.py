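"""Behavioural and physiological covariates, and simple group statistics.

Covers interoceptive accuracy (mean distance index between taps and
heartbeats), heart-rate-variability summaries (mean RR, SDNN), Welch
t-tests from summary statistics, 2x2 chi-square tests and Pearson
correlations - the ingredients of a demographics/neuropsychology comparison
table.

The mean distance index (MDI) used here is the nearest-target normalised
distance: for each tap, the distance to the nearest heartbeat divided by
the local inter-beat interval, averaged over taps.  0 means perfect
entrainment; taps falling midway between beats score 0.5.  The definition
is isolated behind one function so an alternative convention can be swapped
in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ConfigError, EventTrain

__all__ = [
    "mean_distance_index",
    "hrv_metrics",
    "welch_t_from_summary",
    "chisq_2x2",
    "pearson_r",
    "group_table",
    "REFERENCE_TABLE1",
]


def mean_distance_index(taps: EventTrain, targets: EventTrain) -> float:
    """Interoceptive accuracy: mean normalised tap-to-heartbeat distance.

    For each tap the distance to the nearest target event is divided by the
    length of the inter-target interval the tap falls in (edge taps use the
    nearest interval).  Lower is better; 0 = perfect entrainment.
    """
    t = np.asarray(taps.times, float)
    g = np.asarray(targets.times, float)
    if t.size < 3 or g.size < 3:
        raise ConfigError("MDI needs >= 3 taps and >= 3 targets")
    gaps = np.diff(g)
    # nearest target per tap
    right = np.searchsorted(g, t)
    left = np.clip(right - 1, 0, g.size - 1)
    right = np.clip(right, 0, g.size - 1)
    d_left = np.abs(t - g[left])
    d_right = np.abs(t - g[right])
    dist = np.minimum(d_left, d_right)
    # local interval: the inter-target gap containing the tap (clipped to
    # the first/last gap for taps outside the target span)
    gap_idx = np.clip(np.searchsorted(g, t) - 1, 0, gaps.size - 1)
    return float(np.mean(dist / gaps[gap_idx]))


def hrv_metrics(rpeaks: EventTrain) -> tuple[float, float]:
    """Mean RR interval and SDNN, both in milliseconds (population SD)."""
    t = np.asarray(rpeaks.times, float)
    if t.size < 3:
        raise ConfigError("HRV needs >= 3 R-peaks")
    if np.any(np.diff(t) <= 0):
        raise ConfigError("R-peak train must be strictly increasing")
    rr = np.diff(t) * 1000.0
    return float(rr.mean()), float(rr.std(ddof=0))


def welch_t_from_summary(m1: float, s1: float, n1: int,
                         m2: float, s2: float, n2: int
                         ) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test from group summaries.

    Returns ``(t, df, p)`` with Welch-Satterthwaite degrees of freedom and a
    two-sided p-value.
    """
    if s1 < 0 or s2 < 0:
        raise ConfigError("standard deviations must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ConfigError("each group needs n >= 2")
    v1, v2 = s1 ** 2 / n1, s2 ** 2 / n2
    denom = v1 + v2
    if denom == 0:
        if m1 == m2:
            raise ConfigError("t undefined: zero variance and equal means")
        return (np.inf if m1 > m2 else -np.inf, float(n1 + n2 - 2), 0.0)
    t = (m1 - m2) / np.sqrt(denom)
    df = denom ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def chisq_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on a 2x2 table.

    Rows are groups, columns are categories (e.g. male/female counts).
    """
    if min(a, b, c, d) < 0:
        raise ConfigError("counts must be non-negative")
    table = np.array([[a, b], [c, d]], float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ConfigError("zero margin in 2x2 table")
    n = table.sum()
    chi2 = n * (a * d - b * c) ** 2 / (
        (a + b) * (c + d) * (a + c) * (b + d))
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided t-based p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ConfigError("Pearson r needs >= 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ConfigError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConfigError("constant input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# group comparison table
# ---------------------------------------------------------------------------

@dataclass
class _SummaryRow:
    name: str
    kind: str  # 'welch' or 'chisq'
    group1: tuple
    group2: tuple


# Published demographic summaries of the dementia cohorts the synthetic
# generator emulates: (mean, SD, n) per group, or male/female counts for
# sex.  Used as reference inputs for summary-statistics tests.
REFERENCE_TABLE1 = {
    "AD": {
        "age": ((72.44, 5.58, 34), (73.37, 7.65, 35)),
        "education": ((13.32, 3.57, 34), (12.49, 4.91, 35)),
        "sex_mf": ((13, 21), (12, 23)),
        "mmse": ((28.03, 1.14, 34), (22.74, 2.85, 35)),
    },
    "bvFTD": {
        "age": ((66.94, 9.06, 31), (67.87, 11.38, 31)),
        "education": ((15.06, 3.55, 31), (14.48, 4.82, 31)),
        "sex_mf": ((18, 13), (15, 16)),
        "mmse": ((28.04, 1.17, 31), (25.24, 2.64, 31)),
    },
}


def group_table(df: pd.DataFrame, group_col: str, control: str, patient: str,
                numeric: list[str], sex_col: str = "sex"
                ) -> pd.DataFrame:
    """Demographics/neuropsychology comparison table for two groups.

    Numeric variables get mean +/- SD per group and a Welch t-test; the sex
    column gets male:female counts and a chi-square test.  Mirrors the
    standard layout of cohort description tables.
    """
    g1 = df[df[group_col] == control]
    g2 = df[df[group_col] == patient]
    rows = []
    for col in numeric:
        x1 = g1[col].dropna().to_numpy(float)
        x2 = g2[col].dropna().to_numpy(float)
        t, dfree, p = welch_t_from_summary(
            x1.mean(), x1.std(ddof=1), x1.size,
            x2.mean(), x2.std(ddof=1), x2.size)
        rows.append({
            "variable": col,
            control: f"{x1.mean():.2f} ± {x1.std(ddof=1):.2f}",
            patient: f"{x2.mean():.2f} ± {x2.std(ddof=1):.2f}",
            "statistic": t, "df": dfree, "p": p, "test": "welch_t",
        })
    if sex_col in df.columns:
        m1 = int((g1[sex_col] == "M").sum())
        f1 = int((g1[sex_col] == "F").sum())
        m2 = int((g2[sex_col] == "M").sum())
        f2 = int((g2[sex_col] == "F").sum())
        chi2, p = chisq_2x2(m1, f1, m2, f2)
        rows.append({
            "variable": "sex (M:F)",
            control: f"{m1}:{f1}", patient: f"{m2}:{f2}",
            "statistic": chi2, "df": 1.0, "p": p, "test": "chi2",
        })
    return pd.DataFrame(rows)
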