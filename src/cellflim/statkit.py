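"""Repeatability and group statistics for per-cell FLIM parameters.

Covers the statistical toolkit used around the cell-encircled analysis:

* two-way mixed-effects intraclass correlation (ICC), single measure, in
  both the consistency and absolute-agreement forms, with the conventional
  interpretation bands (<0.5 poor, 0.5-0.75 moderate, 0.75-0.9 good, >=0.9
  excellent) and a non-significance flag from the ICC F-test;
* absolute and percent pairwise differences for repeat measurements;
* fixed-factor one-way ANOVA (eccentricity effects per channel) and
  repeated-measures / mixed ANOVA (spectral-channel effects within
  subjects, eccentricity between);
* unpaired pooled-variance t-tests with step-down Holm-Bonferroni
  correction;
* two-group sample-size computation by the normal approximation, and
  ordinary least-squares linear trends.

ICC, Holm, the one-way ANOVA, paired differences and the sample-size
formula are implemented directly from their mean-squares / z-score
definitions; repeated-measures and mixed ANOVA delegate to pingouin.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IccModel",
    "IccClass",
    "RepeatabilityReport",
    "StatResult",
    "PowerSpec",
    "icc_consistency",
    "icc_agreement",
    "icc_f_test",
    "classify_icc",
    "repeatability_report",
    "paired_difference_stats",
    "one_way_anova",
    "rm_anova",
    "t_test_unpaired",
    "holm_bonferroni",
    "sample_size_two_group",
    "linear_trend",
]


class IccModel(str, enum.Enum):
    consistency = "consistency"
    agreement = "agreement"


class IccClass(str, enum.Enum):
    poor = "poor"
    moderate = "moderate"
    good = "good"
    excellent = "excellent"
    ns = "ns"


@dataclass
class RepeatabilityReport:
    """ICC plus difference statistics for one parameter across repeats."""

    parameter: str
    icc_value: float
    icc_model: IccModel
    icc_class: IccClass
    icc_p_value: float
    mean_abs_diff: float
    sd_abs_diff: float
    mean_pct_diff: float
    sd_pct_diff: float
    n_units: int
    n_measurements: int


@dataclass
class StatResult:
    """One ANOVA effect: F statistic, degrees of freedom and p-value."""

    effect: str
    F: float
    df_between: float
    df_within: float
    p_value: float

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError("F must be non-negative")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


@dataclass
class PowerSpec:
    """Two-group difference-of-means power specification."""

    delta: float
    sigma: float
    power: float = 0.8
    alpha: float = 0.05
    sided: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.power < 1):
            raise ValueError("power must lie in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.sided not in (1, 2):
            raise ValueError("sided must be 1 or 2")


# ---------------------------------------------------------------------------
# ICC (two-way mixed effects, single measure)
# ---------------------------------------------------------------------------

def _two_way_mean_squares(data: np.ndarray) -> Tuple[float, float, float, int, int]:
    """Two-way ANOVA mean squares (rows = units, columns = measurements).

    Returns (MSR, MSC, MSE, n, k): between-unit, between-measurement and
    residual mean squares from the complete two-way decomposition.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a 2-D units x measurements matrix")
    n, k = data.shape
    if n < 3 or k < 2:
        raise ValueError(f"need >= 3 units and >= 2 measurements, got {n} x {k}")
    if not np.all(np.isfinite(data)):
        raise ValueError("missing cells: ICC requires a complete matrix")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((data - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse, 0.0) / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_consistency(data: np.ndarray) -> float:
    """Single-measure two-way mixed-effects consistency ICC, ICC(C,1).

    (MSR - MSE) / (MSR + (k-1) MSE): systematic offsets between
    measurements do not count against agreement.
    """
    msr, _msc, mse, _n, k = _two_way_mean_squares(data)
    denom = msr + (k - 1) * mse
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)


def icc_agreement(data: np.ndarray) -> float:
    """Single-measure two-way mixed-effects absolute-agreement ICC, ICC(A,1).

    (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n): systematic offsets
    between measurements reduce the coefficient.
    """
    msr, msc, mse, n, k = _two_way_mean_squares(data)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)


def icc_f_test(data: np.ndarray) -> Tuple[float, int, int, float]:
    """F-test of ICC > 0: F = MSR/MSE with df (n-1, (n-1)(k-1))."""
    msr, _msc, mse, n, k = _two_way_mean_squares(data)
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if mse == 0:
        return float("inf"), df1, df2, 0.0
    f = msr / mse
    return float(f), df1, df2, float(stats.f.sf(f, df1, df2))


def classify_icc(value: float) -> IccClass:
    """Interpretation bands: <0.5 poor, [0.5, 0.75) moderate, [0.75, 0.9)
    good, >=0.9 excellent."""
    if value > 1 + 1e-12:
        raise ValueError("ICC cannot exceed 1")
    if value < 0.5:
        return IccClass.poor
    if value < 0.75:
        return IccClass.moderate
    if value < 0.9:
        return IccClass.good
    return IccClass.excellent


def repeatability_report(
    parameter: str,
    x1: Sequence[float],
    x2: Sequence[float],
    model: IccModel = IccModel.agreement,
    alpha: float = 0.05,
) -> RepeatabilityReport:
    """Full repeatability summary for one parameter across two measurements.

    Combines the requested ICC form, its F-test (ICC reported as 'ns' when
    p > alpha), and the absolute / percent difference statistics.
    """
    data = np.column_stack([np.asarray(x1, float), np.asarray(x2, float)])
    keep = np.all(np.isfinite(data), axis=1)
    data = data[keep]
    model = IccModel(model)
    value = icc_consistency(data) if model is IccModel.consistency else icc_agreement(data)
    _f, _d1, _d2, p = icc_f_test(data)
    cls = IccClass.ns if p > alpha else classify_icc(value)
    (mad, sad), (mpd, spd) = paired_difference_stats(data[:, 0], data[:, 1])
    return RepeatabilityReport(
        parameter=parameter,
        icc_value=value,
        icc_model=model,
        icc_class=cls,
        icc_p_value=p,
        mean_abs_diff=mad,
        sd_abs_diff=sad,
        mean_pct_diff=mpd,
        sd_pct_diff=spd,
        n_units=int(data.shape[0]),
        n_measurements=2,
    )


# ---------------------------------------------------------------------------
# paired differences
# ---------------------------------------------------------------------------

def paired_difference_stats(
    x1: Sequence[float],
    x2: Sequence[float],
) -> Tuple[Tuple[float, float], Tuple[float, float]]:
    """Absolute and percent differences of paired measurements.

    Per unit, d = |x1 - x2| and pct = 100 d / pair mean; returns
    ((mean |d|, SD |d|), (mean pct, SD pct)) with sample SDs.  Units whose
    pair mean is zero are excluded from the percent statistics with a
    warning (the percent difference is undefined there).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1 or x1.size < 2:
        raise ValueError("x1 and x2 must be equal-length 1-D arrays, length >= 2")
    d = np.abs(x1 - x2)
    pair_mean = (x1 + x2) / 2.0
    ok = pair_mean != 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} unit(s) with zero pair mean excluded from "
            "percent differences",
            stacklevel=2,
        )
    pct = 100.0 * d[ok] / pair_mean[ok]
    sd = float(d.std(ddof=1))
    if pct.size >= 2:
        pct_stats = (float(pct.mean()), float(pct.std(ddof=1)))
    elif pct.size == 1:
        pct_stats = (float(pct.mean()), float("nan"))
    else:
        pct_stats = (float("nan"), float("nan"))
    return (float(d.mean()), sd), pct_stats


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def one_way_anova(values: Sequence[float], group_labels: Sequence) -> StatResult:
    """Fixed-factor one-way ANOVA: F = MS_between / MS_within."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if values.shape != labels.shape:
        raise ValueError("values and group_labels must have equal length")
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("every group needs at least two values")
    grand = values.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df_b = len(groups) - 1
    df_w = values.size - len(groups)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        f = 0.0 if ms_b == 0 else float("inf")
        p = 1.0 if ms_b == 0 else 0.0
    else:
        f = ms_b / ms_w
        p = float(stats.f.sf(f, df_b, df_w))
    return StatResult("group", float(f), df_b, df_w, p)


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    subject: str,
    within: str,
    between: Optional[str] = None,
) -> List[StatResult]:
    """Repeated-measures (or mixed) ANOVA on a long-format table.

    With only a within factor (e.g. spectral channel), returns the
    within-subject effect; adding a between factor (e.g. eccentricity)
    returns between, within and interaction effects.  Subjects missing any
    within-factor level are dropped (complete cases), with the count noted
    in a warning.
    """
    import pingouin as pg

    df = table[[c for c in (dv, subject, within, between) if c is not None]].dropna()
    k = df[within].nunique()
    complete = df.groupby(subject)[within].nunique()
    keep = complete[complete == k].index
    dropped = complete.size - keep.size
    if dropped:
        warnings.warn(f"rm_anova: dropped {dropped} incomplete subject(s)", stacklevel=2)
    df = df[df[subject].isin(keep)]
    if df.empty:
        raise ValueError("no complete cases for the repeated-measures ANOVA")
    if between is None:
        aov = pg.rm_anova(data=df, dv=dv, within=within, subject=subject, detailed=True)
        row = aov.loc[aov["Source"] == within].iloc[0]
        f = float(row["F"]) if "F" in aov.columns and np.isfinite(row.get("F", np.nan)) else np.nan
        p = float(row["p_unc"]) if "p_unc" in aov.columns and np.isfinite(row.get("p_unc", np.nan)) else np.nan
        if not np.isfinite(f):
            # degenerate 0/0 case: no variance anywhere in the within effect
            f, p = (0.0, 1.0) if row["SS"] == 0 else (float("inf"), 0.0)
        return [
            StatResult(within, f, float(row["DF"]),
                       float(aov.loc[aov["Source"] == "Error", "DF"].iloc[0]), p)
        ]
    aov = pg.mixed_anova(data=df, dv=dv, within=within, subject=subject, between=between)
    out = []
    for _, row in aov.iterrows():
        out.append(
            StatResult(
                str(row["Source"]), float(row["F"]), float(row["DF1"]),
                float(row["DF2"]), float(row["p_unc"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# t-tests and Holm-Bonferroni
# ---------------------------------------------------------------------------

def t_test_unpaired(x: Sequence[float], y: Sequence[float]) -> Tuple[float, int, float]:
    """Unpaired pooled-variance Student's t-test: (t, df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least two values")
    n1, n2 = x.size, y.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        t = 0.0 if x.mean() == y.mean() else math.copysign(float("inf"), x.mean() - y.mean())
    else:
        t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = float(2 * stats.t.sf(abs(t), df)) if math.isfinite(t) else 0.0
    return float(t), df, p


def holm_bonferroni(
    p_values: Sequence[float],
    alpha: float = 0.05,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Step-down Holm-Bonferroni correction.

    Sorts the m p-values ascending and compares the i-th smallest against
    alpha / (m - i + 1), rejecting until the first failure.  Returns
    (thresholds in ascending-p order, rejection flags in the original
    order, adjusted p-values in the original order).  Adjusted p-values
    are the running maximum of (m - i + 1) * p_(i), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("p_values must not be empty")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p_values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = alpha / (m - np.arange(m))
    sorted_p = p[order]
    reject_sorted = np.zeros(m, dtype=bool)
    for i in range(m):
        if sorted_p[i] <= thresholds[i]:
            reject_sorted[i] = True
        else:
            break
    adj_sorted = np.maximum.accumulate((m - np.arange(m)) * sorted_p)
    adj_sorted = np.minimum(adj_sorted, 1.0)
    reject = np.zeros(m, dtype=bool)
    adjusted = np.empty(m)
    reject[order] = reject_sorted
    adjusted[order] = adj_sorted
    return thresholds, reject, adjusted


# ---------------------------------------------------------------------------
# power / sample size and trends
# ---------------------------------------------------------------------------

def sample_size_two_group(spec: PowerSpec) -> int:
    """Per-group n to detect a mean difference, normal approximation.

    n = ceil( 2 * (z_{1-alpha/sided} + z_{power})^2 * (sigma / delta)^2 ).
    """
    if spec.delta == 0:
        raise ValueError("delta must be non-zero")
    z_a = stats.norm.ppf(1.0 - spec.alpha / spec.sided)
    z_b = stats.norm.ppf(spec.power)
    n = 2.0 * (z_a + z_b) ** 2 * (spec.sigma / spec.delta) ** 2
    return int(math.ceil(n))


def linear_trend(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float, float]:
    """Ordinary least-squares trend line: (slope, intercept, r)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("need at least two distinct x values")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)
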