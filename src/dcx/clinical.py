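"""Clinical statistics: normality-gated group tests, correlations,
logistic cut-off, harmonic-mean summaries.

Continuous variables are gated by Shapiro-Wilk: if either group departs
from normality (p < alpha) the comparison uses Mann-Whitney U (normal
approximation with tie correction) and summaries are median (IQR);
otherwise a pooled-variance t-test with mean +/- SD summaries.
Categorical variables use Pearson's chi-squared (no continuity
correction by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupTestResult:
    variable: str
    test: str                  # "t" | "mann-whitney" | "chi2"
    statistic: float
    p: float
    summary_a: str
    summary_b: str
    flag: str = ""


def _summary_normal(x: np.ndarray) -> str:
    return f"{np.mean(x):.3g} ± {np.std(x, ddof=1):.3g}"


def _summary_nonnormal(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.3g} ({q1:.3g}-{q3:.3g})"


def compare_groups(
    values_a,
    values_b,
    variable_type: str = "continuous",
    variable: str = "",
    normality_alpha: float = 0.05,
    yates: bool = False,
) -> GroupTestResult:
    """Two-group comparison with the normality-gated test choice.

    Continuous: Shapiro-Wilk on each group; Mann-Whitney U if either
    p < ``normality_alpha``, else unpaired pooled-variance t-test.
    Categorical: ``values_a``/``values_b`` are per-group category counts
    (same category order) compared by Pearson chi-squared.
    """
    if variable_type == "categorical":
        table = np.asarray([values_a, values_b], dtype=float)
        if table.min() < 0 or table.sum() == 0:
            raise ValueError("invalid contingency counts")
        if np.array_equal(table[0], table[1]):
            stat, p = 0.0, 1.0
        else:
            stat, p, *_ = stats.chi2_contingency(table, correction=yates)
        return GroupTestResult(
            variable, "chi2", float(stat), float(p),
            summary_a=str(list(np.asarray(values_a))),
            summary_b=str(list(np.asarray(values_b))),
        )
    if variable_type != "continuous":
        raise ValueError(f"unknown variable_type {variable_type!r}")

    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 observations per group")

    flag = ""
    try:
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            raise ValueError("constant input")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_norm_a = stats.shapiro(a).pvalue
            p_norm_b = stats.shapiro(b).pvalue
        normal = p_norm_a >= normality_alpha and p_norm_b >= normality_alpha
    except ValueError:
        normal = False
        flag = "shapiro-undefined"

    if normal:
        stat, p = stats.ttest_ind(a, b, equal_var=True)
        return GroupTestResult(
            variable, "t", float(stat), float(p), _summary_normal(a), _summary_normal(b)
        )
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return GroupTestResult(
        variable, "mann-whitney", float(res.statistic), float(res.pvalue),
        _summary_nonnormal(a), _summary_nonnormal(b), flag=flag,
    )


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient and two-sided p (t-approximation, n-2 df).

    Spearman is Pearson on average ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length 1-D inputs with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if 1.0 - abs(r) < 1e-14:  # exact linear dependence up to rounding
        r = math.copysign(1.0, r)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


@dataclass
class CutoffResult:
    cutoff: float
    beta0: float
    beta1: float
    converged: bool
    separated: bool = False


def optimal_cutoff(
    marker: np.ndarray,
    labels: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CutoffResult:
    """Optimal marker cut-off from a univariate logistic regression.

    Fits P(label=1 | x) = expit(b0 + b1 x) by iteratively reweighted
    least squares and returns the probability-0.5 point -b0/b1. On
    complete separation (divergent fit) the midpoint between the closest
    opposing-class values is returned with ``separated`` set.
    """
    x = np.asarray(marker, dtype=float)
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("labels must contain both classes (0 and 1)")
    if not np.isfinite(x).all():
        raise ValueError("marker contains non-finite values")

    def separation_midpoint() -> float:
        lo = x[y == 0]
        hi = x[y == 1]
        if lo.max() < hi.min():
            return float((lo.max() + hi.min()) / 2.0)
        if hi.max() < lo.min():
            return float((hi.max() + lo.min()) / 2.0)
        return float(np.median(x))

    # IRLS on centered/scaled marker for conditioning
    mu, sd = x.mean(), x.std()
    sd = sd if sd > 0 else 1.0
    xs = (x - mu) / sd
    design = np.column_stack([np.ones_like(xs), xs])
    beta = np.zeros(2)
    converged = False
    diverged = False
    for _ in range(max_iter):
        eta = design @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = p * (1.0 - p)
        if w.max() < 1e-12 or np.abs(beta).max() > 1e6:
            diverged = True
            break
        wd = design * w[:, None]
        try:
            step = np.linalg.solve(design.T @ wd, design.T @ (y - p))
        except np.linalg.LinAlgError:
            diverged = True
            break
        beta = beta + step
        if np.abs(step).max() < tol:
            converged = True
            break

    # translate back to the original scale
    b1 = beta[1] / sd
    b0 = beta[0] - beta[1] * mu / sd
    if converged and b1 != 0 and abs(beta).max() < 50:
        return CutoffResult(float(-b0 / b1), float(b0), float(b1), True)
    return CutoffResult(separation_midpoint(), float(b0), float(b1), False, separated=True)


@dataclass
class RbmMeasurementSet:
    measurements: np.ndarray
    harmonic_mean: float
    interval_um: float = 9.5
    flag: str = ""


def rbm_harmonic_mean(measurements, interval_um: float = 9.5) -> RbmMeasurementSet:
    """Harmonic-mean summary of membrane-thickness measurements.

    All measurements must be positive; fewer than 30 triggers a warning
    flag (the sampling protocol expects at least 30 per subject).
    """
    x = np.asarray(measurements, dtype=float)
    if x.size == 0 or np.any(x <= 0) or not np.isfinite(x).all():
        raise ValueError("measurements must be positive and finite")
    hm = float(x.size / np.sum(1.0 / x))
    flag = ""
    if x.size < 30:
        flag = f"only {x.size} measurements (expected >= 30)"
        warnings.warn(flag)
    return RbmMeasurementSet(x, hm, interval_um, flag)


def clinical_summary_table(
    table: pd.DataFrame,
    group_column: str = "condition",
    categorical: tuple[str, ...] = ("sex", "oral_steroid"),
) -> pd.DataFrame:
    """Compare every numeric column across the two groups of a clinical table.

    Returns a tidy frame (variable, group summaries, test, statistic, p)
    mirroring a study characteristics table.
    """
    groups = sorted(table[group_column].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    a = table[table[group_column] == groups[0]]
    b = table[table[group_column] == groups[1]]
    rows = []
    for col in table.columns:
        if col == group_column:
            continue
        if not pd.api.types.is_numeric_dtype(table[col]):
            continue
        if col in categorical:
            counts_a = [int((a[col] == 1).sum()), int((a[col] != 1).sum())]
            counts_b = [int((b[col] == 1).sum()), int((b[col] != 1).sum())]
            res = compare_groups(counts_a, counts_b, "categorical", variable=col)
        else:
            res = compare_groups(a[col].to_numpy(), b[col].to_numpy(), variable=col)
        rows.append(
            (col, groups[0], res.summary_a, groups[1], res.summary_b, res.test,
             res.statistic, res.p)
        )
    return pd.DataFrame(
        rows,
        columns=["variable", "group_a", "summary_a", "group_b", "summary_b",
                 "test", "statistic", "p"],
    )
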