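"""Gene-wise covariate-adjusted differential expression and sample size.

The "ANCOVA" here is ordinary least squares per gene on a design of
intercept + group indicator + covariates; the group coefficient is the
log2 fold change and its two-sided t-test the raw p-value. Multiplicity
is handled by Benjamini-Hochberg step-up adjustment. The sample-size
calculator controls the expected number of false positives among m
genes via a per-gene two-sided level alpha = FP/m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from dcx.dataset import ExpressionDataset

GROUP_COLUMN = "condition"


@dataclass(frozen=True)
class SampleSizeSpec:
    n_genes: int
    fold: float
    sigma: float
    power: float = 0.8
    expected_fp: float = 4.0

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError("fold must be > 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not (0 < self.power < 1):
            raise ValueError("power must be in (0, 1)")
        if not (0 < self.expected_fp < self.n_genes):
            raise ValueError("expected_fp must be in (0, n_genes)")


def _design_matrix(
    samples: pd.DataFrame, covariates: list[str], reference: str
) -> tuple[np.ndarray, list[str]]:
    conditions = samples[GROUP_COLUMN].to_numpy()
    levels = sorted(set(conditions))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 conditions, got {levels}")
    if reference not in levels:
        raise ValueError(f"reference {reference!r} not among conditions {levels}")
    group = (conditions != reference).astype(float)
    cols = [np.ones(len(samples)), group]
    names = ["intercept", "group"]
    for cov in covariates:
        if cov not in samples.columns:
            raise ValueError(f"covariate {cov!r} missing from sample annotation")
        v = samples[cov].to_numpy(dtype=float)
        cols.append(v)
        names.append(cov)
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # identify the offending column for the error message
        for j in range(2, x.shape[1]):
            sub = x[:, list(range(j)) + [j]]
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                raise ValueError(
                    f"design matrix rank-deficient: column {names[j]!r} is "
                    "confounded with earlier columns"
                )
        raise ValueError("design matrix rank-deficient")
    return x, names


def fit_gene_ancova(
    dataset: ExpressionDataset,
    covariates: list[str] | None = None,
    reference: str = "NEA",
) -> pd.DataFrame:
    """Per-gene OLS of expression on group + covariates.

    Returns a DataFrame (gene, log2fc, p_raw, p_adj, df_resid, flag)
    where log2fc is the group coefficient (non-reference minus
    reference, adjusted). Genes with zero residual variance get p = 1
    and flag ``constant``. The group coding treats ``reference`` as 0.
    """
    covariates = list(covariates or [])
    x, names = _design_matrix(dataset.samples, covariates, reference)
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than parameters ({p})")
    y = dataset.values.T  # samples x genes

    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y                      # p x genes
    resid = y - x @ beta
    df = n - p
    rss = np.sum(resid**2, axis=0)
    sigma2 = rss / df
    se = np.sqrt(np.maximum(sigma2, 0.0) * xtx_inv[1, 1])

    log2fc = beta[1]
    # zero residual variance (constant or perfectly fitted gene): p = 1, flagged
    degenerate = sigma2 <= np.finfo(float).eps * (np.mean(y**2, axis=0) + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(degenerate, 0.0, log2fc / np.where(se > 0, se, np.inf))
    p_raw = np.where(degenerate, 1.0, 2.0 * stats.t.sf(np.abs(tstat), df))

    result = pd.DataFrame(
        {
            "gene": dataset.gene_ids,
            "log2fc": log2fc,
            "p_raw": p_raw,
            "p_adj": bh_adjust(p_raw),
            "df_resid": df,
            "flag": np.where(degenerate, "zero-residual", ""),
        }
    )
    return result


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} min(1, m * p_(j) / j) over the sorted values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D array of p-values")
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted
    return out


def sample_size_efp(spec: SampleSizeSpec) -> tuple[int, float]:
    """Per-group n controlling the expected number of false positives.

    Sets the per-gene two-sided level alpha = expected_fp / m and
    applies the normal-approximation two-sample formula

        n = ceil( 2 * (z_{1-alpha/2} + z_power)^2 * sigma^2 / delta^2 )

    with delta = log2(fold). Returns (n, alpha).
    """
    alpha = spec.expected_fp / spec.n_genes
    delta = math.log2(spec.fold)
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(spec.power)
    n = math.ceil(2.0 * (z_a + z_b) ** 2 * spec.sigma**2 / delta**2)
    return n, alpha
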