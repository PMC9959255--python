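"""Expression preprocessing: background correction, quantile normalization, CV filter.

Pipeline order is background -> quantile -> CV filter. The CV band is
applied on the linear-intensity scale (a CV band of 0.3-10 is only
meaningful there); the optional log2 transform is the last step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from dcx.dataset import ExpressionDataset


@dataclass(frozen=True)
class PreprocConfig:
    bg_method: str = "subtract-floor"
    floor: float = 1.0
    cv_low: float = 0.3
    cv_high: float = 10.0
    log2_output: bool = True

    def __post_init__(self) -> None:
        if self.bg_method not in ("subtract-floor", "none"):
            raise ValueError(f"unknown bg_method {self.bg_method!r}")
        if self.floor <= 0:
            raise ValueError("floor must be > 0")
        if not (0 < self.cv_low < self.cv_high):
            raise ValueError("need 0 < cv_low < cv_high")


def background_correct(raw_signal: np.ndarray, config: PreprocConfig) -> np.ndarray:
    """Replace non-positive (background-over-subtracted) values by the floor.

    Strictly positive values are untouched, so their order is preserved.
    The log2 transform, when requested, is applied by the caller at the
    end of the pipeline, not here.
    """
    m = np.asarray(raw_signal, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("raw signal contains non-finite values")
    if config.bg_method == "none":
        return m.copy()
    out = m.copy()
    out[out <= 0] = config.floor
    return out


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns (samples) of a genes x samples matrix.

    Each column's sorted values are replaced by the across-column means
    of the order statistics; tied values within a column receive the
    mean of the reference values their ranks would span. Afterwards all
    columns share an identical sorted value multiset.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if np.isnan(m).any():
        raise ValueError("missing values not supported")
    if m.shape[1] < 2:
        warnings.warn("quantile normalization of a single column is the identity")
        return m.copy()

    order = np.argsort(m, axis=0, kind="stable")
    reference = np.sort(m, axis=0).mean(axis=1)

    out = np.empty_like(m)
    for j in range(m.shape[1]):
        col = m[:, j]
        idx = order[:, j]
        sorted_col = col[idx]
        assigned = reference.copy()
        # average the reference over each tie block
        start = 0
        for k in range(1, len(sorted_col) + 1):
            if k == len(sorted_col) or sorted_col[k] != sorted_col[start]:
                if k - start > 1:
                    assigned[start:k] = reference[start:k].mean()
                start = k
        out[idx, j] = assigned
    return out


def cv_filter(
    matrix: np.ndarray,
    gene_ids: list[str],
    cv_low: float = 0.3,
    cv_high: float = 10.0,
) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Keep genes whose coefficient of variation (sd/mean, sd with n-1)
    lies in [cv_low, cv_high]; the matrix must be on the intensity scale.

    Returns the filtered matrix, kept gene ids, and a per-gene report
    (gene, cv, kept, reason).
    """
    m = np.asarray(matrix, dtype=float)
    if m.shape[0] != len(gene_ids):
        raise ValueError("gene_ids length mismatch")
    mean = m.mean(axis=1)
    sd = m.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)

    kept = np.zeros(len(gene_ids), dtype=bool)
    reasons = []
    for i in range(len(gene_ids)):
        if not mean[i] > 0:
            reasons.append("non-positive mean")
        elif cv[i] < cv_low:
            reasons.append("cv below band")
        elif cv[i] > cv_high:
            reasons.append("cv above band")
        else:
            kept[i] = True
            reasons.append("")
    report = pd.DataFrame({"gene": gene_ids, "cv": cv, "kept": kept, "reason": reasons})
    kept_ids = [g for g, k in zip(gene_ids, kept) if k]
    return m[kept], kept_ids, report


def preprocess_dataset(
    dataset: ExpressionDataset, config: PreprocConfig | None = None
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Run background -> quantile normalization -> CV filter on a raw dataset.

    Input must be on the intensity scale; output is log2 when
    ``config.log2_output`` (the default). Returns the processed dataset
    and the CV-filter report.
    """
    config = config or PreprocConfig()
    if dataset.log2:
        raise ValueError("preprocess expects intensity-scale input (log2=False)")
    corrected = background_correct(dataset.values, config)
    normalized = quantile_normalize(corrected)
    filtered, kept_ids, report = cv_filter(
        normalized, dataset.gene_ids, config.cv_low, config.cv_high
    )
    values = np.log2(filtered) if config.log2_output else filtered
    out = ExpressionDataset(
        values,
        kept_ids,
        dataset.samples,
        log2=config.log2_output,
        stage="filtered",
    )
    return out, report
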