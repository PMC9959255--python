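"""Core expression-dataset container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: recognised provenance stages, in pipeline order
STAGES = ("raw", "corrected", "normalized", "filtered")


@dataclass
class ExpressionDataset:
    """A genes x samples matrix plus per-sample annotations.

    Parameters
    ----------
    values : ndarray, shape (n_genes, n_samples)
        Expression values. ``log2`` records whether they are on the
        log2 scale.
    gene_ids : list of str
        Row identifiers, unique.
    samples : pandas.DataFrame
        One row per sample (index = sample id). Must contain a
        ``condition`` column; covariate columns (age, sex, bmi, ocs)
        are optional.
    log2 : bool
        True when ``values`` are log2 intensities.
    stage : str
        Provenance flag, one of :data:`STAGES`.
    """

    values: np.ndarray
    gene_ids: list[str]
    samples: pd.DataFrame
    log2: bool = True
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        if self.values.shape[0] != len(self.gene_ids):
            raise ValueError(
                f"{self.values.shape[0]} rows but {len(self.gene_ids)} gene ids"
            )
        if self.values.shape[1] != len(self.samples):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.samples)} sample rows"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if "condition" not in self.samples.columns:
            raise ValueError("sample annotation must contain a 'condition' column")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    @property
    def conditions(self) -> np.ndarray:
        return self.samples["condition"].to_numpy()

    def condition_matrix(self, condition: str) -> np.ndarray:
        """Sub-matrix (genes x samples) of one condition's samples."""
        mask = self.conditions == condition
        if not mask.any():
            raise ValueError(f"no samples with condition {condition!r}")
        return self.values[:, mask]

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionDataset":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"unknown gene ids: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return replace(self, values=self.values[rows], gene_ids=list(gene_ids))

    def with_stage(self, values: np.ndarray, stage: str, log2: bool | None = None) -> "ExpressionDataset":
        """New dataset with replaced values and updated provenance flag."""
        return replace(
            self,
            values=values,
            stage=stage,
            log2=self.log2 if log2 is None else log2,
        )
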