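"""Resampling-based differential co-expression analysis.

Genes are clustered by correlation distance (1 - Pearson r) in one
condition; each resulting group is scored in both conditions by a
one-sample t-statistic over its within-group pairwise correlations, and
the statistic's non-randomness is assessed against B random gene groups
of the same size drawn from the same condition's matrix. A group is a
differential co-expression group (DCG) when its correlations are
non-random in EA (p < alpha) and random in NEA (p >= alpha). Groups are
ranked by the mean pairwise correlation difference r_EA - r_NEA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from dcx.dataset import ExpressionDataset

EA = "EA"
NEA = "NEA"


@dataclass(frozen=True)
class CoexParams:
    cluster_condition: str = EA
    linkage: str = "average"
    cut_height: float = 0.6
    min_group: int = 3
    n_resamples: int = 1000
    alpha: float = 0.05
    seed: int = 0
    fisher_z: bool = False   # apply atanh to correlations before the t-statistic

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_resamples < 100:
            raise ValueError("n_resamples must be >= 100")
        if self.min_group < 3:
            raise ValueError("min_group must be >= 3")
        if self.linkage not in ("average", "complete"):
            raise ValueError("linkage must be 'average' or 'complete'")
        if not (0 < self.cut_height < 2):
            raise ValueError("cut_height must be in (0, 2)")


@dataclass
class CoexGroup:
    genes: list[str]
    t_EA: float
    t_NEA: float
    p_EA: float
    p_NEA: float
    mean_dr: float
    is_dcg: bool

    @property
    def size(self) -> int:
        return len(self.genes)


def pairwise_correlations(sub_matrix: np.ndarray, gene_ids: list[str] | None = None) -> np.ndarray:
    """Pearson r for all unordered gene pairs of a genes x samples block.

    Pairs are enumerated row-major: (0,1), (0,2), ..., (1,2), ...;
    length k(k-1)/2. A zero-variance gene raises an error naming it.
    """
    m = np.asarray(sub_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need >= 2 genes")
    if m.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    sd = m.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        name = gene_ids[bad] if gene_ids else f"row {bad}"
        raise ValueError(f"zero-variance gene: {name}")
    r = np.corrcoef(m)
    iu = np.triu_indices(m.shape[0], k=1)
    return np.clip(r[iu], -1.0, 1.0)


def group_statistic(correlations: np.ndarray, fisher_z: bool = False) -> float:
    """One-sample t of within-group pairwise correlations against zero.

    t = mean / (sd / sqrt(n_pairs)), sd with n-1. Zero spread returns
    +inf, -inf or 0 depending on the sign of the mean.
    """
    r = np.asarray(correlations, dtype=float)
    if r.size < 3:
        raise ValueError("need >= 3 pairwise correlations")
    if fisher_z:
        r = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    mean = r.mean()
    sd = r.std(ddof=1)
    if sd == 0:
        return math.inf if mean > 0 else (-math.inf if mean < 0 else 0.0)
    return float(mean / (sd / math.sqrt(r.size)))


def cluster_genes(matrix_in_condition: np.ndarray, params: CoexParams) -> list[np.ndarray]:
    """Agglomerative clustering on 1 - r distance, cut at ``cut_height``.

    Returns groups of gene row indices with at least ``min_group``
    members, ordered by smallest member index; deterministic for a given
    input.
    """
    m = np.asarray(matrix_in_condition, dtype=float)
    if m.shape[0] < params.min_group:
        raise ValueError(f"need at least {params.min_group} genes")
    r = np.corrcoef(m)
    dist = 1.0 - np.clip(r, -1.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    condensed = squareform((dist + dist.T) / 2.0, checks=False)
    z = hierarchy.linkage(condensed, method=params.linkage)
    labels = hierarchy.fcluster(z, t=params.cut_height, criterion="distance")
    groups = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size >= params.min_group:
            groups.append(idx)
    groups.sort(key=lambda idx: int(idx[0]))
    return groups


def _standardize(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance gene in pool")
    return (m - mu) / sd


def _group_t_from_z(z: np.ndarray, idx: np.ndarray, fisher_z: bool) -> float:
    n = z.shape[1]
    r = (z[idx] @ z[idx].T) / (n - 1)
    iu = np.triu_indices(idx.size, k=1)
    return group_statistic(np.clip(r[iu], -1.0, 1.0), fisher_z=fisher_z)


def resample_null_p(
    matrix_in_condition: np.ndarray,
    group_size: int,
    observed_t: float,
    n_resamples: int = 1000,
    seed: int = 0,
    fisher_z: bool = False,
) -> float:
    """One-sided resampling p-value of a group t-statistic.

    Draws ``n_resamples`` uniform random gene sets of ``group_size``
    from the full gene pool, computes the group statistic for each in
    the same condition, and returns the add-one estimator
    ``(1 + #{t_null >= t_obs}) / (B + 1)`` (always > 0).
    """
    m = np.asarray(matrix_in_condition, dtype=float)
    if group_size < 3:
        raise ValueError("group_size must be >= 3")
    if m.shape[0] < 2 * group_size:
        raise ValueError(
            f"gene pool ({m.shape[0]}) too small for group size {group_size}"
        )
    z = _standardize(m)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_resamples):
        idx = rng.choice(m.shape[0], size=group_size, replace=False)
        if _group_t_from_z(z, idx, fisher_z) >= observed_t:
            exceed += 1
    return (1 + exceed) / (n_resamples + 1)


def differential_coexpression(
    dataset: ExpressionDataset, params: CoexParams | None = None
) -> list[CoexGroup]:
    """Full differential co-expression analysis of a two-condition dataset.

    Clusters genes in ``params.cluster_condition``; for every group of
    at least ``min_group`` genes computes the correlation t-statistic
    and its resampling p-value in each condition (nulls drawn from that
    condition's matrix), flags DCGs by p_EA < alpha and p_NEA >= alpha,
    and returns groups sorted by mean pairwise correlation difference
    (descending), ties by group size then gene ids.
    """
    params = params or CoexParams()
    conditions = sorted(set(dataset.conditions))
    if conditions != [EA, NEA]:
        raise ValueError(f"need conditions {{'EA', 'NEA'}}, got {conditions}")
    if params.cluster_condition not in conditions:
        raise ValueError(f"cluster_condition {params.cluster_condition!r} not in {conditions}")

    mats = {c: dataset.condition_matrix(c) for c in conditions}
    zs = {c: _standardize(mats[c]) for c in conditions}
    groups_idx = cluster_genes(mats[params.cluster_condition], params)

    rng = np.random.default_rng(params.seed)
    results = []
    for idx in groups_idx:
        per_cond: dict[str, tuple[float, float, np.ndarray]] = {}
        for cond in (EA, NEA):
            corr = pairwise_correlations(
                mats[cond][idx], [dataset.gene_ids[i] for i in idx]
            )
            t = group_statistic(corr, fisher_z=params.fisher_z)
            p = _resample_p_from_z(
                zs[cond], idx.size, t, params.n_resamples, rng, params.fisher_z
            )
            per_cond[cond] = (t, p, corr)
        t_ea, p_ea, corr_ea = per_cond[EA]
        t_nea, p_nea, corr_nea = per_cond[NEA]
        results.append(
            CoexGroup(
                genes=[dataset.gene_ids[i] for i in idx],
                t_EA=t_ea,
                t_NEA=t_nea,
                p_EA=p_ea,
                p_NEA=p_nea,
                mean_dr=float(np.mean(corr_ea - corr_nea)),
                is_dcg=bool(p_ea < params.alpha and p_nea >= params.alpha),
            )
        )

    results.sort(key=lambda g: (-g.mean_dr, -g.size, tuple(g.genes)))
    return results


def _resample_p_from_z(
    z: np.ndarray,
    group_size: int,
    observed_t: float,
    n_resamples: int,
    rng: np.random.Generator,
    fisher_z: bool,
) -> float:
    if z.shape[0] < 2 * group_size:
        raise ValueError("gene pool too small for resampling")
    exceed = 0
    for _ in range(n_resamples):
        idx = rng.choice(z.shape[0], size=group_size, replace=False)
        if _group_t_from_z(z, idx, fisher_z) >= observed_t:
            exceed += 1
    return (1 + exceed) / (n_resamples + 1)
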