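"""Synthetic data generation with full ground-truth records.

Every input the pipeline consumes can be simulated here: expression
matrices with planted differential-expression effects and correlated
gene modules, clinical/biomarker tables, and grayscale array-scan
images with positioning markers and known spot geometry.

The expression generator uses a single-latent-factor model per module
and condition: a gene in a module with target correlation ``rho`` is

    x = mu_g + sd * (sqrt(rho) * F_s + sqrt(1 - rho) * eps_gs)

with ``F_s`` shared within the module for sample ``s`` and ``eps``
independent, so the expected within-module pairwise correlation equals
``rho`` exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dcx.dataset import ExpressionDataset

EA = "EA"
NEA = "NEA"

MAX_INTENSITY = 65535.0


@dataclass(frozen=True)
class ModuleSpec:
    """A planted gene module with condition-specific pairwise correlation."""

    size: int
    rho_EA: float
    rho_NEA: float

    def __post_init__(self) -> None:
        if self.size < 3:
            raise ValueError("module size must be >= 3")
        for name, rho in (("rho_EA", self.rho_EA), ("rho_NEA", self.rho_NEA)):
            if not (0.0 <= rho < 1.0):
                raise ValueError(f"{name}={rho} outside [0, 1)")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic two-group expression experiment."""

    n_genes: int
    n_per_group: int = 20
    de_fraction: float = 0.0
    de_log2fc: float = 1.0
    gene_sd: float = 0.7
    modules: tuple[ModuleSpec, ...] = ()
    covariate_effects: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    baseline_range: tuple[float, float] = (6.0, 12.0)

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ValueError("de_fraction must be in [0, 1]")
        if self.gene_sd <= 0:
            raise ValueError("gene_sd must be > 0")
        if sum(m.size for m in self.modules) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        object.__setattr__(self, "modules", tuple(self.modules))


@dataclass
class GroundTruth:
    """Planted truth accompanying a simulated artifact."""

    de_genes: dict[str, float] = field(default_factory=dict)
    module_membership: dict[str, int] = field(default_factory=dict)
    planted_spot_intensities: np.ndarray | None = None
    spot_centers: np.ndarray | None = None
    marker_centers: np.ndarray | None = None
    baseline: float | None = None

    def module_genes(self, module_index: int) -> list[str]:
        return [g for g, m in self.module_membership.items() if m == module_index]


COVARIATE_COLUMNS = ("age", "sex", "bmi", "ocs")


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Covariate fixtures: age uniform 20-70 y, BMI lognormal, binary sex/OCS."""
    return pd.DataFrame(
        {
            "age": rng.uniform(20.0, 70.0, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "bmi": rng.lognormal(mean=math.log(25.0), sigma=0.15, size=n),
            "ocs": (rng.random(n) < 0.25).astype(float),
        }
    )


def generate_expression_dataset(config: SimConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Simulate a log2-scale two-group expression matrix with planted truth.

    Deterministic for a fixed ``config`` (the seed lives inside it).
    Returns the dataset (EA samples first) and the ground-truth record of
    differential genes and module membership.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_per_group
    n_samples = 2 * n
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    conditions = np.array([EA] * n + [NEA] * n)

    samples = _draw_covariates(rng, n_samples)
    samples.insert(0, "condition", conditions)
    samples.index = pd.Index(
        [f"{c}{i % n + 1:02d}" for i, c in enumerate(conditions)], name="sample"
    )

    mu = rng.uniform(*config.baseline_range, size=config.n_genes)
    values = mu[:, None] + config.gene_sd * rng.standard_normal((config.n_genes, n_samples))

    truth = GroundTruth()

    # planted modules: disjoint blocks of a random gene permutation
    perm = rng.permutation(config.n_genes)
    offset = 0
    for m_idx, spec in enumerate(config.modules):
        rows = perm[offset : offset + spec.size]
        offset += spec.size
        for cond, rho in ((EA, spec.rho_EA), (NEA, spec.rho_NEA)):
            cols = np.flatnonzero(conditions == cond)
            factor = rng.standard_normal(cols.size)
            eps = rng.standard_normal((spec.size, cols.size))
            values[np.ix_(rows, cols)] = (
                mu[rows, None]
                + config.gene_sd * (math.sqrt(rho) * factor[None, :] + math.sqrt(1.0 - rho) * eps)
            )
        for r in rows:
            truth.module_membership[gene_ids[r]] = m_idx

    # planted DE: add the log2 effect to the EA group
    n_de = int(round(config.de_fraction * config.n_genes))
    if n_de:
        de_rows = rng.choice(config.n_genes, size=n_de, replace=False)
        values[np.ix_(de_rows, np.flatnonzero(conditions == EA))] += config.de_log2fc
        truth.de_genes = {gene_ids[r]: config.de_log2fc for r in sorted(de_rows)}

    # linear covariate effects, independent of condition
    for cov, beta in config.covariate_effects.items():
        if cov not in samples.columns:
            raise KeyError(f"unknown covariate {cov!r}")
        values += beta * samples[cov].to_numpy()[None, :]

    dataset = ExpressionDataset(values, gene_ids, samples, log2=True, stage="normalized")
    return dataset, truth


def to_intensity_scale(dataset: ExpressionDataset) -> ExpressionDataset:
    """Inverse-transform a log2 dataset to the raw-intensity scale (2**x)."""
    if not dataset.log2:
        raise ValueError("dataset is already on the intensity scale")
    return dataset.with_stage(np.exp2(dataset.values), stage="raw", log2=False)


def generate_clinical_table(n_per_group: int, seed: int) -> pd.DataFrame:
    """Simulate a per-sample clinical/biomarker table.

    EA rows have BAL eosinophils >= 1 %, NEA rows < 1 %, and blood
    eosinophil counts are drawn with a higher EA location (lognormal
    medians 480 vs 140 cells/uL).
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_per_group
    conditions = np.array([EA] * n + [NEA] * n)
    table = _draw_covariates(rng, 2 * n)
    table.insert(0, "condition", conditions)
    table = table.rename(columns={"ocs": "oral_steroid"})

    bal = np.empty(2 * n)
    bal[:n] = 1.0 + rng.lognormal(mean=1.0, sigma=0.8, size=n)       # EA: >= 1 %
    bal[n:] = rng.uniform(0.0, 1.0, size=n) * 0.999                  # NEA: < 1 %
    table["bal_eos_pct"] = bal

    blood = np.empty(2 * n)
    blood[:n] = rng.lognormal(mean=math.log(480.0), sigma=0.6, size=n)
    blood[n:] = rng.lognormal(mean=math.log(140.0), sigma=0.6, size=n)
    table["blood_eos"] = blood

    # extra numeric biomarkers (arbitrary columns downstream stats accept)
    table["feno_ppb"] = rng.lognormal(mean=math.log(30.0), sigma=0.5, size=2 * n)
    table["ige_iu_ml"] = rng.lognormal(mean=math.log(150.0), sigma=0.9, size=2 * n)

    table.index = pd.Index(
        [f"{c}{i % n + 1:02d}" for i, c in enumerate(conditions)], name="sample"
    )
    return table


# ---------------------------------------------------------------------------
# array-scan rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AffineParams:
    """Rigid-ish displacement of the nominal grid: rotation then translation."""

    dx: float = 0.0
    dy: float = 0.0
    rotation_deg: float = 0.0
    scale: float = 1.0

    def matrix(self) -> np.ndarray:
        """2x3 matrix mapping nominal (x, y) to displaced (x, y)."""
        th = math.radians(self.rotation_deg)
        c, s = self.scale * math.cos(th), self.scale * math.sin(th)
        return np.array([[c, -s, self.dx], [s, c, self.dy]])

    def apply(self, xy: np.ndarray) -> np.ndarray:
        m = self.matrix()
        return xy @ m[:, :2].T + m[:, 2]


@dataclass
class ArrayScan:
    """A rendered 16-bit scan image plus the layout used to draw it."""

    image: np.ndarray
    layout: "object"  # GridLayout; typed loosely to avoid a circular import


def _render_gaussian(canvas: np.ndarray, cx: float, cy: float, sigma: float, amp: float) -> None:
    r = int(math.ceil(4 * sigma))
    x0, x1 = max(0, int(cx) - r), min(canvas.shape[1], int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(canvas.shape[0], int(cy) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - cx
    ys = np.arange(y0, y1) - cy
    d2 = ys[:, None] ** 2 + xs[None, :] ** 2
    canvas[y0:y1, x0:x1] += amp * np.exp(-d2 / (2.0 * sigma**2))


def _render_disc(canvas: np.ndarray, cx: float, cy: float, radius: float, amp: float) -> None:
    r = int(math.ceil(radius)) + 1
    x0, x1 = max(0, int(cx) - r), min(canvas.shape[1], int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(canvas.shape[0], int(cy) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - cx
    ys = np.arange(y0, y1) - cy
    d2 = ys[:, None] ** 2 + xs[None, :] ** 2
    canvas[y0:y1, x0:x1] += amp * (d2 <= radius**2)


def generate_array_scan(
    layout,
    intensities: np.ndarray,
    displacement: AffineParams | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    jitter_max: float = 0.0,
    baseline: float = 1000.0,
    marker_amp: float = 55000.0,
) -> tuple[ArrayScan, GroundTruth]:
    """Render a synthetic 16-bit scan with Gaussian spots and disc markers.

    Spots sit at affine-transformed nominal lattice positions plus
    optional uniform jitter bounded by ``jitter_max``; positioning
    markers are solid discs of ``layout.marker_radius`` at the
    transformed anchor positions. The returned truth records exact
    centers and planted amplitudes.
    """
    intensities = np.asarray(intensities, dtype=float)
    if intensities.shape != (layout.rows, layout.cols):
        raise ValueError(
            f"intensities shape {intensities.shape} != layout {(layout.rows, layout.cols)}"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    displacement = displacement or AffineParams()
    rng = np.random.default_rng(seed)

    nominal = layout.nominal_positions()            # (rows*cols, 2) of (x, y)
    centers = displacement.apply(nominal)
    if jitter_max > 0:
        centers = centers + rng.uniform(-jitter_max, jitter_max, size=centers.shape)
    marker_nominal = layout.nominal_marker_positions()
    marker_centers = displacement.apply(marker_nominal)

    h, w = layout.canvas_shape()
    all_xy = np.vstack([centers, marker_centers])
    if (all_xy[:, 0].min() < 0 or all_xy[:, 0].max() > w - 1
            or all_xy[:, 1].min() < 0 or all_xy[:, 1].max() > h - 1):
        raise ValueError("displaced spot or marker centers fall outside the canvas")

    canvas = np.full((h, w), float(baseline))
    sigma = layout.spot_radius / 2.0
    for (cx, cy), amp in zip(centers, intensities.ravel()):
        _render_gaussian(canvas, cx, cy, sigma, amp)
    for cx, cy in marker_centers:
        _render_disc(canvas, cx, cy, layout.marker_radius, marker_amp)

    if noise_sd > 0:
        canvas += rng.normal(0.0, noise_sd, canvas.shape)
    image = np.clip(canvas, 0.0, MAX_INTENSITY).astype(np.uint16)

    truth = GroundTruth(
        planted_spot_intensities=intensities.copy(),
        spot_centers=centers.reshape(layout.rows, layout.cols, 2),
        marker_centers=marker_centers,
        baseline=float(baseline),
    )
    return ArrayScan(image=image, layout=layout), truth
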