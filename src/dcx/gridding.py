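"""Array-scan gridding: MSER marker detection, affine grid fit, spot quantification.

Positioning markers are located with a maximally-stable-extremal-regions
detector built on a max-tree (component tree) of the image: connected
components of the superlevel sets ``{I >= t}`` are tracked across all
thresholds and a component is reported when its relative area change
over an intensity window ``delta`` is small.

Stability definition (shared with the brute-force test oracle): for a
component C existing at level ``l`` with seed pixel s (brightest pixel
of C),

    psi(C) = (A(l - delta) - A(l + delta)) / A(l)

where ``A(t)`` is the area of the connected component of ``{I >= t}``
containing s, with t clamped into [root level, level of s] so that A is
defined at every threshold.

Coordinate convention: x = column, y = row, origin top-left, pixel
centers at integer coordinates. 4-connectivity.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridLayout:
    """Nominal geometry of a spot grid plus positioning markers.

    ``marker_anchors`` are lattice coordinates (row, col); the default
    places four markers one pitch outside the spot lattice corners so
    markers never overlap spots.
    """

    rows: int
    cols: int
    pitch: float
    spot_radius: float
    marker_radius: float | None = None
    marker_anchors: tuple[tuple[float, float], ...] | None = None
    margin: float | None = None  # canvas margin in px; default 2 * pitch

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if self.pitch <= 2 * self.spot_radius:
            raise ValueError("pitch must exceed 2 * spot_radius")
        if self.marker_radius is None:
            object.__setattr__(self, "marker_radius", 2.0 * self.spot_radius)
        if self.marker_anchors is None:
            r, c = self.rows, self.cols
            object.__setattr__(
                self,
                "marker_anchors",
                ((-1.0, -1.0), (-1.0, float(c)), (float(r), -1.0), (float(r), float(c))),
            )
        else:
            object.__setattr__(
                self, "marker_anchors", tuple((float(a), float(b)) for a, b in self.marker_anchors)
            )
        if self.margin is None:
            object.__setattr__(self, "margin", 2.0 * self.pitch)

    def lattice_to_xy(self, row_col: np.ndarray) -> np.ndarray:
        """Map lattice (row, col) coordinates to nominal pixel (x, y)."""
        rc = np.asarray(row_col, dtype=float)
        x = self.margin + rc[..., 1] * self.pitch
        y = self.margin + rc[..., 0] * self.pitch
        return np.stack([x, y], axis=-1)

    def nominal_positions(self) -> np.ndarray:
        """(rows*cols, 2) nominal spot centers (x, y), row-major."""
        rr, cc = np.meshgrid(np.arange(self.rows), np.arange(self.cols), indexing="ij")
        return self.lattice_to_xy(np.stack([rr.ravel(), cc.ravel()], axis=-1))

    def nominal_marker_positions(self) -> np.ndarray:
        return self.lattice_to_xy(np.asarray(self.marker_anchors))

    def canvas_shape(self) -> tuple[int, int]:
        h = int(math.ceil(2 * self.margin + self.rows * self.pitch))
        w = int(math.ceil(2 * self.margin + self.cols * self.pitch))
        return h, w


@dataclass(frozen=True)
class MserParams:
    """Detector parameters; areas in px^2, delta in intensity units."""

    delta: float = 2.0
    min_area: float = 10.0
    max_area: float = 1000.0
    max_stability: float = 0.5
    bright_on_dark: bool = True

    def __post_init__(self) -> None:
        if self.delta < 1:
            raise ValueError("delta must be >= 1")
        if not (0 < self.min_area < self.max_area):
            raise ValueError("need 0 < min_area < max_area")

    @classmethod
    def for_layout(cls, layout: GridLayout, **overrides) -> "MserParams":
        """Defaults with the area band sized to the layout's marker radius."""
        area = math.pi * layout.marker_radius**2
        kw = dict(min_area=0.5 * area, max_area=2.0 * area)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def for_scan(cls, image: np.ndarray, layout: GridLayout, **overrides) -> "MserParams":
        """Layout-sized area band with delta scaled to the image dynamic range.

        delta defaults to 2 intensity steps on an 8-bit-equivalent scale
        (range / 128), which keeps the stability window above the noise
        granularity of high-bit-depth scans.
        """
        rng = float(np.ptp(np.asarray(image)))
        delta = max(2.0, rng / 128.0)
        kw = dict(delta=delta)
        kw.update(overrides)
        return cls.for_layout(layout, **kw)


@dataclass(frozen=True)
class DetectedRegion:
    centroid: tuple[float, float]      # (x, y), intensity-weighted, sub-pixel
    area: int
    stability: float
    level: float                       # threshold at which the region was taken


@dataclass
class SpotGrid:
    """Affine map from the nominal lattice to image coordinates."""

    affine: np.ndarray                 # 2x3; maps nominal (x, y) -> image (x, y)
    spot_centers: np.ndarray           # (rows, cols, 2)
    residual_rms: float
    matched_anchors: list[tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=list
    )

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return xy @ self.affine[:, :2].T + self.affine[:, 2]


# ---------------------------------------------------------------------------
# max-tree construction
# ---------------------------------------------------------------------------

class MaxTree:
    """Union-find max-tree of superlevel-set components.

    Attributes (all length n = number of pixels):

    - ``parent``: canonicalized pixel tree; ``parent[p] == p`` at the root.
      Canonical pixels (one per component/level node) are marked in
      ``is_node``.
    - ``area``: for canonical pixels, the area of the component of
      ``{I >= level(p)}`` containing p.
    - ``seed``: brightest pixel of the node's subtree.
    - centroid accumulators ``wsum/wx/wy`` (intensity-weighted).
    """

    def __init__(self, img: np.ndarray):
        h, w = img.shape
        n = h * w
        flat = img.ravel().astype(np.int64)
        order = np.argsort(-flat, kind="stable")  # bright first, raster ties
        parent = np.full(n, -1, dtype=np.int64)
        zpar = np.full(n, -1, dtype=np.int64)
        uf_root = np.full(n, -1, dtype=np.int64)  # tree root of each uf set

        def find(x: int) -> int:
            root = x
            while zpar[root] != root:
                root = zpar[root]
            while zpar[x] != root:
                zpar[x], x = root, zpar[x]
            return root

        for p in order:
            p = int(p)
            parent[p] = p
            zpar[p] = p
            uf_root[p] = p
            y, x = divmod(p, w)
            for q in (p - w if y > 0 else -1,
                      p + w if y < h - 1 else -1,
                      p - 1 if x > 0 else -1,
                      p + 1 if x < w - 1 else -1):
                if q < 0 or zpar[q] < 0:
                    continue
                r = find(q)
                if r != p:
                    parent[uf_root[r]] = p
                    zpar[r] = p
                    uf_root[r] = p

        # canonicalize: iterate from last processed (root side) to first so
        # parents are canonical before their children are re-pointed
        for p in order[::-1]:
            p = int(p)
            q = parent[p]
            if flat[parent[q]] == flat[q]:
                parent[p] = parent[q]

        # bottom-up accumulation: children were processed before parents,
        # so a forward sweep pushes complete subtotals upward
        area = np.ones(n, dtype=np.int64)
        weight = flat.astype(np.float64)
        ys, xs = np.divmod(np.arange(n), w)
        wsum = weight.copy()
        wx = weight * xs
        wy = weight * ys
        seed = np.arange(n)
        for p in order:
            p = int(p)
            q = int(parent[p])
            if q != p:
                area[q] += area[p]
                wsum[q] += wsum[p]
                wx[q] += wx[p]
                wy[q] += wy[p]
                if flat[seed[p]] > flat[seed[q]]:
                    seed[q] = seed[p]

        self.flat = flat
        self.parent = parent
        self.order = order
        self.area = area
        self.wsum, self.wx, self.wy = wsum, wx, wy
        self.seed = seed
        self.is_node = (flat[parent] != flat) | (parent == np.arange(n))
        canon = np.arange(n)
        canon[~self.is_node] = parent[~self.is_node]
        self.canon = canon

    def component_area_at(self, pixel: int, t: float) -> int:
        """Area of the component of {I >= t} containing ``pixel``.

        t above the pixel's level clamps to the pixel's leaf node; t below
        the root level clamps to the root.
        """
        if self.flat[pixel] < t:
            t = self.flat[pixel]
        c = int(self.canon[pixel])
        while self.parent[c] != c and self.flat[self.parent[c]] >= t:
            c = int(self.parent[c])
        return int(self.area[c])

    def stability(self, node: int, delta: float) -> float:
        """psi = (A(l - delta) - A(l + delta)) / A(l) through the seed."""
        l = float(self.flat[node])
        s = int(self.seed[node])
        a_lo = self.component_area_at(s, l - delta)
        a_hi = self.component_area_at(s, l + delta)
        return (a_lo - a_hi) / float(self.area[node])

    def is_ancestor(self, a: int, b: int) -> bool:
        """True when canonical node ``a`` is on ``b``'s root path (a != b ok)."""
        c = b
        while True:
            if c == a:
                return True
            if self.parent[c] == c:
                return False
            c = int(self.parent[c])


def detect_markers(image: np.ndarray, params: MserParams) -> list[DetectedRegion]:
    """Detect maximally stable extremal regions in a 2-D grayscale image.

    Reports components with area in ``[min_area, max_area]`` and
    stability ``psi <= max_stability``; nested candidates are collapsed
    to the most stable one. Returns regions sorted by stability, most
    stable first; a constant image yields an empty list.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("image must be 2-D single-channel")
    if img.size == 0:
        raise ValueError("empty image")
    if img.max() == img.min():
        return []
    work = img.astype(np.int64)
    if not params.bright_on_dark:
        work = work.max() - work

    tree = MaxTree(work)
    cand_idx = np.flatnonzero(
        tree.is_node & (tree.area >= params.min_area) & (tree.area <= params.max_area)
    )
    candidates = []
    for node in cand_idx:
        psi = tree.stability(int(node), params.delta)
        if psi <= params.max_stability:
            candidates.append((psi, int(node)))
    candidates.sort()

    kept: list[tuple[float, int]] = []
    for psi, node in candidates:
        nested = any(
            tree.is_ancestor(k, node) or tree.is_ancestor(node, k) for _, k in kept
        )
        if not nested:
            kept.append((psi, node))

    return [
        DetectedRegion(
            centroid=(float(tree.wx[n] / tree.wsum[n]), float(tree.wy[n] / tree.wsum[n])),
            area=int(tree.area[n]),
            stability=float(psi),
            level=float(tree.flat[n]),
        )
        for psi, n in kept
    ]


# ---------------------------------------------------------------------------
# grid fitting
# ---------------------------------------------------------------------------

def _affine_lstsq(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares 2x3 affine src -> dst; returns (matrix, residual rms)."""
    a = np.column_stack([src, np.ones(len(src))])
    if np.linalg.matrix_rank(a) < 3:
        raise ValueError("collinear anchors: affine fit is singular")
    coef, *_ = np.linalg.lstsq(a, dst, rcond=None)
    resid = a @ coef - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return coef.T, rms


def _similarity_prealign(anchors: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Crude similarity (scale + translation) mapping anchors near pts."""
    ca, cp = anchors.mean(axis=0), pts.mean(axis=0)
    ra = np.sqrt(((anchors - ca) ** 2).sum(axis=1).mean())
    rp = np.sqrt(((pts - cp) ** 2).sum(axis=1).mean())
    s = rp / ra if ra > 0 else 1.0
    return (anchors - ca) * s + cp


def fit_grid(markers: list[DetectedRegion], layout: GridLayout) -> SpotGrid:
    """Fit the affine grid from detected markers and layout anchors.

    Correspondence is chosen by exhaustive assignment minimising the fit
    residual when at most 8 markers (and anchors) are involved;
    otherwise markers are matched to anchors by nearest neighbour after
    a similarity pre-alignment. Requires >= 3 non-collinear anchors.
    """
    anchors = layout.nominal_marker_positions()
    n_anchor = len(anchors)
    if len(markers) < 3 or n_anchor < 3:
        raise ValueError("need >= 3 markers and >= 3 anchors to fit an affine grid")
    if np.linalg.matrix_rank(np.column_stack([anchors, np.ones(n_anchor)])) < 3:
        raise ValueError("collinear anchors: affine fit is singular")

    pool = sorted(markers, key=lambda r: r.stability)[:8]
    pts = np.array([r.centroid for r in pool])

    if n_anchor <= len(pool) <= 8:
        # symmetric marker layouts admit several residual-free assignments
        # (rotations/reflections of the anchor set); among near-equal
        # residuals prefer the affine closest to the identity, since scans
        # are only mildly displaced
        best: tuple[float, float, np.ndarray, tuple[int, ...]] | None = None
        for assign in itertools.permutations(range(len(pool)), n_anchor):
            coef, rms = _affine_lstsq(anchors, pts[list(assign)])
            dev = float(np.linalg.norm(coef[:, :2] - np.eye(2)))
            key = (round(rms, 6), dev)
            if best is None or key < (best[0], best[1]):
                best = (*key, coef, assign)
        assert best is not None
        _, _, affine, assign = best
        _, rms = _affine_lstsq(anchors, pts[list(assign)])
        matched_pts = pts[list(assign)]
    else:
        aligned = _similarity_prealign(anchors, pts)
        assign = []
        for a in aligned:
            d = np.sum((pts - a) ** 2, axis=1)
            assign.append(int(np.argmin(d)))
        matched_pts = pts[assign]
        affine, rms = _affine_lstsq(anchors, matched_pts)

    nominal = layout.nominal_positions()
    centers = (nominal @ affine[:, :2].T + affine[:, 2]).reshape(layout.rows, layout.cols, 2)
    matched = [
        (tuple(layout.marker_anchors[i]), (float(p[0]), float(p[1])))
        for i, p in enumerate(matched_pts)
    ]
    return SpotGrid(affine=affine, spot_centers=centers, residual_rms=rms, matched_anchors=matched)


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

FLAG_OK = "ok"
FLAG_LOW = "low"
FLAG_CLIPPED = "clipped"


def quantify_spots(image: np.ndarray, grid: SpotGrid, layout: GridLayout) -> pd.DataFrame:
    """Per-spot foreground/background/signal table.

    Foreground is the mean intensity in the disk of ``spot_radius``
    around the fitted center; background the median in the annulus
    [1.5 r, 2.5 r]; signal their difference. Spots whose foreground disk
    leaves the canvas are flagged ``clipped``; non-positive signals
    ``low``.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    r = layout.spot_radius
    records = []
    for i in range(layout.rows):
        for j in range(layout.cols):
            cx, cy = grid.spot_centers[i, j]
            clipped = (cx - r < 0) or (cx + r > w - 1) or (cy - r < 0) or (cy + r > h - 1)
            y0, y1 = max(0, int(cy - 2.5 * r) - 1), min(h, int(cy + 2.5 * r) + 2)
            x0, x1 = max(0, int(cx - 2.5 * r) - 1), min(w, int(cx + 2.5 * r) + 2)
            if y0 >= y1 or x0 >= x1:
                records.append((i, j, cx, cy, float("nan"), float("nan"), float("nan"), FLAG_CLIPPED))
                continue
            ys = np.arange(y0, y1) - cy
            xs = np.arange(x0, x1) - cx
            d2 = ys[:, None] ** 2 + xs[None, :] ** 2
            patch = img[y0:y1, x0:x1]
            fg_mask = d2 <= r**2
            bg_mask = ((1.5 * r) ** 2 <= d2) & (d2 <= (2.5 * r) ** 2)
            fg = float(patch[fg_mask].mean()) if fg_mask.any() else float("nan")
            bg = float(np.median(patch[bg_mask])) if bg_mask.any() else float("nan")
            signal = fg - bg
            if clipped:
                flag = FLAG_CLIPPED
            elif not signal > 0:
                flag = FLAG_LOW
            else:
                flag = FLAG_OK
            records.append((i, j, float(cx), float(cy), fg, bg, signal, flag))
    return pd.DataFrame(
        records, columns=["row", "col", "x", "y", "foreground", "background", "signal", "flag"]
    )
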