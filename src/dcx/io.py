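"""Readers and writers for the toolkit's plain-text formats.

Canonical tabular dialect is TSV (UTF-8, '.' decimal); gene sets are
GMT; networks are TSV edge lists or SIF; grids and manifests are JSON.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dcx.dataset import ExpressionDataset
from dcx.gridding import GridLayout, SpotGrid


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_tsv(matrix_path, annotation_path=None) -> ExpressionDataset:
    """Read a genes x samples TSV (first column gene ids, header sample ids).

    Duplicate gene ids and missing/non-numeric cells are rejected with
    coordinates. An optional annotation TSV (indexed by sample, with a
    ``condition`` column) attaches sample metadata; otherwise a minimal
    annotation with condition ``NA`` is created.
    """
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate gene ids: {dupes[:5]}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {matrix_path}: {exc}") from exc
    if np.isnan(values).any():
        gi, si = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"missing value at gene {df.index[gi]!r}, sample {df.columns[si]!r}"
        )
    if annotation_path is not None:
        samples = pd.read_csv(annotation_path, sep="\t", index_col=0)
        missing = [s for s in df.columns if s not in samples.index]
        if missing:
            raise ValueError(f"samples missing from annotation: {missing[:5]}")
        samples = samples.loc[df.columns]
    else:
        samples = pd.DataFrame({"condition": ["NA"] * df.shape[1]}, index=df.columns)
    return ExpressionDataset(values, list(df.index), samples, log2=False, stage="raw")


def write_expression_tsv(dataset: ExpressionDataset, matrix_path, annotation_path=None) -> None:
    df = pd.DataFrame(dataset.values, index=dataset.gene_ids, columns=dataset.sample_ids)
    df.index.name = "gene"
    df.to_csv(matrix_path, sep="\t")
    if annotation_path is not None:
        dataset.samples.to_csv(annotation_path, sep="\t")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set library: name <tab> description <tab> members...

    Duplicate members are deduplicated with a warning; a blank set name
    or a memberless set is an error. An empty file yields an empty
    library with a warning.
    """
    library: dict[str, set[str]] = {}
    lines = Path(path).read_text().splitlines()
    if not any(line.strip() for line in lines):
        warnings.warn(f"empty GMT file: {path}")
        return library
    for lineno, line in enumerate(lines, 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: need >= 3 tab-separated fields")
        name, _desc, *members = fields
        members = [m for m in members if m]
        if not name.strip():
            raise ValueError(f"{path}:{lineno}: blank set name")
        if not members:
            raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
        unique = set(members)
        if len(unique) < len(members):
            warnings.warn(f"{path}:{lineno}: duplicated members in set {name!r}")
        if name in library:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        library[name] = unique
    return library


def write_gmt(library: dict[str, set[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, members in library.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

def read_edge_list(path) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Read a TSV edge list (source, target[, interaction, source_type,
    target_type]) or a SIF file (source, interaction, targets...).

    Returns (edges, node_types).
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    types: dict[str, str] = {}
    if path.suffix.lower() == ".sif":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"malformed SIF line: {line!r}")
            src, _interaction, *targets = parts
            edges.extend((src, t) for t in targets)
        return edges, types
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "source" not in cols or "target" not in cols:
        # headerless two-column fallback
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        if df.shape[1] < 2:
            raise ValueError(f"edge list {path} needs >= 2 columns")
        df.columns = ["source", "target"] + [f"c{i}" for i in range(df.shape[1] - 2)]
    for _, row in df.iterrows():
        edges.append((row["source"], row["target"]))
        if "source_type" in df.columns and pd.notna(row.get("source_type")):
            types[row["source"]] = row["source_type"]
        if "target_type" in df.columns and pd.notna(row.get("target_type")):
            types[row["target"]] = row["target_type"]
    return edges, types


def write_edge_list(edges, path) -> None:
    pd.DataFrame(edges, columns=["source", "target"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# grids, layouts, configs
# ---------------------------------------------------------------------------

def write_grid_json(grid: SpotGrid, path) -> None:
    payload = {
        "affine": grid.affine.tolist(),
        "residual_rms": grid.residual_rms,
        "matched_anchors": [
            {"anchor": list(a), "marker": list(m)} for a, m in grid.matched_anchors
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_grid_json(path, layout: GridLayout) -> SpotGrid:
    payload = json.loads(Path(path).read_text())
    affine = np.asarray(payload["affine"], dtype=float)
    nominal = layout.nominal_positions()
    centers = (nominal @ affine[:, :2].T + affine[:, 2]).reshape(layout.rows, layout.cols, 2)
    return SpotGrid(
        affine=affine,
        spot_centers=centers,
        residual_rms=float(payload["residual_rms"]),
        matched_anchors=[
            (tuple(e["anchor"]), tuple(e["marker"])) for e in payload.get("matched_anchors", [])
        ],
    )


def read_layout_yaml(path) -> GridLayout:
    data = yaml.safe_load(Path(path).read_text())
    if "marker_anchors" in data and data["marker_anchors"] is not None:
        data["marker_anchors"] = tuple(tuple(a) for a in data["marker_anchors"])
    return GridLayout(**data)


def write_layout_yaml(layout: GridLayout, path) -> None:
    data = {
        "rows": layout.rows,
        "cols": layout.cols,
        "pitch": layout.pitch,
        "spot_radius": layout.spot_radius,
        "marker_radius": layout.marker_radius,
        "marker_anchors": [list(a) for a in layout.marker_anchors],
        "margin": layout.margin,
    }
    Path(path).write_text(yaml.safe_dump(data))


def read_marker_overrides(path) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """User-supplied marker positions: anchor_row, anchor_col, x, y TSV."""
    df = pd.read_csv(path, sep="\t")
    required = {"anchor_row", "anchor_col", "x", "y"}
    if not required <= set(df.columns):
        raise ValueError(f"marker override file needs columns {sorted(required)}")
    return [
        ((float(r.anchor_row), float(r.anchor_col)), (float(r.x), float(r.y)))
        for r in df.itertuples()
    ]


def read_image(path) -> np.ndarray:
    """Read a single-channel TIFF or PNG scan."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim == 3:
        if img.shape[2] == 1:
            img = img[:, :, 0]
        else:
            raise ValueError(f"{path}: expected a single-channel image")
    return img


def write_image(image: np.ndarray, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, image)


def read_literature_counts(path) -> pd.Series:
    """Node -> literature count table (TSV with columns node, count)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("literature table needs columns: node, count")
    return pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0].astype(str))
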