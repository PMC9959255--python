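"""End-to-end orchestration: synthetic or file input through every stage.

The pipeline runs simulate (or load) -> preprocess -> differential
expression -> differential co-expression -> network analysis ->
clinical statistics, writes every stage's table under ``out_dir`` and
records a JSON manifest with per-stage checksums so reruns can be
verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dcx import __version__, io
from dcx.coexpress import CoexParams, differential_coexpression
from dcx.diffexpr import fit_gene_ancova
from dcx.clinical import clinical_summary_table
from dcx.network import betweenness, build_graph, topological_attack
from dcx.preprocess import PreprocConfig, preprocess_dataset
from dcx.simulate import (
    ModuleSpec,
    SimConfig,
    generate_clinical_table,
    generate_expression_dataset,
    to_intensity_scale,
)

log = logging.getLogger("dcx")


@dataclass
class PipelineConfig:
    out_dir: str = "dcx-output"
    seed: int = 0
    # synthetic input (used when expression_path is None)
    n_genes: int = 1000
    n_per_group: int = 20
    de_fraction: float = 0.05
    de_log2fc: float = 1.0
    gene_sd: float = 0.7
    modules: list[dict] = field(default_factory=lambda: [
        {"size": 30, "rho_EA": 0.7, "rho_NEA": 0.0},
    ])
    # file input
    expression_path: str | None = None
    annotation_path: str | None = None
    edge_list_path: str | None = None
    # stage parameters
    preprocess: dict = field(default_factory=dict)
    covariates: list[str] = field(default_factory=lambda: ["age", "sex", "bmi", "ocs"])
    coexpress: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _float_fmt(df: pd.DataFrame) -> pd.DataFrame:
    return df


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest (also written to disk).

    Reruns with an identical config produce byte-identical output
    tables.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: v for k, v in vars(config).items()},
        "stages": [],
    }

    def record(stage: str, outputs: list[Path], **info) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "outputs": {p.name: _sha256(p) for p in outputs},
                **info,
            }
        )
        log.info("[%s] done: %s", stage, ", ".join(p.name for p in outputs))

    # ---- stage 1: input -------------------------------------------------
    if config.expression_path is None:
        sim = SimConfig(
            n_genes=config.n_genes,
            n_per_group=config.n_per_group,
            de_fraction=config.de_fraction,
            de_log2fc=config.de_log2fc,
            gene_sd=config.gene_sd,
            modules=tuple(ModuleSpec(**m) for m in config.modules),
            seed=config.seed,
        )
        dataset_log2, truth = generate_expression_dataset(sim)
        raw = to_intensity_scale(dataset_log2)
        truth_path = out / "ground_truth.json"
        truth_path.write_text(
            json.dumps(
                {
                    "de_genes": truth.de_genes,
                    "module_membership": truth.module_membership,
                },
                indent=2,
                sort_keys=True,
            )
        )
        matrix_path = out / "expression_raw.tsv"
        annot_path = out / "samples.tsv"
        io.write_expression_tsv(raw, matrix_path, annot_path)
        record("simulate", [matrix_path, annot_path, truth_path],
               n_genes=raw.n_genes, n_samples=raw.n_samples)
    else:
        raw = io.read_expression_tsv(config.expression_path, config.annotation_path)
        matrix_path = Path(config.expression_path)
        record("load", [], n_genes=raw.n_genes, n_samples=raw.n_samples)

    # ---- stage 2: preprocess -------------------------------------------
    pconf = PreprocConfig(**config.preprocess)
    processed, report = preprocess_dataset(raw, pconf)
    proc_path = out / "expression_processed.tsv"
    report_path = out / "cv_filter_report.tsv"
    io.write_expression_tsv(processed, proc_path)
    report.to_csv(report_path, sep="\t", index=False)
    record("preprocess", [proc_path, report_path],
           n_genes_kept=processed.n_genes)

    # ---- stage 3: differential expression ------------------------------
    covariates = [c for c in config.covariates if c in processed.samples.columns]
    de = fit_gene_ancova(processed, covariates)
    de_path = out / "differential_expression.tsv"
    de.to_csv(de_path, sep="\t", index=False)
    record("diffexpr", [de_path], covariates=covariates,
           n_significant=int((de["p_adj"] < 0.05).sum()))

    # ---- stage 4: differential co-expression ---------------------------
    cparams = CoexParams(seed=config.seed, **config.coexpress)
    groups = differential_coexpression(processed, cparams)
    rows = []
    for gid, g in enumerate(groups, 1):
        for gene in g.genes:
            rows.append((gid, gene, g.t_EA, g.t_NEA, g.p_EA, g.p_NEA, g.mean_dr, g.is_dcg))
    coex = pd.DataFrame(
        rows,
        columns=["group_id", "gene", "t_EA", "t_NEA", "p_EA", "p_NEA", "mean_dr", "is_dcg"],
    )
    coex_path = out / "coexpression_groups.tsv"
    coex.to_csv(coex_path, sep="\t", index=False)
    record("coexpress", [coex_path], n_groups=len(groups),
           n_dcg=sum(g.is_dcg for g in groups))

    # ---- stage 5: network ----------------------------------------------
    if config.edge_list_path is not None:
        edges, types = io.read_edge_list(config.edge_list_path)
        graph = build_graph(edges, types)
    else:
        # default demo graph: connect genes within each co-expression group
        edges = []
        for g in groups:
            hub = g.genes[0]
            edges.extend((hub, other) for other in g.genes[1:])
        if not edges:
            edges = [("g0", "g1")]
        graph = build_graph(edges)
    bc = betweenness(graph)
    bc_path = out / "betweenness.tsv"
    bc.rename_axis("node").to_frame().to_csv(bc_path, sep="\t")
    curve = topological_attack(graph, strategy="betweenness", recompute=True)
    curve_path = out / "attack_curve.tsv"
    curve.as_frame().to_csv(curve_path, sep="\t", index=False)
    record("network", [bc_path, curve_path],
           n_nodes=graph.number_of_nodes(), n_edges=graph.number_of_edges())

    # ---- stage 6: clinical statistics ----------------------------------
    clin = generate_clinical_table(config.n_per_group, config.seed)
    clin_path = out / "clinical_table.tsv"
    clin.to_csv(clin_path, sep="\t")
    summary = clinical_summary_table(clin)
    summary_path = out / "clinical_summary.tsv"
    summary.to_csv(summary_path, sep="\t", index=False)
    record("clinical_stats", [clin_path, summary_path])

    manifest["wall_clock_s"] = round(time.time() - t0, 3)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO if verbose else logging.WARNING)
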