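"""End-to-end pipeline: filter -> confounder screen -> case/control DE ->
randomisation null -> co-expression -> biological age, driven by one YAML
config with a master seed, writing per-stage TSVs and a JSON run manifest
with content digests."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bioage import run_bioage
from .coexpression import (
    batch_regress,
    cluster_group_test,
    cut_clusters,
    filter_coexpression_genes,
    metagenes,
    tom_matrix,
)
from .confounds import screen_covariates
from .datamodel import CountMatrix, SampleMetadata, ValidationError
from .de import ContrastSpec, filter_genes_for_de, normalized_counts, run_de, significant_genes
from .io import read_annotation, read_counts, read_metadata, write_table
from .randomization import fp_expectation, recurrent_fp_genes
from .simulate import SimulationConfig, simulate_dataset, truth_report

log = logging.getLogger("txage")


@dataclass
class PipelineConfig:
    counts: str | None = None
    metadata: str | None = None
    annotation: str | None = None
    covariate_spec: dict[str, str] = field(default_factory=dict)
    simulate: dict | None = None          # SimulationConfig fields instead of paths
    out_dir: str = "txage_out"
    seed: int | None = None
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "confounds": True,
            "group_de": True,
            "randomization": True,
            "coexpression": True,
            "biological_age": True,
        }
    )
    alpha: float = 0.01
    flag_threshold: int = 5
    panel: list[str] | None = None
    n_random_iterations: int = 50
    random_thresholds: tuple = (0.01, 0.05, 0.1, 0.25)
    cut_height: float = 0.95
    min_cluster_size: int = 50
    p_grid: tuple = (0.01, 0.05, 0.1)
    lfc_grid: tuple = (0.0, 0.3, 0.6, 1.0)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for key in ("counts", "metadata", "annotation"):
            value = getattr(cfg, key)
            if value is not None and not Path(value).exists():
                raise ValidationError(f"{key} path does not exist: {value}")
        if cfg.simulate is None and cfg.counts is None:
            raise ValidationError("config needs either input paths or a simulate block")
        stochastic = cfg.simulate is not None or cfg.stages.get("randomization", True)
        if stochastic and cfg.seed is None:
            raise ValidationError("seed required when a stochastic stage is enabled")
        return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "txage_version": __version__,
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }

    # --- inputs -----------------------------------------------------------
    if config.simulate is not None:
        sim = SimulationConfig(**{**config.simulate, "seed": config.seed})
        counts, metadata, annotation, truth = simulate_dataset(sim)
        truth_report(truth, out / "truth.tsv")
        manifest["stages"]["simulate"] = {"n_genes": sim.n_genes,
                                          "n_samples": sim.n_samples}
    else:
        counts = read_counts(config.counts)
        metadata = read_metadata(config.metadata, config.covariate_spec)
        annotation = read_annotation(config.annotation)
    metadata = metadata.aligned_to(counts)
    log.info("inputs: %d genes x %d samples", counts.n_genes, counts.n_samples)

    filtered = filter_genes_for_de(counts, annotation)
    log.info("expression filter kept %d genes", filtered.n_genes)
    manifest["stages"]["filter"] = {"n_genes": filtered.n_genes}

    adjustment: list[str] = []
    if config.stages.get("confounds", True):
        panel = config.panel or list(metadata.covariate_kinds)
        report = screen_covariates(
            filtered, metadata, panel,
            alpha=config.alpha, flag_threshold=config.flag_threshold,
        )
        write_table(report.table, out / "confounders.tsv", index_label="covariate")
        adjustment = [c for c in report.flagged]
        log.info("confound screen: %d/%d flagged", len(adjustment), len(panel))
        manifest["stages"]["confounds"] = {
            "panel_size": len(panel),
            "flagged": adjustment,
            "skipped": report.skipped,
        }

    if config.stages.get("group_de", True):
        md = metadata.table.copy()
        md["is_mdd"] = np.where(md["group"] == "HC", "a_HC", "b_MDD")
        md_meta = SampleMetadata(
            md, {**metadata.covariate_kinds, "is_mdd": "binary"}
        )
        adj = [c for c in adjustment if c != "batch"]
        if "batch" in metadata.covariate_kinds:
            adj = adj + ["batch"]
        result = run_de(
            filtered, md_meta,
            ContrastSpec("is_mdd", mode="binary", adjustment_covariates=adj,
                         alpha=config.alpha),
        )
        write_table(result, out / "de_hc_vs_mdd.tsv", index_label="gene_id")
        sig = significant_genes(result, config.alpha)
        log.info("HC vs MDD: %d significant genes at p_adj < %g", len(sig), config.alpha)
        manifest["stages"]["group_de"] = {
            "n_significant": len(sig),
            "significant_genes": sig[:50],
            "adjustment": adj,
        }

    if config.stages.get("randomization", True):
        n_case = int((metadata.table["group"] == "HC").sum()) or 44
        summary = fp_expectation(
            filtered, n_case=n_case,
            n_iter=config.n_random_iterations,
            thresholds=config.random_thresholds,
            seed=config.seed,
        )
        write_table(summary.counts, out / "random_null_counts.tsv",
                    index_label="iteration")
        write_table(summary.gene_mean_p.to_frame(), out / "gene_mean_p.tsv",
                    index_label="gene_id")
        recurrent = recurrent_fp_genes(
            summary, k=min(50, filtered.n_genes)
        )
        (out / "recurrent_fp_genes.txt").write_text("\n".join(recurrent) + "\n")
        manifest["stages"]["randomization"] = {
            "n_iterations": summary.n_iterations,
            "median_counts": summary.median_counts.to_dict(),
            "max_counts": summary.max_counts.to_dict(),
        }
        log.info("randomisation null: median counts %s",
                 summary.median_counts.to_dict())

    if config.stages.get("coexpression", True):
        expr = normalized_counts(filtered)
        if "batch" in metadata.covariate_kinds:
            expr = batch_regress(expr, metadata.table["batch"])
        try:
            genes = filter_coexpression_genes(expr)
        except ValidationError as err:
            log.warning("co-expression skipped: %s", err)
            manifest["stages"]["coexpression"] = {"skipped": str(err)}
            genes = None
        if genes is not None:
            tom = tom_matrix(expr, genes)
            clusters = cut_clusters(tom, config.cut_height, config.min_cluster_size)
            if len(clusters):
                mg = metagenes(expr.loc[genes], clusters)
                tests = cluster_group_test(mg, metadata)
                write_table(clusters.membership().to_frame(), out / "clusters.tsv",
                            index_label="gene_id")
                write_table(mg, out / "metagenes.tsv", index_label="cluster")
                write_table(tests, out / "cluster_tests.tsv", index_label="cluster")
                manifest["stages"]["coexpression"] = {
                    "n_genes": len(genes),
                    "n_clusters": len(clusters),
                    "min_p_adj": float(tests["p_adj"].min()),
                }
            else:
                manifest["stages"]["coexpression"] = {
                    "n_genes": len(genes), "n_clusters": 0,
                }
            log.info("co-expression: %s", manifest["stages"]["coexpression"])

    if config.stages.get("biological_age", True):
        metadata.require_age()
        signature, result, grid = run_bioage(
            filtered, metadata, p_grid=config.p_grid, lfc_grid=config.lfc_grid
        )
        write_table(signature.genes.to_frame("sign"), out / "signature.tsv",
                    index_label="gene_id")
        write_table(result.samples, out / "bioage_scores.tsv",
                    index_label="sample_id")
        write_table(grid, out / "signature_grid.tsv")
        contingency = {
            "table": {g: result.table.loc[g].to_dict() for g in result.table.index},
            "fisher_p": result.fisher_p,
            "slope": result.slope,
            "intercept": result.intercept,
            "spearman": result.spearman,
            "spearman_p": result.spearman_p,
            "n_signature_genes": signature.n_genes,
            "p_cutoff": signature.p_cutoff,
            "lfc_cutoff": signature.lfc_cutoff,
        }
        (out / "contingency.json").write_text(json.dumps(contingency, indent=2))
        manifest["stages"]["biological_age"] = contingency
        log.info("biological age: SCC=%.3f fisher_p=%.4g",
                 result.spearman, result.fisher_p)

    for artefact in sorted(out.iterdir()):
        if artefact.is_file() and artefact.name != "manifest.json":
            manifest["outputs"][artefact.name] = _digest(artefact)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
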