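"""End-to-end pipeline orchestration with a reproducible report bundle.

A single :class:`RunConfig` drives ingest -> annotation -> differential ->
network (-> enrichment) -> classification, writing every stage table plus a
manifest of seeds, thresholds and content hashes.  One master seed fans out
to per-stage sub-seeds by a stable derivation so stages are individually
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import classifier as clf
from . import differential as diff_mod
from . import ingest as ingest_mod
from . import lipids as lipids_mod
from . import network as net_mod
from . import synthetic as syn_mod
from .core import GroupDesign, QuantTable, TableError

logger = logging.getLogger("liprom")

_STAGE_OFFSETS = {
    "synthetic": 11,
    "qc": 12,
    "split": 13,
    "screen": 14,
    "search": 15,
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed derived from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big")


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    out_dir: str = "liprom_run"
    seed: int = 0
    # input files (ignored when synthetic is set)
    data: Optional[str] = None
    meta: Optional[str] = None
    design: Optional[str] = None
    qc: Optional[str] = None
    gmt: Optional[str] = None
    synthetic: Optional[syn_mod.SyntheticConfig] = None
    qc_replicates: int = 10
    # thresholds
    max_missing: float = 0.30
    max_cv: float = 0.30
    alpha: float = 0.05
    r_min: float = 0.5
    p_corr_max: float = 0.002
    p_diff_max: float = 0.05
    endpoint_rule: str = "either"
    # classifier settings
    run_classifier: bool = True
    cycles: int = 100
    pool_size: int = 20
    per_cycle_top: int = 20
    hidden_nodes: int = 5
    restarts: int = 2
    max_iter: int = 300
    selection_mode: str = "cv"
    max_predictors: Optional[int] = None
    cv_folds: int = 5
    n_trees: int = 50
    train_fraction: float = 0.70

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", None)
        config = cls(**raw)
        if syn is not None:
            effects = [
                syn_mod.Effect(
                    group=e["group"],
                    features=tuple(e["features"]),
                    factor=float(e["factor"]),
                )
                for e in syn.pop("effects", [])
            ]
            factors = [
                syn_mod.LatentFactor(
                    name=f["name"],
                    loading={k: float(v) for k, v in f["loading"].items()},
                    group_scale={
                        k: float(v) for k, v in f.get("group_scale", {}).items()
                    },
                    cv=float(f.get("cv", 0.15)),
                )
                for f in syn.pop("latent_factors", [])
            ]
            config.synthetic = syn_mod.SyntheticConfig(
                effects=effects, latent_factors=factors, **syn
            )
        return config


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "thresholds": {
            "max_missing": config.max_missing,
            "max_cv": config.max_cv,
            "alpha": config.alpha,
            "r_min": config.r_min,
            "p_corr_max": config.p_corr_max,
            "p_diff_max": config.p_diff_max,
            "endpoint_rule": config.endpoint_rule,
        },
        "stage_seeds": {
            s: stage_seed(config.seed, s) for s in _STAGE_OFFSETS
        },
        "inputs": {},
        "outputs": {},
    }

    def _write_df(df: pd.DataFrame, name: str, **kwargs) -> Path:
        path = out / name
        df.to_csv(path, sep="\t", **kwargs)
        manifest["outputs"][name] = _sha256(path)
        return path

    # -- stage: inputs ---------------------------------------------------
    try:
        if config.synthetic is not None:
            syn_config = config.synthetic
            syn_config.seed = stage_seed(config.seed, "synthetic")
            table, design, truth = syn_mod.generate_cohort(syn_config)
            qc_table = syn_mod.generate_qc_replicates(
                syn_config, config.qc_replicates
            )
            (out / "ground_truth.json").write_text(
                json.dumps(truth.to_jsonable(), indent=1)
            )
            manifest["outputs"]["ground_truth.json"] = _sha256(
                out / "ground_truth.json"
            )
            ingest_mod.write_quant_table(
                table, out / "cohort.csv", out / "cohort_meta.csv"
            )
            ingest_mod.write_design(design, out / "design.csv")
        else:
            for key in ("data", "meta", "design", "qc"):
                path = getattr(config, key)
                if path is None:
                    raise TableError(f"config lacks input path {key!r}")
                manifest["inputs"][key] = _sha256(Path(path))
            table = ingest_mod.read_quant_table(config.data, config.meta)
            design = ingest_mod.read_design(config.design)
            qc_table = ingest_mod.read_quant_table(config.qc, config.meta)
        design.check_table(table)
    except Exception as exc:
        raise TableError(f"[ingest] {exc}") from exc
    logger.info("ingest: %d samples x %d features", table.n_samples, table.n_features)

    # -- stage: QC filter + imputation -----------------------------------
    filtered, qc_summary = ingest_mod.ingest(
        table, qc_table, max_missing=config.max_missing, max_cv=config.max_cv
    )
    _write_df(qc_summary.table, "qc_summary.tsv")
    _write_df(
        ingest_mod.class_cv_summary(qc_table).to_frame("median_cv"),
        "class_cv_summary.tsv",
    )
    ingest_mod.write_quant_table(
        filtered, out / "filtered.csv", out / "filtered_meta.csv"
    )

    # -- stage: annotation ------------------------------------------------
    try:
        annotation = lipids_mod.annotate_features(filtered)
        _write_df(annotation, "lipid_annotation.tsv")
        totals = lipids_mod.class_totals(filtered)
        _write_df(totals, "class_totals.tsv", index_label="sample_id")
        abund = lipids_mod.subclass_abundance(filtered)
        _write_df(abund, "subclass_abundance.tsv", index_label="sample_id")
        abund_summary = lipids_mod.abundance_group_summary(abund, design)
        _write_df(abund_summary, "abundance_group_summary.tsv", index=False)
    except Exception as exc:
        raise TableError(f"[annotate] {exc}") from exc

    # -- stage: differential ----------------------------------------------
    try:
        diff = diff_mod.differential_analysis(filtered, design, alpha=config.alpha)
        _write_df(diff.table, "differential.tsv", index=False)
        protein_cols = filtered.protein_features
        class_table = pd.concat(
            [totals, filtered.values[protein_cols]], axis=1
        )
        _write_df(
            diff_mod.class_comparison(class_table, design), "class_comparison.tsv"
        )
        for direction in ("up", "down"):
            cells = diff_mod.venn_sets(diff, direction)
            _write_df(
                diff_mod.venn_counts(cells), f"venn_{direction}.tsv", index=False
            )
        z = diff_mod.group_mean_zscores(totals, design)
        row_order, col_order, _, _ = diff_mod.hierarchical_cluster(z)
        _write_df(z.loc[row_order, col_order], "class_zscores.tsv")
    except Exception as exc:
        raise TableError(f"[differential] {exc}") from exc

    # -- stage: networks (+ optional enrichment) --------------------------
    try:
        hub_frames = []
        for group in design.non_reference_groups:
            edges = net_mod.pairwise_correlations(filtered, design, group)
            net = net_mod.dual_filter(
                edges, diff, filtered,
                r_min=config.r_min, p_corr_max=config.p_corr_max,
                p_diff_max=config.p_diff_max,
                endpoint_rule=config.endpoint_rule,
            )
            net_mod.export_network(net, out / f"network_{group}.sif", "sif")
            net_mod.export_network(
                net, out / f"network_{group}.graphml", "graphml"
            )
            net_mod.export_network(net, out / f"network_{group}.tsv", "tsv")
            for name in (f"network_{group}.sif", f"network_{group}.tsv"):
                manifest["outputs"][name] = _sha256(out / name)
            hubs = net_mod.hub_table(net)
            if len(hubs):
                hub_frames.append(hubs.assign(group=group))
            if config.gmt and len(hubs):
                sets = net_mod.read_gmt(config.gmt)
                ora = net_mod.ora_enrichment(
                    set(hubs.index), sets, set(filtered.protein_features)
                )
                _write_df(ora, f"enrichment_{group}.tsv")
        if hub_frames:
            _write_df(pd.concat(hub_frames), "hub_proteins.tsv")
    except Exception as exc:
        raise TableError(f"[network] {exc}") from exc

    # -- stage: classifier -------------------------------------------------
    if config.run_classifier:
        try:
            report = clf.run_classification_stage(
                filtered, design,
                split=clf.SplitSpec(
                    train_fraction=config.train_fraction,
                    seed=stage_seed(config.seed, "split"),
                ),
                cycles=config.cycles, per_cycle_top=config.per_cycle_top,
                pool_size=config.pool_size,
                selection_mode=config.selection_mode,
                max_size=config.max_predictors,
                hidden_nodes=config.hidden_nodes, restarts=config.restarts,
                max_iter=config.max_iter, cv_folds=config.cv_folds,
                n_trees=config.n_trees,
                seed=stage_seed(config.seed, "screen"),
            )
            _write_df(report.screening.table, "screening.tsv")
            (out / "search_trace.json").write_text(
                json.dumps(
                    {
                        "pool": report.trace.pool,
                        "runs": report.trace.runs,
                        "best_predictors": report.trace.best_predictors,
                        "best_accuracy": report.trace.best_accuracy,
                        "selection_mode": report.trace.selection_mode,
                    },
                    indent=1,
                )
            )
            manifest["outputs"]["search_trace.json"] = _sha256(
                out / "search_trace.json"
            )
            _write_df(report.train_eval.confusion_matrix, "confusion_train.tsv")
            _write_df(report.test_eval.confusion_matrix, "confusion_test.tsv")
            _write_df(report.trace.accuracy_curve(), "accuracy_curve.tsv", index=False)
            manifest["classifier"] = {
                "best_predictors": report.trace.best_predictors,
                "train_accuracy": report.train_eval.overall_accuracy,
                "test_accuracy": report.test_eval.overall_accuracy,
                "train_macro_auc": report.train_eval.macro_auc,
                "test_macro_auc": report.test_eval.macro_auc,
            }
        except Exception as exc:
            raise TableError(f"[classifier] {exc}") from exc

    manifest["runtime_s"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
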