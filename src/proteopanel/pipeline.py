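"""End-to-end orchestration: simulate -> quantify -> preprocess -> PCA/enrichment -> classify.

Every stage serializes its output to the run directory so a run is
inspectable and restartable; a machine-readable report collects seeds, counts
and timing per stage. Each stochastic stage derives its seed from the global
seed plus a fixed stage offset, so a single seed reproduces the whole run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, enrichment, preprocess, quantify, simulate, unsupervised

logger = logging.getLogger("proteopanel")

STAGE_SEED_OFFSETS = {"simulate": 11, "annotations": 23, "impute": 37, "cv": 53}

STAGES = ("simulate", "quantify", "preprocess", "pca", "enrich", "classify")


@dataclass
class PipelineConfig:
    outdir: str = "proteopanel_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    sim: dict = field(default_factory=dict)
    quant: dict = field(default_factory=dict)
    filter: dict = field(default_factory=dict)
    impute: dict = field(default_factory=dict)
    cv: dict = field(default_factory=dict)
    stat: dict = field(default_factory=dict)
    n_categories: int = 20
    category_size: int = 25
    frac_differential_category: float = 0.8
    loading_quantile: float = 0.9
    feature_table: str | None = None  # external input instead of simulate
    labels_file: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def validate(self) -> None:
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        if "simulate" not in self.stages and self.feature_table is None:
            raise ValueError("need either the simulate stage or an input feature_table")
        for p in (self.feature_table, self.labels_file):
            if p is not None and not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")
        # stage dependency: normalization needs a complete matrix
        if "preprocess" in self.stages and self.impute.get("enabled", True) is False:
            raise ValueError("preprocess stage with imputation disabled would leave "
                             "missing values before normalization")


def validate_inputs(feature_table_path, labels_path=None, catalog_path=None) -> dict:
    """Schema validation of external inputs; returns {'errors': [...], 'warnings': [...]}."""
    errors, warnings = [], []
    try:
        table = simulate.read_feature_table(feature_table_path)
    except Exception as exc:  # header/dtype problems
        return {"errors": [str(exc)], "warnings": []}
    for col in ("intensity_l", "intensity_h"):
        bad = table.index[table[col].notna() & (table[col] <= 0)]
        for i in bad[:10]:
            errors.append(f"line {i + 2}: non-positive {col}")
    samples = set(table["sample_id"])
    if labels_path is not None:
        labels = simulate.read_labels(labels_path)
        unknown = set(labels.index) - samples
        if unknown:
            errors.append(f"label file names unknown samples: {sorted(unknown)[:5]}")
        unlabelled = samples - set(labels.index)
        if unlabelled:
            warnings.append(f"samples without labels: {sorted(unlabelled)[:5]}")
    if catalog_path is not None:
        catalog = enrichment.read_catalog(catalog_path)
        ids = set(table["protein_group_id"])
        overlap = sum(len(v & ids) for v in catalog.values())
        if overlap == 0:
            warnings.append("annotation catalog shares no protein IDs with the table")
    return {"errors": errors, "warnings": warnings}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in fixed order; returns the run report."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    logger.addHandler(fh)
    report: dict = {"seed": config.seed, "stages": {}}
    t0 = time.time()
    try:
        truth = None
        labels = None
        if "simulate" in config.stages:
            t = time.time()
            cfg = simulate.SimConfig(
                **{**config.sim, "seed": config.seed + STAGE_SEED_OFFSETS["simulate"]}
            )
            table, truth = simulate.generate_cohort(cfg)
            labels = truth.subtype_labels
            simulate.write_feature_table(table, out / "features.tsv")
            simulate.write_truth(truth, out / "truth")
            simulate.write_labels(labels, out / "labels.tsv")
            catalog = simulate.generate_annotations(
                truth,
                config.n_categories,
                config.category_size,
                config.frac_differential_category,
                seed=config.seed + STAGE_SEED_OFFSETS["annotations"],
            )
            enrichment.write_catalog(catalog, out / "catalog.tsv")
            report["stages"]["simulate"] = {
                "n_rows": len(table),
                "n_proteins": cfg.n_proteins,
                "n_samples": cfg.n_samples_A + cfg.n_samples_B,
                "seconds": round(time.time() - t, 3),
            }
            logger.info("simulate: %d feature rows", len(table))
        else:
            table = simulate.read_feature_table(config.feature_table)
            labels = simulate.read_labels(config.labels_file) if config.labels_file else None
            catalog = None

        matrix = None
        if "quantify" in config.stages:
            t = time.time()
            qcfg = quantify.QuantConfig(**config.quant)
            matrix, qreport = quantify.quantify_matrix(table, qcfg)
            matrix.to_csv(out / "protein_profiles.tsv", sep="\t")
            (out / "quant_report.json").write_text(json.dumps(qreport.to_dict(), indent=2))
            report["stages"]["quantify"] = {**qreport.to_dict(), "seconds": round(time.time() - t, 3)}
            logger.info("quantify: %d/%d quantified", qreport.n_quantified, qreport.n_protein_groups)

        norm = None
        if "preprocess" in config.stages:
            t = time.time()
            fp = preprocess.FilterParams(**config.filter)
            ip_kwargs = {k: v for k, v in config.impute.items() if k != "enabled"}
            ip = preprocess.ImputeParams(
                **{**ip_kwargs, "seed": config.seed + STAGE_SEED_OFFSETS["impute"]}
            )
            filtered, thr = preprocess.filter_valid_values(matrix, fp)
            prep_rep = preprocess.preprocess_report(matrix, filtered, thr)
            imputed = preprocess.impute(filtered, ip)
            norm = preprocess.width_normalize(imputed)
            norm.to_csv(out / "normalized.tsv", sep="\t")
            (out / "preprocess_report.json").write_text(json.dumps(prep_rep, indent=2))
            report["stages"]["preprocess"] = {
                "threshold": thr,
                "n_retained": int(filtered.shape[0]),
                "seconds": round(time.time() - t, 3),
            }

        pca_res = None
        if "pca" in config.stages:
            t = time.time()
            pca_res = unsupervised.pca(norm)
            pca_res.scores.to_csv(out / "pca_scores.tsv", sep="\t")
            pca_res.loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
            pd.Series(
                pca_res.explained_variance_fraction,
                index=pca_res.scores.columns,
                name="explained_variance_fraction",
            ).to_csv(out / "pca_variance.tsv", sep="\t")
            stage = {"n_components": int(pca_res.scores.shape[1]), "seconds": round(time.time() - t, 3)}
            if labels is not None:
                pair = unsupervised.select_component_pair(pca_res, labels)
                stage["selected_pair"] = list(pair)
            report["stages"]["pca"] = stage

        if "enrich" in config.stages and catalog:
            t = time.time()
            comp = report["stages"].get("pca", {}).get("selected_pair", ["PC1"])[0]
            enr, skipped = enrichment.component_driver_enrichment(
                pca_res, comp, catalog, config.loading_quantile
            )
            enr.to_csv(out / "component_enrichment.tsv", sep="\t", index=False)
            lab_classes = sorted(labels.unique())
            med_x = norm[labels.index[labels == lab_classes[0]]].median(axis=1)
            med_y = norm[labels.index[labels == lab_classes[1]]].median(axis=1)
            enr2d = enrichment.enrichment_2d(med_x, med_y, catalog)
            enr2d.to_csv(out / "enrichment_2d.tsv", sep="\t", index=False)
            report["stages"]["enrich"] = {
                "component": comp,
                "n_categories": len(enr),
                "n_skipped": skipped,
                "n_significant_2d": int(enr2d["significant"].sum()) if len(enr2d) else 0,
                "seconds": round(time.time() - t, 3),
            }

        if "classify" in config.stages:
            t = time.time()
            cvc = classify.CVConfig(
                **{**config.cv, "seed": config.seed + STAGE_SEED_OFFSETS["cv"]}
            )
            statp = classify.ModeratedStatParams(**config.stat)
            cv_report = classify.cv_feature_selection(norm, labels, cvc, statp)
            (out / "cv_report.json").write_text(json.dumps(cv_report.to_dict(), indent=2))
            cv_report.mean_error.rename_axis("k").rename("mean_error").to_csv(
                out / "error_curve.tsv", sep="\t"
            )
            pd.Series(cv_report.panel, name="protein_group_id").to_csv(
                out / "panel.tsv", sep="\t", index=False
            )
            ranked = classify.rank_features(norm, labels, statp)
            cutoff = classify.clustering_loss_cutoff(norm, labels, ranked)
            report["stages"]["classify"] = {
                "optimal_k": cv_report.optimal_k,
                "mean_error_at_optimal_k": float(cv_report.mean_error[cv_report.optimal_k]),
                "clustering_loss_cutoff": cutoff,
                "seconds": round(time.time() - t, 3),
            }
            logger.info("classify: optimal k=%d", cv_report.optimal_k)

        report["wall_clock_seconds"] = round(time.time() - t0, 3)
        report["status"] = "ok"
    except Exception as exc:
        report["status"] = "failed"
        report["error"] = str(exc)
        (out / "run_report.json").write_text(json.dumps(report, indent=2))
        raise
    finally:
        logger.removeHandler(fh)
        fh.close()
    (out / "run_report.json").write_text(json.dumps(report, indent=2))
    return report
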