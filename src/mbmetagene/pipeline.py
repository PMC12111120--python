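"""Staged workflow orchestration.

Each stage reads typed TSV/JSON artifacts from the previous stage's
directory under a common output root, writes its own outputs under a fixed
directory name, and records a JSON manifest (input hashes, configuration,
seeds, package version) so reruns are verifiably identical.

Stage layout under ``output_dir``::

    simulate/   beta.tsv annotation.tsv samples.tsv
    qc/         matrix.tsv filter_report.{json,tsv} samples.tsv
    extract/    W.tsv H.tsv consensus.json rank_scan.tsv probe_means.tsv
    project/    H_V.tsv coverage.json
    train/      model.joblib split.json evaluation_test.{json,tsv...}
    evaluate/   evaluation_validation.{json,tsv...}
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .matrix_io import (
    BetaMatrix,
    SampleSheet,
    read_annotation,
    read_beta_table,
    read_sample_sheet,
    write_beta_table,
    write_sample_sheet,
)
from .metagene_factorization import consensus_nmf, rank_scan
from .metagene_projection import align_probes, project
from .qc_preprocess import (
    QCConfig,
    filter_probes,
    filter_samples,
    knn_impute,
    mask_low_confidence,
    select_top_variance,
)
from .subgroup_classifier import (
    evaluate,
    minmax_scale,
    misclassification_report,
    roc_curve_ovr,
    stratified_split,
    tune_and_train,
)
from .synthetic_data import generate_cohort

log = logging.getLogger("mbmetagene")

CONFIG_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Workflow configuration; round-trips through YAML unchanged."""

    output_dir: str = "runs/default"
    beta_table: str | None = None
    dialect: str = "paired-columns"
    annotation: str | None = None
    sample_sheet: str | None = None
    validation_beta_table: str | None = None
    validation_sample_sheet: str | None = None
    qc: dict = field(
        default_factory=lambda: {
            "detection_p_threshold": 0.05,
            "max_missing_fraction": 0.5,
            "maf_threshold": 0.05,
            "n_top_variance": 10000,
            "knn_k": 10,
        }
    )
    factorization: dict = field(
        default_factory=lambda: {
            "rank": 6,
            "n_runs": 30,
            "objective": "kl",
            "max_iter": 2000,
            "tol": 1e-6,
            "seed": 0,
            "scan_ranks": [],
        }
    )
    projection: dict = field(
        default_factory=lambda: {"fill_policy": "train-mean", "coverage_floor": 0.95}
    )
    classifier: dict = field(
        default_factory=lambda: {
            "family": "svm_rbf",
            "n_candidates": 20,
            "cv_folds": 10,
            "train_fraction": 0.8,
            "seed": 0,
        }
    )
    simulate: dict = field(
        default_factory=lambda: {
            "n_probes": 2000,
            "n_samples": 350,
            "k": 6,
            "noise_sd": 0.02,
            "missing_rate": 0.02,
            "separation": 0.25,
            "warp": True,
            "seed": 0,
        }
    )
    schema_version: int = CONFIG_SCHEMA_VERSION

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def qc_config(self) -> QCConfig:
        return QCConfig(**self.qc)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(stage_dir: Path, stage: str, config: RunConfig, inputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
    }
    with open(stage_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _stage_dir(config: RunConfig, stage: str) -> Path:
    d = Path(config.output_dir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the '{produced_by}' stage first"
        )
    return path


def _timed(stage: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage=%s start", stage)
            return self

        def __exit__(self, *exc):
            log.info("stage=%s wall_time=%.2fs", stage, time.perf_counter() - self.t0)

    return _T()


def cmd_simulate(config: RunConfig) -> Path:
    """Generate a synthetic cohort and write it in the formats cmd_qc reads."""
    out = _stage_dir(config, "simulate")
    with _timed("simulate"):
        sim = config.simulate
        bm, sheet, truth = generate_cohort(
            n_probes=sim["n_probes"],
            n_samples=sim["n_samples"],
            k=sim["k"],
            noise_sd=sim["noise_sd"],
            missing_rate=sim["missing_rate"],
            separation=sim["separation"],
            warp=sim["warp"],
            seed=sim["seed"],
        )
        write_beta_table(bm, out / "beta.tsv", dialect="paired-columns")
        truth.planted_annotation.table.to_csv(out / "annotation.tsv", sep="\t", index=False)
        write_sample_sheet(sheet, out / "samples.tsv")
        log.info("stage=simulate probes=%d samples=%d", bm.n_probes, bm.n_samples)
    _write_manifest(out, "simulate", config, [])
    return out


def _resolve_inputs(config: RunConfig, validation: bool) -> tuple[Path, Path, Path]:
    sim_dir = Path(config.output_dir) / "simulate"
    beta = config.validation_beta_table if validation else config.beta_table
    sheet = config.validation_sample_sheet if validation else config.sample_sheet
    beta = Path(beta) if beta else sim_dir / "beta.tsv"
    sheet = Path(sheet) if sheet else sim_dir / "samples.tsv"
    ann = Path(config.annotation) if config.annotation else sim_dir / "annotation.tsv"
    return beta, ann, sheet


def cmd_qc(config: RunConfig, validation: bool = False) -> Path:
    """Masking, probe/sample filtering, imputation, top-variance selection."""
    stage = "qc_validation" if validation else "qc"
    out = _stage_dir(config, stage)
    beta_path, ann_path, sheet_path = _resolve_inputs(config, validation)
    _require(beta_path, "simulate (or set beta_table)")
    cfg = config.qc_config()
    with _timed(stage):
        bm = read_beta_table(beta_path, dialect=config.dialect)
        ann = read_annotation(ann_path)
        sheet = read_sample_sheet(sheet_path)
        n0p, n0s = bm.shape
        masked = mask_low_confidence(bm, cfg.detection_p_threshold)
        filtered, report = filter_probes(masked, ann, cfg)
        filtered, kept_sheet = filter_samples(filtered, sheet)
        imputed = knn_impute(filtered, cfg.knn_k)
        n_top = min(cfg.n_top_variance, imputed.n_probes)
        selected = select_top_variance(imputed, n_top)
        log.info(
            "stage=%s probes_in=%d probes_out=%d samples_in=%d samples_out=%d "
            "removed_unique=%d", stage, n0p, selected.n_probes, n0s,
            selected.n_samples, report.n_unique_removed,
        )
        write_beta_table(selected, out / "matrix.tsv", dialect="beta-only")
        report.to_json(out / "filter_report.json")
        report.to_tsv(out / "filter_report.tsv")
        write_sample_sheet(kept_sheet, out / "samples.tsv")
    _write_manifest(out, stage, config, [beta_path, ann_path, sheet_path])
    return out


def cmd_extract(config: RunConfig) -> Path:
    """Consensus NMF on the QC'd primary matrix; writes W, H, diagnostics."""
    out = _stage_dir(config, "extract")
    qc_matrix = _require(Path(config.output_dir) / "qc" / "matrix.tsv", "qc")
    fac = config.factorization
    with _timed("extract"):
        bm = read_beta_table(qc_matrix, dialect="beta-only")
        res = consensus_nmf(
            bm.beta,
            k=fac["rank"],
            n_runs=fac["n_runs"],
            base_seed=fac["seed"],
            objective=fac["objective"],
            max_iter=fac["max_iter"],
            tol=fac["tol"],
        )
        metagenes = [f"V{i + 1}" for i in range(fac["rank"])]
        pd.DataFrame(res.best.W, index=bm.probe_ids, columns=metagenes).to_csv(
            out / "W.tsv", sep="\t", index_label="probe_id"
        )
        pd.DataFrame(res.best.H, index=metagenes, columns=bm.sample_ids).to_csv(
            out / "H.tsv", sep="\t", index_label="metagene"
        )
        pd.DataFrame(
            {"probe_id": bm.probe_ids, "train_mean": bm.beta.mean(axis=1)}
        ).to_csv(out / "probe_means.tsv", sep="\t", index=False)
        with open(out / "consensus.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "rank": res.rank,
                    "n_runs": res.n_runs,
                    "cophenetic": res.cophenetic,
                    "best_seed": res.best.seed,
                    "best_final_objective": res.best.final_objective,
                    "best_converged": res.best.converged,
                },
                fh,
                indent=2,
            )
            fh.write("\n")
        if fac.get("scan_ranks"):
            scan = rank_scan(
                bm.beta, fac["scan_ranks"], n_runs=fac["n_runs"],
                base_seed=fac["seed"], objective=fac["objective"],
                max_iter=fac["max_iter"], tol=fac["tol"],
            )
            scan.to_csv(out / "rank_scan.tsv", sep="\t", index=False)
        log.info("stage=extract rank=%d cophenetic=%.4f", res.rank, res.cophenetic)
    _write_manifest(out, "extract", config, [qc_matrix])
    return out


def cmd_project(config: RunConfig) -> Path:
    """NNLS projection of the QC'd validation cohort onto the stored basis."""
    out = _stage_dir(config, "project")
    w_path = _require(Path(config.output_dir) / "extract" / "W.tsv", "extract")
    val_matrix = _require(
        Path(config.output_dir) / "qc_validation" / "matrix.tsv", "qc --validation"
    )
    with _timed("project"):
        Wdf = pd.read_csv(w_path, sep="\t", index_col="probe_id")
        means = pd.read_csv(
            Path(config.output_dir) / "extract" / "probe_means.tsv", sep="\t"
        ).set_index("probe_id")["train_mean"].to_dict()
        val = read_beta_table(val_matrix, dialect="beta-only")
        aligned, coverage = align_probes(
            val,
            Wdf.index.tolist(),
            fill_policy=config.projection["fill_policy"],
            train_means=means,
            coverage_floor=config.projection["coverage_floor"],
        )
        res = project(
            Wdf.to_numpy(), aligned, sample_ids=val.sample_ids,
            probe_coverage=coverage["coverage"],
        )
        pd.DataFrame(res.H_V, index=Wdf.columns, columns=val.sample_ids).to_csv(
            out / "H_V.tsv", sep="\t", index_label="metagene"
        )
        with open(out / "coverage.json", "w", encoding="utf-8") as fh:
            json.dump(coverage, fh, indent=2)
            fh.write("\n")
        log.info("stage=project samples=%d coverage=%.3f", len(val.sample_ids), coverage["coverage"])
    _write_manifest(out, "project", config, [w_path, val_matrix])
    return out


def _write_evaluation(out: Path, prefix: str, report, miscls: pd.DataFrame, roc_points: dict) -> None:
    with open(out / f"{prefix}.json", "w", encoding="utf-8") as fh:
        json.dump(report.summary(), fh, indent=2)
        fh.write("\n")
    pd.DataFrame(
        report.confusion, index=report.class_names, columns=report.class_names
    ).to_csv(out / f"{prefix}_confusion.tsv", sep="\t", index_label="true\\predicted")
    report.per_class.to_csv(out / f"{prefix}_per_class.tsv", sep="\t", index=False)
    report.probabilities.to_csv(out / f"{prefix}_probabilities.tsv", sep="\t", index=False)
    miscls.to_csv(out / f"{prefix}_misclassified.tsv", sep="\t", index=False)
    rows = []
    for cls, points in roc_points.items():
        for fpr, tpr in points:
            rows.append({"class": cls, "fpr": fpr, "tpr": tpr})
    pd.DataFrame(rows).to_csv(out / f"{prefix}_roc.tsv", sep="\t", index=False)


def _evaluate_with_artifacts(model, scaler, H_df, sheet, out, prefix):
    features = scaler.transform(H_df.to_numpy().T)
    labels = sheet.labels_for(list(H_df.columns))
    report = evaluate(model, features, labels)
    miscls = misclassification_report(
        labels, report.predictions, report.probabilities.to_numpy(), report.class_names
    )
    roc_points = {}
    for i, c in enumerate(report.class_names):
        if c in labels and any(l != c for l in labels):
            points, _ = roc_curve_ovr(labels, report.probabilities.to_numpy()[:, i], c)
            roc_points[c] = points
    _write_evaluation(out, prefix, report, miscls, roc_points)
    return report


def cmd_train(config: RunConfig) -> Path:
    """Split, scale, tune/train the classifier; evaluate on the held-out test set."""
    out = _stage_dir(config, "train")
    h_path = _require(Path(config.output_dir) / "extract" / "H.tsv", "extract")
    sheet_path = _require(Path(config.output_dir) / "qc" / "samples.tsv", "qc")
    cc = config.classifier
    with _timed("train"):
        H = pd.read_csv(h_path, sep="\t", index_col="metagene")
        sheet = read_sample_sheet(sheet_path)
        sample_ids = list(H.columns)
        labels = sheet.labels_for(sample_ids)
        X = H.to_numpy().T  # samples x metagenes
        split = stratified_split(labels, cc["train_fraction"], seed=cc["seed"])
        X_train, X_test = X[split.train_indices], X[split.test_indices]
        y_train = [labels[i] for i in split.train_indices]
        y_test = [labels[i] for i in split.test_indices]
        X_train_s, X_test_s, scaler = minmax_scale(X_train, X_test)
        model = tune_and_train(
            X_train_s, y_train, family=cc["family"],
            n_candidates=cc["n_candidates"], cv_folds=cc["cv_folds"], seed=cc["seed"],
        )
        joblib.dump({"model": model, "scaler": scaler}, out / "model.joblib")
        with open(out / "split.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "seed": split.seed,
                    "n_train": split.n_train,
                    "n_test": split.n_test,
                    "train_counts": split.train_counts,
                    "train_percentages": split.train_percentages(),
                },
                fh,
                indent=2,
            )
            fh.write("\n")
        with open(out / "selected_config.json", "w", encoding="utf-8") as fh:
            json.dump(
                {"family": model.family, "config": model.config,
                 "cv_balanced_accuracy": model.cv_score, "seed": model.seed},
                fh, indent=2,
            )
            fh.write("\n")
        if len(y_test):
            report = evaluate(model, X_test_s, y_test)
            miscls = misclassification_report(
                y_test, report.predictions,
                report.probabilities.to_numpy(), report.class_names,
            )
            roc_points = {}
            for i, c in enumerate(report.class_names):
                if c in y_test and any(l != c for l in y_test):
                    pts, _ = roc_curve_ovr(
                        y_test, report.probabilities.to_numpy()[:, i], c
                    )
                    roc_points[c] = pts
            _write_evaluation(out, "evaluation_test", report, miscls, roc_points)
            log.info(
                "stage=train family=%s balanced_accuracy=%.4f",
                cc["family"], report.balanced_accuracy_sens_spec,
            )
    _write_manifest(out, "train", config, [h_path, sheet_path])
    return out


def cmd_evaluate(config: RunConfig) -> Path:
    """Evaluate the trained model on the projected validation cohort."""
    out = _stage_dir(config, "evaluate")
    model_path = _require(Path(config.output_dir) / "train" / "model.joblib", "train")
    hv_path = _require(Path(config.output_dir) / "project" / "H_V.tsv", "project")
    sheet_path = _require(
        Path(config.output_dir) / "qc_validation" / "samples.tsv", "qc --validation"
    )
    with _timed("evaluate"):
        bundle = joblib.load(model_path)
        H_V = pd.read_csv(hv_path, sep="\t", index_col="metagene")
        sheet = read_sample_sheet(sheet_path)
        report = _evaluate_with_artifacts(
            bundle["model"], bundle["scaler"], H_V, sheet, out, "evaluation_validation"
        )
        log.info(
            "stage=evaluate balanced_accuracy=%.4f macro_auc=%s",
            report.balanced_accuracy_sens_spec, report.macro_auc,
        )
    _write_manifest(out, "evaluate", config, [model_path, hv_path, sheet_path])
    return out


def cmd_full(config: RunConfig) -> None:
    """qc -> extract -> train on the primary cohort; if a validation cohort is
    configured (or simulated), qc -> project -> evaluate on it."""
    cmd_qc(config, validation=False)
    cmd_extract(config)
    cmd_train(config)
    has_validation = config.validation_beta_table is not None or (
        Path(config.output_dir) / "simulate" / "beta.tsv"
    ).exists()
    if has_validation:
        cmd_qc(config, validation=True)
        cmd_project(config)
        cmd_evaluate(config)
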