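"""End-to-end experiment: generate -> split -> train all strategies -> evaluate -> report.

Reproducibility contract: every stage's rng is derived from
(experiment seed, replicate seed, stage tag, fold, strategy) via a
counter-based SeedSequence scheme, so adding or removing a strategy does not
perturb any other stage's randomness, and rerunning the same config
reproduces every artifact byte-for-byte (single-threaded numpy execution).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dxprog import __version__
from dxprog.cohorts import CohortBundle, build_cohorts
from dxprog.config import ExperimentConfig, StrategySpec, config_to_dict
from dxprog.exceptions import LeakageError
from dxprog.reports import MetricReport, build_tables, evaluate_predictions, save_confusion_figure
from dxprog.splits import SplitPlan, make_split_plan, save_split_plan
from dxprog.strategies import (
    ScanDataset,
    TrainedModel,
    dataset_from_bundle,
    fold_datasets,
    train_strategy_for_fold,
)

FLOAT_FMT = "%.10g"


def _tag(*parts) -> tuple[int, ...]:
    return tuple(zlib.crc32(str(p).encode()) for p in parts)


def stage_rng(experiment_seed: int, *parts) -> np.random.Generator:
    """Deterministic per-stage rng: independent of execution order."""
    return np.random.default_rng(np.random.SeedSequence((experiment_seed, *_tag(*parts))))


def stage_seed(experiment_seed: int, *parts) -> int:
    return int(stage_rng(experiment_seed, *parts).integers(0, 2**31 - 1))


@dataclass
class SeedResult:
    """All artifacts of one seed replicate."""

    seed: int
    bundle: CohortBundle
    plan: SplitPlan
    predictions: pd.DataFrame
    report: MetricReport
    tables: dict[str, pd.DataFrame]
    external_metrics: dict | None = None
    models: dict[tuple[int, str], TrainedModel] = field(default_factory=dict)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    seed_results: list[SeedResult]
    aggregate_tables: dict[str, pd.DataFrame]
    output_dir: Path
    provenance: dict


# ---------------------------------------------------------------------------
# Per-seed execution
# ---------------------------------------------------------------------------

def _predict_rows(model: TrainedModel, ds: ScanDataset, partition: str, key: str) -> list[dict]:
    if len(ds) == 0:
        return []
    diag_probs, prog_scores = model.model.predict(ds.images)
    rows = []
    for i, scan_id in enumerate(ds.scan_ids):
        row = {
            "scan_id": scan_id,
            "fold_index": model.fold_index,
            "strategy": key,
            "partition": partition,
            "prognosis_score": float(prog_scores[i]),
        }
        for c in range(diag_probs.shape[1]):
            row[f"grade_prob_{c}"] = float(diag_probs[i, c])
        rows.append(row)
    return rows


def _audit_models(
    models: dict[tuple[int, str], TrainedModel],
    plan: SplitPlan,
    ds: ScanDataset,
) -> None:
    """Leakage + regime-definition audit over every recorded data access."""
    scan_to_patient = dict(zip(ds.scan_ids, ds.patient_ids))
    prog_scan_ids = set(ds.scan_ids[~np.isnan(ds.prog_labels)])
    for (fold_index, key), model in models.items():
        fold = plan.folds[fold_index]
        touched = {scan_to_patient[s] for s in model.audit.train_scan_ids | model.audit.val_scan_ids}
        if touched & (fold.test_patients | fold.test_diagnosis_patients):
            raise LeakageError(f"{key} fold {fold_index}: test patients touched during training/validation")
        train_patients = {scan_to_patient[s] for s in model.audit.train_scan_ids}
        if key in ("single_cohort_mt", "diag_pretrained_mt"):
            allowed = {s for s in prog_scan_ids if scan_to_patient[s] in fold.train_patients}
            if not model.audit.train_scan_ids <= allowed:
                raise LeakageError(f"{key} fold {fold_index}: read scans outside the prognosis train cohort")
        if key.startswith("prognosis_single_task"):
            if not train_patients <= fold.train_patients:
                raise LeakageError(f"{key} fold {fold_index}: trained beyond the prognosis train patients")
        allowed_pool = (
            fold.pretrain_diagnosis_patients - fold.val_patients - fold.val_diagnosis_patients
        ) | fold.train_patients
        if not train_patients <= allowed_pool:
            raise LeakageError(f"{key} fold {fold_index}: trained outside the allowed pool")


def run_seed(config: ExperimentConfig, seed: int, out_dir: Path, keep_models: bool = False) -> SeedResult:
    """One complete replicate: cohort, split plan, all strategies on all folds."""
    out_dir.mkdir(parents=True, exist_ok=True)
    gen_cfg = dataclasses.replace(config.generator, seed=stage_seed(seed, "generate"))
    bundle = build_cohorts(gen_cfg, out_dir / "cohort")
    ds = dataset_from_bundle(bundle)
    plan = make_split_plan(bundle, k=config.n_folds, seed=stage_seed(seed, "split", config.split_seed))
    save_split_plan(plan, out_dir / "split_plan.csv")

    needs_reference = any(
        s.name == "diagnosis_reference" or s.needs_pretrained for s in config.strategies
    )
    rows: list[dict] = []
    models: dict[tuple[int, str], TrainedModel] = {}
    logs: dict[str, list] = {}
    for fold in plan.folds:
        data = fold_datasets(ds, fold)
        reference = None
        if needs_reference:
            reference = train_strategy_for_fold(
                StrategySpec("diagnosis_reference"),
                data,
                config.backbone,
                config.train,
                stage_rng(seed, "train", fold.fold_index, "diagnosis_reference"),
                None,
                fold.fold_index,
            )
        for spec in config.strategies:
            if spec.name == "diagnosis_reference":
                model = reference
            else:
                model = train_strategy_for_fold(
                    spec,
                    data,
                    config.backbone,
                    config.train,
                    stage_rng(seed, "train", fold.fold_index, spec.key),
                    reference,
                    fold.fold_index,
                )
            models[(fold.fold_index, spec.key)] = model
            logs.setdefault(spec.key, []).append(
                {"fold_index": fold.fold_index, "selected_epoch": model.selected_epoch, "log": model.training_log}
            )
            rows.extend(_predict_rows(model, data["diag_test"], "test", spec.key))
            rows.extend(_predict_rows(model, data["diag_val"], "validation", spec.key))

    _audit_models(models, plan, ds)

    preds = pd.DataFrame(rows).sort_values(["strategy", "fold_index", "partition", "scan_id"], kind="stable")
    preds.to_csv(out_dir / "predictions.csv", index=False, float_format=FLOAT_FMT)
    with open(out_dir / "training_logs.json", "w") as fh:
        json.dump(logs, fh, indent=1, sort_keys=True, default=float)

    # evaluate strictly from the stored artifact so reports are regenerable
    preds_loaded = pd.read_csv(out_dir / "predictions.csv")
    report = evaluate_predictions(
        preds_loaded, bundle.diagnosis_scans, bundle.patients, config.generator.n_grades
    )
    tables = build_tables(report)
    for name, frame in tables.items():
        frame.to_csv(out_dir / f"{name}.csv", index=False, float_format=FLOAT_FMT)
    for key, cm in report.confusions.items():
        pd.DataFrame(cm).to_csv(out_dir / f"confusion_{key}.csv", index=False, header=False)
    if report.confusions:
        save_confusion_figure(report.confusions, out_dir / "confusion_matrices.png")

    external_metrics = _external_evaluation(config, seed, models, out_dir)
    result = SeedResult(seed, bundle, plan, preds_loaded, report, tables, external_metrics)
    if keep_models:
        result.models = models
    return result


def _external_evaluation(
    config: ExperimentConfig,
    seed: int,
    models: dict[tuple[int, str], TrainedModel],
    out_dir: Path,
) -> dict | None:
    """Transfer-style check: a shifted-generator cohort scored by all fold
    models of each prognosis strategy, probabilities averaged."""
    gen = config.external_generator(stage_seed(seed, "external"))
    if gen is None:
        return None
    from dxprog.metrics import auprc, auroc, ensemble_scores

    bundle = build_cohorts(gen, out_dir / "external_cohort")
    ds = dataset_from_bundle(bundle)
    labeled = ds.subset(~np.isnan(ds.prog_labels))
    if len(labeled) == 0:
        return None
    keys = sorted({key for (_, key) in models if key != "diagnosis_reference"})
    out: dict = {}
    for key in keys:
        fold_scores = []
        for (fold_index, k2), model in sorted(models.items()):
            if k2 != key:
                continue
            _, scores = model.model.predict(labeled.images)
            fold_scores.append(dict(zip(labeled.scan_ids, scores)))
        pooled = ensemble_scores(fold_scores)
        s = np.array([pooled[sid] for sid in labeled.scan_ids])
        y = labeled.prog_labels.astype(int)
        if 0 < y.sum() < len(y):
            out[key] = {"auroc": auroc(s, y), "auprc": auprc(s, y), "n": int(len(y))}
    with open(out_dir / "external_metrics.json", "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True)
    return out


# ---------------------------------------------------------------------------
# Experiment-level aggregation
# ---------------------------------------------------------------------------

def _aggregate(seed_results: list[SeedResult]) -> dict[str, pd.DataFrame]:
    """Stack per-seed summary tables and add cross-seed means."""
    out: dict[str, pd.DataFrame] = {}
    for name in ("table1_init_comparison", "table2_prognosis_mt", "table3_diagnosis"):
        frames = []
        for res in seed_results:
            frame = res.tables[name].copy()
            if frame.empty:
                continue
            frame.insert(0, "seed", res.seed)
            frames.append(frame)
        if frames:
            stacked = pd.concat(frames, ignore_index=True)
            mean_cols = [c for c in stacked.columns if c.endswith("_mean")]
            agg = stacked.groupby("metric", sort=True)[mean_cols].mean().round(10).reset_index()
            agg.insert(0, "seed", "mean")
            out[name] = pd.concat([stacked, agg], ignore_index=True)
    delong_frames = [
        res.report.delong.assign(seed=res.seed) for res in seed_results if len(res.report.delong)
    ]
    if delong_frames:
        out["delong"] = pd.concat(delong_frames, ignore_index=True)
    return out


def config_hash(config: ExperimentConfig) -> str:
    blob = json.dumps(config_to_dict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_experiment(config: ExperimentConfig, keep_models: bool = False) -> ExperimentResult:
    """Run every seed replicate and write all artifacts under a
    config-hash-named directory (timestamp-free for reproducibility)."""
    config.validate()
    root = Path(config.output_dir) / config_hash(config)
    root.mkdir(parents=True, exist_ok=True)
    seed_results = []
    for seed in config.seeds:
        seed_results.append(run_seed(config, seed, root / f"seed{seed}", keep_models=keep_models))

    aggregate = _aggregate(seed_results)
    for name, frame in aggregate.items():
        frame.to_csv(root / f"aggregate_{name}.csv", index=False, float_format=FLOAT_FMT)
    provenance = {
        "config_hash": config_hash(config),
        "version": __version__,
        "seeds": list(config.seeds),
        "stage_seeds": {
            f"seed{seed}": {"generate": stage_seed(seed, "generate"), "split": stage_seed(seed, "split", config.split_seed)}
            for seed in config.seeds
        },
    }
    with open(root / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
    return ExperimentResult(config, seed_results, aggregate, root, provenance)
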