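"""Assembling per-fold predictions into the benchmark's report tables.

Everything here is a pure function of (predictions frame, cohort metadata,
ground truth, split plan), so reports can be regenerated bit-identically from
stored artifacts without retraining.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dxprog.exceptions import UndefinedMetricError
from dxprog.metrics import (
    auprc,
    auroc,
    balanced_accuracy,
    confusion_matrix,
    delong_test,
    macro_micro_auroc,
    per_class_recall,
    sens_spec_at_threshold,
    youden_threshold,
)
from dxprog.splits import assign_subgroup

PROGNOSIS_METRICS = ["auroc", "auprc", "sensitivity", "specificity"]
DIAGNOSIS_METRICS = ["balanced_accuracy", "macro_auroc", "micro_auroc"]

#: strategy pairs compared with the DeLong test on pooled out-of-fold scores
DELONG_PAIRS = [
    ("prognosis_single_task_pretrained", "prognosis_single_task_random"),
    ("seq_replay", "single_cohort_mt"),
    ("seq_replay", "concurrent_mt"),
    ("seq_replay", "diag_pretrained_mt"),
    ("seq_replay", "prognosis_single_task_pretrained"),
]


@dataclass
class MetricReport:
    """Per-fold and fold-ensembled metrics for both tasks, plus comparisons."""

    prognosis_folds: pd.DataFrame
    prognosis_summary: pd.DataFrame
    diagnosis_folds: pd.DataFrame
    diagnosis_summary: pd.DataFrame
    delong: pd.DataFrame
    subgroups: pd.DataFrame
    forgetting: pd.DataFrame
    confusions: dict[str, np.ndarray] = field(default_factory=dict)


def ensemble_predictions(prediction_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Average the probability columns of several prediction frames per scan.

    Covers the union of scans; scans present in only some frames are averaged
    over the frames that scored them.
    """
    if not prediction_sets:
        raise ValueError("no prediction sets to ensemble")
    stacked = pd.concat(prediction_sets, ignore_index=True)
    value_cols = ["prognosis_score"] + _grade_prob_columns(stacked)
    return stacked.groupby("scan_id", sort=True)[value_cols].mean().reset_index()


def _grade_prob_columns(preds: pd.DataFrame) -> list[str]:
    cols = sorted(
        (c for c in preds.columns if c.startswith("grade_prob_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    return cols


def _summary(folds: pd.DataFrame, metrics: list[str]) -> pd.DataFrame:
    """mean ± sd over folds (sample sd, ddof=1), long layout."""
    rows = []
    for strategy, grp in folds.groupby("strategy", sort=True):
        for metric in metrics:
            vals = grp[metric].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                continue
            rows.append(
                {
                    "strategy": strategy,
                    "metric": metric,
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                    "n_folds": len(vals),
                }
            )
    return pd.DataFrame(rows)


def evaluate_predictions(
    preds: pd.DataFrame,
    metadata: pd.DataFrame,
    ground_truth: pd.DataFrame,
    n_grades: int,
) -> MetricReport:
    """Compute the full metric suite from a predictions frame.

    ``preds`` columns: scan_id, fold_index, strategy, partition
    (validation/test), prognosis_score, grade_prob_0..grade_prob_{G-1}.
    """
    prob_cols = _grade_prob_columns(preds)
    preds = preds.merge(
        metadata[["scan_id", "patient_id", "grade", "progression_label"]], on="scan_id", how="left"
    )
    gt = ground_truth.set_index("patient_id")

    strategies = sorted(preds["strategy"].unique())
    test = preds[preds["partition"] == "test"]
    val = preds[preds["partition"] == "validation"]

    prog_rows, diag_rows, subgroup_rows = [], [], []
    confusions: dict[str, np.ndarray] = {}
    pooled_prog: dict[str, pd.DataFrame] = {}

    for strategy in strategies:
        t_all = test[test["strategy"] == strategy]
        v_all = val[val["strategy"] == strategy]
        trains_prognosis = strategy != "diagnosis_reference"
        t_prog = t_all[t_all["progression_label"].notna()] if trains_prognosis else t_all.iloc[:0]
        v_prog = v_all[v_all["progression_label"].notna()] if trains_prognosis else v_all.iloc[:0]
        if trains_prognosis:
            pooled_prog[strategy] = t_prog

        for fold, t_fold in t_all.groupby("fold_index", sort=True):
            # diagnosis metrics on all test scans of the fold
            probs = t_fold[prob_cols].to_numpy(dtype=float)
            grades = t_fold["grade"].to_numpy(dtype=int)
            cm = confusion_matrix(grades, probs.argmax(axis=1), n_grades)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                balacc = balanced_accuracy(cm)
                try:
                    macro, micro = macro_micro_auroc(probs, grades)
                except UndefinedMetricError:
                    macro = micro = float("nan")
            diag_rows.append(
                {
                    "strategy": strategy,
                    "fold_index": fold,
                    "balanced_accuracy": balacc,
                    "macro_auroc": macro,
                    "micro_auroc": micro,
                }
            )
            confusions[strategy] = confusions.get(strategy, np.zeros((n_grades, n_grades), dtype=int)) + cm

            # prognosis metrics on the labeled subset
            tf = t_prog[t_prog["fold_index"] == fold]
            vf = v_prog[v_prog["fold_index"] == fold]
            if len(tf) == 0:
                continue
            y_test = tf["progression_label"].to_numpy(dtype=int)
            s_test = tf["prognosis_score"].to_numpy(dtype=float)
            row = {"strategy": strategy, "fold_index": fold}
            try:
                row["auroc"] = auroc(s_test, y_test)
                row["auprc"] = auprc(s_test, y_test)
            except UndefinedMetricError:
                row["auroc"] = row["auprc"] = float("nan")
            try:
                thr = youden_threshold(
                    vf["prognosis_score"].to_numpy(dtype=float),
                    vf["progression_label"].to_numpy(dtype=int),
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    row["sensitivity"], row["specificity"] = sens_spec_at_threshold(s_test, y_test, thr)
                row["youden_threshold"] = thr
            except (UndefinedMetricError, ValueError):
                row["sensitivity"] = row["specificity"] = row["youden_threshold"] = float("nan")
            prog_rows.append(row)

            # subgroup AUROCs within the fold
            pids = tf["patient_id"]
            base = gt.loc[pids, "baseline_grade"].to_numpy(dtype=int)
            fup = gt.loc[pids, "followup_grade"].to_numpy(dtype=int)
            groups = np.array([assign_subgroup(b, f, n_grades)[0] for b, f in zip(base, fup)])
            for name in ("incidence", "progression"):
                mask = groups == name
                yg, sg = y_test[mask], s_test[mask]
                if len(yg) == 0 or yg.sum() in (0, len(yg)):
                    warnings.warn(
                        f"subgroup {name} skipped for {strategy} fold {fold}: single-class or empty",
                        stacklevel=2,
                    )
                    continue
                subgroup_rows.append(
                    {
                        "strategy": strategy,
                        "fold_index": fold,
                        "subgroup": name,
                        "auroc": auroc(sg, yg),
                        "n": int(len(yg)),
                    }
                )

    prognosis_folds = pd.DataFrame(prog_rows)
    diagnosis_folds = pd.DataFrame(diag_rows)
    prognosis_summary = _summary(prognosis_folds, PROGNOSIS_METRICS) if len(prog_rows) else pd.DataFrame()
    diagnosis_summary = _summary(diagnosis_folds, DIAGNOSIS_METRICS)

    # pooled out-of-fold ensemble AUROC per strategy
    if len(prognosis_summary):
        ens_rows = []
        for strategy, frame in pooled_prog.items():
            if len(frame) == 0:
                continue
            pooled = frame.groupby("scan_id").agg(
                prognosis_score=("prognosis_score", "mean"),
                progression_label=("progression_label", "first"),
            )
            try:
                ens = auroc(pooled["prognosis_score"], pooled["progression_label"].astype(int))
            except UndefinedMetricError:
                ens = float("nan")
            ens_rows.append(
                {"strategy": strategy, "metric": "ensembled_auroc", "mean": ens, "sd": 0.0, "n_folds": 0}
            )
        prognosis_summary = pd.concat([prognosis_summary, pd.DataFrame(ens_rows)], ignore_index=True)

    delong = _delong_table(pooled_prog)
    subgroups = pd.DataFrame(subgroup_rows)
    if len(subgroups):
        subgroups = (
            subgroups.groupby(["strategy", "subgroup"], sort=True)
            .agg(auroc_mean=("auroc", "mean"), auroc_sd=("auroc", lambda v: v.std(ddof=1)), n=("n", "sum"))
            .reset_index()
        )
    forgetting = _forgetting_table(diagnosis_folds, confusions)
    return MetricReport(
        prognosis_folds,
        prognosis_summary,
        diagnosis_folds,
        diagnosis_summary,
        delong,
        subgroups,
        forgetting,
        confusions,
    )


def _delong_table(pooled_prog: dict[str, pd.DataFrame]) -> pd.DataFrame:
    rows = []
    for a, b in DELONG_PAIRS:
        if a not in pooled_prog or b not in pooled_prog:
            continue
        fa = pooled_prog[a].groupby("scan_id").agg(
            score=("prognosis_score", "mean"), label=("progression_label", "first")
        )
        fb = pooled_prog[b].groupby("scan_id")["prognosis_score"].mean()
        common = fa.index.intersection(fb.index)
        if len(common) == 0:
            continue
        labels = fa.loc[common, "label"].astype(int).to_numpy()
        try:
            res = delong_test(fa.loc[common, "score"].to_numpy(), fb.loc[common].to_numpy(), labels)
        except UndefinedMetricError:
            continue
        rows.append(
            {
                "strategy_a": a,
                "strategy_b": b,
                "auroc_a": res.auroc_a,
                "auroc_b": res.auroc_b,
                "z": res.z,
                "p": res.p,
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)


def _forgetting_table(diagnosis_folds: pd.DataFrame, confusions: dict[str, np.ndarray]) -> pd.DataFrame:
    """Balanced-accuracy deltas vs the dedicated diagnosis reference plus
    per-class recalls from the fold-summed confusion matrices."""
    if "diagnosis_reference" not in confusions:
        return pd.DataFrame()
    ref_mean = diagnosis_folds.loc[
        diagnosis_folds["strategy"] == "diagnosis_reference", "balanced_accuracy"
    ].mean()
    rows = []
    for strategy, cm in sorted(confusions.items()):
        mean_balacc = diagnosis_folds.loc[
            diagnosis_folds["strategy"] == strategy, "balanced_accuracy"
        ].mean()
        recalls = per_class_recall(cm)
        row = {
            "strategy": strategy,
            "balanced_accuracy": float(mean_balacc),
            "delta_vs_reference": float(mean_balacc - ref_mean),
        }
        for c, r in enumerate(recalls):
            row[f"recall_grade_{c}"] = float(r)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Table rendering
# ---------------------------------------------------------------------------

def _format_wide(summary: pd.DataFrame, metrics: list[str]) -> pd.DataFrame:
    """metric-by-strategy table: display 'mean ± sd' columns, machine columns,
    and a best-per-metric marker (arg-max across strategies)."""
    if summary.empty:
        return pd.DataFrame()
    strategies = sorted(summary["strategy"].unique())
    rows = []
    for metric in metrics:
        sub = summary[summary["metric"] == metric].set_index("strategy")
        if sub.empty:
            continue
        row: dict = {"metric": metric}
        best_strategy, best_val = "", -np.inf
        for strategy in strategies:
            if strategy in sub.index:
                m, s = sub.loc[strategy, "mean"], sub.loc[strategy, "sd"]
                row[strategy] = f"{m:.3f} ± {s:.3f}"
                row[f"{strategy}_mean"] = round(float(m), 10)
                row[f"{strategy}_sd"] = round(float(s), 10)
                if np.isfinite(m) and m > best_val:
                    best_strategy, best_val = strategy, float(m)
            else:
                row[strategy] = ""
        row["best"] = best_strategy
        rows.append(row)
    return pd.DataFrame(rows)


def build_tables(report: MetricReport) -> dict[str, pd.DataFrame]:
    """The three-table structure: initialization comparison, MT prognosis
    comparison, and MT diagnosis comparison, with missing strategies omitted
    (warning emitted)."""
    summary = report.prognosis_summary
    if summary.empty:
        summary = pd.DataFrame(columns=["strategy", "metric", "mean", "sd", "n_folds"])
    present = set(summary["strategy"].unique())
    init_strats = {"prognosis_single_task_random", "prognosis_single_task_pretrained"}
    if init_strats - present:
        warnings.warn(f"strategies missing from init comparison: {sorted(init_strats - present)}", stacklevel=2)

    table1 = _format_wide(
        summary[summary["strategy"].isin(init_strats)], PROGNOSIS_METRICS + ["ensembled_auroc"]
    )
    mt = present - {"prognosis_single_task_random"}
    table2 = _format_wide(
        summary[summary["strategy"].isin(mt)], PROGNOSIS_METRICS + ["ensembled_auroc"]
    )
    table3 = _format_wide(report.diagnosis_summary, DIAGNOSIS_METRICS)
    return {
        "table1_init_comparison": table1,
        "table2_prognosis_mt": table2,
        "table3_diagnosis": table3,
        "delong": report.delong,
        "subgroups": report.subgroups,
        "forgetting": report.forgetting,
    }


def save_confusion_figure(confusions: dict[str, np.ndarray], path) -> None:
    """Panel of confusion matrices per strategy (diagnosis task)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    strategies = sorted(confusions)
    fig, axes = plt.subplots(1, len(strategies), figsize=(3 * len(strategies), 3), squeeze=False)
    for ax, strategy in zip(axes[0], strategies):
        cm = confusions[strategy].astype(float)
        norm = cm / np.maximum(cm.sum(axis=1, keepdims=True), 1)
        ax.imshow(norm, cmap="Blues", vmin=0, vmax=1)
        ax.set_title(strategy, fontsize=7)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
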