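"""The training regimes compared by the benchmark.

Six regimes over one two-headed CNN:

- ``diagnosis_reference``: diagnosis head trained on the large (holdout-safe)
  diagnosis pool; also serves as the pretrained initialization.
- ``prognosis_single_task`` (random or diagnosis-pretrained init): prognosis
  head only; the attached diagnosis head is left untouched so its post-hoc
  metrics quantify forgetting.
- ``single_cohort_mt``: both heads, prognosis-cohort scans only, random init.
- ``diag_pretrained_mt``: same data regime, initialized from Phase 1.
- ``concurrent_mt``: per-batch sampling between both cohorts, random init.
- ``seq_replay``: Phase-1 init plus per-batch experience replay from the
  diagnosis cohort during prognosis training.

Every regime records the scan ids it touched for gradient updates and for
validation, which the pipeline audits against the fold's patient sets.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from dxprog.cohorts import CohortBundle, load_image_stack
from dxprog.config import BackboneConfig, StrategySpec, TrainConfig
from dxprog.exceptions import ConfigError, UndefinedMetricError
from dxprog.metrics import auroc, balanced_accuracy, confusion_matrix
from dxprog.nn import Adam, TwoHeadCNN, augment_batch, cosine_lr
from dxprog.nn.layers import bce_logit_loss, softmax_ce_loss
from dxprog.splits import FoldAssignment


# ---------------------------------------------------------------------------
# In-memory dataset
# ---------------------------------------------------------------------------

@dataclass
class ScanDataset:
    """Column arrays for a set of scans plus their (pre-downsampled) images."""

    scan_ids: np.ndarray
    patient_ids: np.ndarray
    grades: np.ndarray
    prog_labels: np.ndarray  # float, NaN where absent
    images: np.ndarray  # (N, h, w) float32

    def __len__(self) -> int:
        return len(self.scan_ids)

    def subset(self, mask: np.ndarray) -> "ScanDataset":
        return ScanDataset(
            self.scan_ids[mask],
            self.patient_ids[mask],
            self.grades[mask],
            self.prog_labels[mask],
            self.images[mask],
        )

    def for_patients(self, patients: frozenset[str] | set[str], labeled_only: bool = False) -> "ScanDataset":
        mask = np.isin(self.patient_ids, list(patients))
        if labeled_only:
            mask &= ~np.isnan(self.prog_labels)
        return self.subset(mask)


def dataset_from_bundle(bundle: CohortBundle, downsample: int = 2) -> ScanDataset:
    """Images are half-resolution in memory (augmentation happens at that
    scale); the model pools the rest of the way on entry."""
    meta = bundle.diagnosis_scans
    labels = meta["progression_label"].astype("Float64").to_numpy(dtype=float, na_value=np.nan)
    return ScanDataset(
        scan_ids=meta["scan_id"].to_numpy(dtype=object),
        patient_ids=meta["patient_id"].to_numpy(dtype=object),
        grades=meta["grade"].to_numpy(dtype=int),
        prog_labels=labels,
        images=load_image_stack(bundle, downsample=downsample),
    )


# ---------------------------------------------------------------------------
# Bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class TrainAudit:
    """Scan ids touched by gradient updates and by validation."""

    train_scan_ids: set = field(default_factory=set)
    val_scan_ids: set = field(default_factory=set)


@dataclass
class TrainedModel:
    model: TwoHeadCNN
    strategy: StrategySpec
    fold_index: int
    training_log: list[dict]
    selected_epoch: int
    audit: TrainAudit


def inverse_frequency_weights(grades: np.ndarray, n_classes: int) -> np.ndarray:
    """Per-class weights proportional to 1/count, renormalized to mean 1 over
    the classes present in the data; absent classes get weight 0."""
    counts = np.bincount(np.asarray(grades, dtype=int), minlength=n_classes).astype(float)
    present = counts > 0
    if not present.all():
        warnings.warn(
            f"grade classes {np.where(~present)[0].tolist()} absent from training data",
            stacklevel=2,
        )
    weights = np.zeros(n_classes)
    weights[present] = 1.0 / counts[present]
    weights[present] *= present.sum() / weights[present].sum()
    return weights


def replay_batch_source(rng: np.random.Generator, p: float) -> str:
    """Bernoulli(p) choice of the cohort the next (single-task) batch comes from."""
    if not (0.0 <= p <= 1.0):
        raise ConfigError("replay probability must be in [0, 1]")
    return "prognosis" if rng.random() < p else "diagnosis"


def select_checkpoint(training_log: list[dict], criterion: str) -> int:
    """Arg-max epoch of the criterion (arg-min for losses); NaNs skipped with a
    warning; ties break toward the earliest epoch."""
    if not training_log:
        raise ValueError("training log is empty")
    sign = -1.0 if criterion == "val_total_loss" else 1.0
    values = np.array([sign * entry.get(criterion, np.nan) for entry in training_log], dtype=float)
    if np.isnan(values).any():
        warnings.warn(f"{criterion} undefined at epochs {np.where(np.isnan(values))[0].tolist()}", stacklevel=2)
    if np.isnan(values).all():
        raise UndefinedMetricError(f"{criterion} undefined at every epoch")
    best = np.nanmax(values)
    return int(np.where(values >= best - 1e-15)[0][0])


# ---------------------------------------------------------------------------
# Core training loop
# ---------------------------------------------------------------------------

def _epoch_validation(model: TwoHeadCNN, val_diag: ScanDataset | None, val_prog: ScanDataset | None) -> dict:
    entry: dict = {}
    total_loss = 0.0
    if val_prog is not None and len(val_prog):
        _, prog_logits, _ = model.forward(val_prog.images)
        loss, _ = bce_logit_loss(prog_logits, val_prog.prog_labels)
        total_loss += loss
        y = val_prog.prog_labels.astype(int)
        if 0 < y.sum() < len(y):
            from dxprog.nn.layers import sigmoid

            entry["val_prognosis_auroc"] = auroc(sigmoid(prog_logits.ravel()), y)
        else:
            entry["val_prognosis_auroc"] = float("nan")
    if val_diag is not None and len(val_diag):
        diag_logits, _, _ = model.forward(val_diag.images)
        loss, _ = softmax_ce_loss(diag_logits, val_diag.grades)
        total_loss += loss
        preds = diag_logits.argmax(axis=1)
        n_classes = model.cfg.diagnosis_classes
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            entry["val_diagnosis_balacc"] = balanced_accuracy(
                confusion_matrix(val_diag.grades, preds, n_classes)
            )
    entry["val_total_loss"] = total_loss
    return entry


def _train_loop(
    model: TwoHeadCNN,
    batch_plan,
    cfg: TrainConfig,
    rng: np.random.Generator,
    val_diag: ScanDataset | None,
    val_prog: ScanDataset | None,
    class_weights: np.ndarray | None,
    criterion: str,
    audit: TrainAudit,
) -> tuple[list[dict], int, list[dict]]:
    """Generic epoch loop. ``batch_plan(epoch, rng)`` yields
    (dataset, index_array, task) triples with task in {diag, prog, both}."""
    optimizer = Adam(model.params, lr=cfg.lr, betas=cfg.betas)
    training_log: list[dict] = []
    states: list[dict] = []
    sign = -1.0 if criterion == "val_total_loss" else 1.0
    best_value = -np.inf
    since_best = 0
    for epoch in range(cfg.epochs):
        optimizer.lr = cosine_lr(cfg.lr, cfg.lr_min, epoch, cfg.epochs)
        epoch_loss, n_batches = 0.0, 0
        for ds, idx, task in batch_plan(epoch, rng):
            audit.train_scan_ids.update(ds.scan_ids[idx])
            x = ds.images[idx]
            if cfg.augmentation == "flips+crops+rotations":
                x = augment_batch(x, rng)
            diag_logits, prog_logits, cache = model.forward(x)
            d_diag = d_prog = None
            loss = 0.0
            if task in ("diag", "both"):
                l_d, d_diag = softmax_ce_loss(diag_logits, ds.grades[idx], class_weights)
                loss += l_d
            if task in ("prog", "both"):
                l_p, d_prog = bce_logit_loss(prog_logits, ds.prog_labels[idx])
                loss += l_p
            grads = model.backward(cache, d_diag, d_prog)
            optimizer.step(grads)
            epoch_loss += loss
            n_batches += 1
        entry = {"epoch": epoch, "lr": optimizer.lr, "train_loss": epoch_loss / max(n_batches, 1)}
        entry.update(_epoch_validation(model, val_diag, val_prog))
        training_log.append(entry)
        states.append(model.state_dict())
        value = sign * entry.get(criterion, np.nan)
        if np.isfinite(value) and value > best_value + 1e-15:
            best_value = value
            since_best = 0
        else:
            since_best += 1
        if since_best >= cfg.early_stop_patience:
            break
    if val_diag is not None:
        audit.val_scan_ids.update(val_diag.scan_ids)
    if val_prog is not None:
        audit.val_scan_ids.update(val_prog.scan_ids)
    return training_log, _select_with_fallback(training_log, criterion), states


def _select_with_fallback(training_log: list[dict], criterion: str) -> int:
    try:
        return select_checkpoint(training_log, criterion)
    except UndefinedMetricError:
        warnings.warn(f"{criterion} undefined throughout; falling back to val_total_loss", stacklevel=2)
        return select_checkpoint(training_log, "val_total_loss")


def _shuffled_batches(ds: ScanDataset, task: str, batch_size: int):
    def plan(epoch: int, rng: np.random.Generator):
        order = rng.permutation(len(ds))
        for start in range(0, len(ds), batch_size):
            yield ds, order[start : start + batch_size], task

    return plan


# ---------------------------------------------------------------------------
# Regimes
# ---------------------------------------------------------------------------

def train_diagnosis_reference(
    pretrain_ds: ScanDataset,
    val_ds: ScanDataset,
    backbone: BackboneConfig,
    cfg: TrainConfig,
    rng: np.random.Generator,
    fold_index: int = 0,
) -> TrainedModel:
    """Phase 1: diagnosis head on the large cohort; checkpoint on validation
    balanced accuracy. Doubles as the pretrained initialization downstream."""
    model = TwoHeadCNN(backbone, rng)
    weights = inverse_frequency_weights(pretrain_ds.grades, backbone.diagnosis_classes) if cfg.weighted_ce else None
    audit = TrainAudit()
    log, selected, states = _train_loop(
        model,
        _shuffled_batches(pretrain_ds, "diag", cfg.batch_size),
        cfg,
        rng,
        val_diag=val_ds,
        val_prog=None,
        class_weights=weights,
        criterion="val_diagnosis_balacc",
        audit=audit,
    )
    model.load_state_dict(states[selected])
    return TrainedModel(model, StrategySpec("diagnosis_reference"), fold_index, log, selected, audit)


def train_prognosis_single_task(
    train_ds: ScanDataset,
    val_ds: ScanDataset,
    init: str,
    backbone: BackboneConfig,
    cfg: TrainConfig,
    rng: np.random.Generator,
    pretrained: TrainedModel | None = None,
    fold_index: int = 0,
) -> TrainedModel:
    """Single-task prognosis fine-tuning from random or diagnosis-pretrained weights."""
    if np.isnan(train_ds.prog_labels).any():
        raise ValueError("prognosis training scans must all carry progression labels")
    spec = StrategySpec("prognosis_single_task", init=init)
    model = TwoHeadCNN(backbone, rng)
    if init == "diagnosis_pretrained":
        if pretrained is None:
            raise ConfigError("diagnosis_pretrained init requires a Phase-1 model")
        model.copy_trunk_and_diag_from(pretrained.model)
        cfg = dataclasses.replace(cfg, lr=cfg.lr * cfg.finetune_lr_scale)
    audit = TrainAudit()
    log, selected, states = _train_loop(
        model,
        _shuffled_batches(train_ds, "prog", cfg.batch_size),
        cfg,
        rng,
        val_diag=None,
        val_prog=val_ds,
        class_weights=None,
        criterion="val_prognosis_auroc",
        audit=audit,
    )
    model.load_state_dict(states[selected])
    return TrainedModel(model, spec, fold_index, log, selected, audit)


def train_multitask(
    strategy: StrategySpec,
    prog_train: ScanDataset,
    diag_replay: ScanDataset | None,
    val_prog: ScanDataset,
    val_diag: ScanDataset,
    backbone: BackboneConfig,
    cfg: TrainConfig,
    rng: np.random.Generator,
    pretrained: TrainedModel | None = None,
    fold_index: int = 0,
) -> TrainedModel:
    """The four multitask regimes; all checkpoint on validation prognosis AUROC
    (configurable via ``cfg.checkpoint_criterion``)."""
    if not strategy.is_multitask:
        raise ConfigError(f"{strategy.name} is not a multitask strategy")
    if strategy.needs_pretrained and pretrained is None:
        raise ConfigError(f"{strategy.name} requires a Phase-1 pretrained model")
    uses_replay = strategy.name in ("concurrent_mt", "seq_replay")
    if uses_replay and diag_replay is None:
        raise ConfigError(f"{strategy.name} requires a diagnosis replay pool")

    model = TwoHeadCNN(backbone, rng)
    if strategy.needs_pretrained:
        model.copy_trunk_and_diag_from(pretrained.model)
        cfg = dataclasses.replace(cfg, lr=cfg.lr * cfg.finetune_lr_scale)

    n_classes = backbone.diagnosis_classes
    weight_source = diag_replay.grades if uses_replay else prog_train.grades
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        class_weights = inverse_frequency_weights(weight_source, n_classes) if cfg.weighted_ce else None

    batch_size = cfg.batch_size
    if uses_replay:
        # epoch sized at twice the replay pool so diagnosis exposure per epoch
        # matches the dedicated reference (half the batches in expectation at
        # p = 0.5)
        steps = max(2 * math.ceil(len(prog_train) / batch_size), 2 * math.ceil(len(diag_replay) / batch_size))

        def plan(epoch: int, rng_: np.random.Generator):
            for _ in range(steps):
                source = replay_batch_source(rng_, cfg.replay_probability)
                if source == "prognosis":
                    take = min(batch_size, len(prog_train))
                    yield prog_train, rng_.choice(len(prog_train), size=take, replace=False), "prog"
                else:
                    take = min(batch_size, len(diag_replay))
                    yield diag_replay, rng_.choice(len(diag_replay), size=take, replace=False), "diag"

    else:
        plan = _shuffled_batches(prog_train, "both", batch_size)

    audit = TrainAudit()
    log, selected, states = _train_loop(
        model,
        plan,
        cfg,
        rng,
        val_diag=val_diag,
        val_prog=val_prog,
        class_weights=class_weights,
        criterion=cfg.checkpoint_criterion,
        audit=audit,
    )
    model.load_state_dict(states[selected])
    return TrainedModel(model, strategy, fold_index, log, selected, audit)


# ---------------------------------------------------------------------------
# Fold orchestration helper
# ---------------------------------------------------------------------------

def fold_datasets(ds: ScanDataset, fold: FoldAssignment) -> dict[str, ScanDataset]:
    """Slice the cohort into the per-fold training/validation/test datasets.

    The diagnosis pretraining/replay pool excludes the fold's validation
    patients (in addition to the mandated test holdout) so that validation
    metrics stay untouched by any gradient.
    """
    diag_pool_patients = (
        fold.pretrain_diagnosis_patients - fold.val_patients - fold.val_diagnosis_patients
    )
    return {
        "diag_train": ds.for_patients(diag_pool_patients),
        "diag_val": ds.for_patients(fold.val_patients | fold.val_diagnosis_patients),
        "diag_test": ds.for_patients(fold.test_patients | fold.test_diagnosis_patients),
        "prog_train": ds.for_patients(fold.train_patients, labeled_only=True),
        "prog_val": ds.for_patients(fold.val_patients, labeled_only=True),
        "prog_test": ds.for_patients(fold.test_patients, labeled_only=True),
    }


def train_strategy_for_fold(
    strategy: StrategySpec,
    data: dict[str, ScanDataset],
    backbone: BackboneConfig,
    cfg: TrainConfig,
    rng: np.random.Generator,
    reference: TrainedModel | None,
    fold_index: int,
) -> TrainedModel:
    """Dispatch one strategy on one fold's datasets."""
    if strategy.name == "diagnosis_reference":
        return train_diagnosis_reference(
            data["diag_train"], data["diag_val"], backbone, cfg, rng, fold_index
        )
    if strategy.name == "prognosis_single_task":
        return train_prognosis_single_task(
            data["prog_train"],
            data["prog_val"],
            strategy.init,
            backbone,
            cfg,
            rng,
            pretrained=reference,
            fold_index=fold_index,
        )
    return train_multitask(
        strategy,
        data["prog_train"],
        data["diag_train"],
        data["prog_val"],
        data["diag_val"],
        backbone,
        cfg,
        rng,
        pretrained=reference,
        fold_index=fold_index,
    )
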