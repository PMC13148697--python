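"""Patient-level 5-fold cross-validation with a pretraining test-set holdout.

Folds partition the *prognosis-cohort patients*; every patient serves as part
of a test set exactly once. Per fold, the validation fold is the next fold
cyclically and the remaining three folds train. The diagnosis-pretraining
pool for a fold is every diagnosis-cohort patient except that fold's test
patients, so the pretraining stage never sees a patient it will later be
evaluated on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from dxprog.cohorts import CohortBundle
from dxprog.exceptions import LeakageError, SplitError


@dataclass
class FoldAssignment:
    fold_index: int
    test_patients: frozenset[str]
    val_patients: frozenset[str]
    train_patients: frozenset[str]
    pretrain_diagnosis_patients: frozenset[str]
    #: diagnosis-cohort-only patients (never prognosis-labeled, including all
    #: maximal-grade patients) folded in parallel so the diagnosis task has
    #: held-out test/validation data covering every grade; both sets are
    #: excluded from the fold's gradient updates
    val_diagnosis_patients: frozenset[str] = frozenset()
    test_diagnosis_patients: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.test_patients & self.val_patients or self.test_patients & self.train_patients:
            raise SplitError("test patients overlap train/val")
        if self.val_patients & self.train_patients:
            raise SplitError("val patients overlap train")
        if self.pretrain_diagnosis_patients & (self.test_patients | self.test_diagnosis_patients):
            raise SplitError("pretraining pool contains test patients")
        prog = self.test_patients | self.val_patients | self.train_patients
        if (self.val_diagnosis_patients | self.test_diagnosis_patients) & prog:
            raise SplitError("diagnosis-only fold extras must be diagnosis-only patients")
        if self.val_diagnosis_patients & self.test_diagnosis_patients:
            raise SplitError("diagnosis-only test and validation extras overlap")


@dataclass
class SplitPlan:
    folds: list[FoldAssignment]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)


def make_split_plan(bundle: CohortBundle, k: int = 5, seed: int = 0) -> SplitPlan:
    """Partition prognosis-cohort patients into k folds (test/val/train roles).

    Diagnosis-only patients (which include every maximal-grade patient) are
    partitioned into k parallel folds as well: per fold one chunk is the
    held-out diagnosis test extension and the next (cyclically) the diagnosis
    validation extension. Both are excluded from that fold's pretraining
    gradients, so diagnosis metrics — including rare-grade recall — are always
    computed on never-seen patients.
    """
    if k < 2:
        raise SplitError("k must be >= 2")
    prog_patients = sorted(bundle.prognosis_scans["patient_id"].unique())
    all_patients = sorted(bundle.diagnosis_scans["patient_id"].unique())
    if len(prog_patients) < k:
        raise SplitError(f"need at least {k} prognosis-cohort patients, have {len(prog_patients)}")

    rng = np.random.default_rng(np.random.SeedSequence((seed, 17)))
    permuted = list(np.array(prog_patients)[rng.permutation(len(prog_patients))])
    chunks = [set(map(str, c)) for c in np.array_split(permuted, k)]

    diag_only = sorted(set(all_patients) - set(prog_patients))
    if diag_only:
        diag_perm = list(np.array(diag_only)[rng.permutation(len(diag_only))])
        diag_chunks = [set(map(str, c)) for c in np.array_split(diag_perm, k)]
    else:
        diag_chunks = [set() for _ in range(k)]

    folds = []
    for i in range(k):
        test = chunks[i]
        val = chunks[(i + 1) % k]
        train = set().union(*(chunks[j] for j in range(k) if j != i and j != (i + 1) % k))
        test_diag = diag_chunks[i]
        val_diag = diag_chunks[(i + 1) % k]
        pretrain = set(all_patients) - test - test_diag
        folds.append(
            FoldAssignment(
                fold_index=i,
                test_patients=frozenset(test),
                val_patients=frozenset(val),
                train_patients=frozenset(train),
                pretrain_diagnosis_patients=frozenset(pretrain),
                val_diagnosis_patients=frozenset(val_diag),
                test_diagnosis_patients=frozenset(test_diag),
            )
        )
    return SplitPlan(folds=folds, seed=seed)


def assign_subgroup(baseline_grade: int, followup_grade: int, n_grades: int = 5):
    """Clinical subgroup and event status from baseline and follow-up grades.

    Early baseline grades (0-1) form the *incidence* subgroup (event: reaching
    grade >= 2); established grades up to n_grades-2 form the *progression*
    subgroup (event: any grade increase); the maximal baseline grade is
    excluded.
    """
    if not (0 <= baseline_grade <= n_grades - 1) or not (0 <= followup_grade <= n_grades - 1):
        raise ValueError("grades out of range")
    if followup_grade < baseline_grade:
        raise ValueError("follow-up grade must be >= baseline grade")
    if baseline_grade == n_grades - 1:
        return "excluded", None
    if baseline_grade <= 1:
        return "incidence", int(followup_grade >= 2)
    return "progression", int(followup_grade > baseline_grade)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def split_plan_to_frame(plan: SplitPlan) -> pd.DataFrame:
    """Wide CSV layout: one row per patient, a role column per fold."""
    patients = sorted(set().union(*(f.pretrain_diagnosis_patients | f.test_patients for f in plan.folds)))
    records = []
    for pid in patients:
        row: dict = {"patient_id": pid, "fold_of_test": ""}
        for fold in plan.folds:
            if pid in fold.test_patients:
                role = "test"
                row["fold_of_test"] = fold.fold_index
            elif pid in fold.val_patients:
                role = "val"
            elif pid in fold.train_patients:
                role = "train"
            elif pid in fold.test_diagnosis_patients:
                role = "test_diag"
            elif pid in fold.val_diagnosis_patients:
                role = "val_diag"
            elif pid in fold.pretrain_diagnosis_patients:
                role = "pretrain_only"
            else:
                role = "none"
            row[f"role_fold{fold.fold_index}"] = role
        records.append(row)
    return pd.DataFrame(records)


def save_split_plan(plan: SplitPlan, path: str | Path) -> None:
    split_plan_to_frame(plan).to_csv(path, index=False)


def load_split_plan(path: str | Path, seed: int = 0) -> SplitPlan:
    frame = pd.read_csv(path, dtype={"patient_id": str})
    role_cols = sorted(c for c in frame.columns if c.startswith("role_fold"))
    folds = []
    for i, col in enumerate(role_cols):
        test = frozenset(frame.loc[frame[col] == "test", "patient_id"])
        val = frozenset(frame.loc[frame[col] == "val", "patient_id"])
        train = frozenset(frame.loc[frame[col] == "train", "patient_id"])
        val_diag = frozenset(frame.loc[frame[col] == "val_diag", "patient_id"])
        test_diag = frozenset(frame.loc[frame[col] == "test_diag", "patient_id"])
        pretrain = frozenset(
            frame.loc[~frame[col].isin(["test", "test_diag", "none"]), "patient_id"]
        )
        folds.append(FoldAssignment(i, test, val, train, pretrain, val_diag, test_diag))
    return SplitPlan(folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# Leakage audit
# ---------------------------------------------------------------------------

def audit_fold_access(
    fold: FoldAssignment,
    scan_to_patient: dict[str, str],
    train_scan_ids: set[str],
    stage: str,
) -> None:
    """Raise LeakageError if any accessed training scan belongs to a test patient."""
    touched = {scan_to_patient[s] for s in train_scan_ids}
    bad = touched & fold.test_patients
    if bad:
        raise LeakageError(
            f"{stage}: fold {fold.fold_index} trained on scans of test patients {sorted(bad)[:5]}"
        )
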