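import warnings

import numpy as np
import pytest

from dxprog import strategies as S
from dxprog.config import BackboneConfig, StrategySpec, TrainConfig
from dxprog.exceptions import ConfigError, UndefinedMetricError
from dxprog.metrics import auroc
from dxprog.splits import make_split_plan


@pytest.fixture(scope="module")
def fold_data(tiny_bundle, tiny_dataset):
    plan = make_split_plan(tiny_bundle, k=5, seed=0)
    return S.fold_datasets(tiny_dataset, plan.folds[0]), plan.folds[0]


class TestInverseFrequencyWeights:
    def test_two_class_example(self):
        grades = np.array([0] * 90 + [1] * 10)
        w = S.inverse_frequency_weights(grades, 2)
        # proportional to (1/90, 1/10), renormalized to mean 1
        raw = np.array([1 / 90, 1 / 10])
        expected = raw * 2 / raw.sum()
        np.testing.assert_allclose(w, expected, atol=1e-12)
        assert w.mean() == pytest.approx(1.0)

    def test_absent_class_warns_and_zero_weight(self):
        with pytest.warns(UserWarning):
            w = S.inverse_frequency_weights(np.array([0, 0, 2]), 4)
        assert w[1] == 0.0 and w[3] == 0.0
        assert w[w > 0].mean() == pytest.approx(1.0)


class TestReplayBatchSource:
    def test_p_one_always_prognosis(self):
        rng = np.random.default_rng(0)
        assert all(S.replay_batch_source(rng, 1.0) == "prognosis" for _ in range(100))

    def test_p_zero_always_diagnosis(self):
        rng = np.random.default_rng(1)
        assert all(S.replay_batch_source(rng, 0.0) == "diagnosis" for _ in range(100))

    def test_p_half_binomial_interval(self):
        rng = np.random.default_rng(2)
        draws = [S.replay_batch_source(rng, 0.5) for _ in range(10000)]
        frac_diag = draws.count("diagnosis") / len(draws)
        assert 0.48 <= frac_diag <= 0.52

    def test_invalid_p(self):
        with pytest.raises(ConfigError):
            S.replay_batch_source(np.random.default_rng(0), 1.5)


class TestSelectCheckpoint:
    def _log(self, values, key="val_prognosis_auroc"):
        return [{key: v} for v in values]

    def test_argmax(self):
        assert S.select_checkpoint(self._log([0.6, 0.8, 0.7]), "val_prognosis_auroc") == 1

    def test_tie_breaks_earliest(self):
        assert S.select_checkpoint(self._log([0.7, 0.7, 0.7]), "val_prognosis_auroc") == 0

    def test_nan_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            sel = S.select_checkpoint(self._log([0.6, 0.7, float("nan")]), "val_prognosis_auroc")
        assert sel == 1

    def test_all_nan_errors(self):
        with pytest.raises(UndefinedMetricError), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            S.select_checkpoint(self._log([float("nan")] * 3), "val_prognosis_auroc")

    def test_loss_criterion_minimizes(self):
        log = self._log([0.9, 0.4, 0.6], key="val_total_loss")
        assert S.select_checkpoint(log, "val_total_loss") == 1

    def test_empty_log_errors(self):
        with pytest.raises(ValueError):
            S.select_checkpoint([], "val_prognosis_auroc")


class TestDiagnosisReference:
    def test_one_epoch_bookkeeping(self, fold_data, small_backbone):
        data, _ = fold_data
        cfg = TrainConfig(epochs=1, batch_size=16)
        model = S.train_diagnosis_reference(
            data["diag_train"], data["diag_val"], small_backbone, cfg, np.random.default_rng(0)
        )
        assert len(model.training_log) == 1
        assert model.selected_epoch == 0

    def test_learns_better_than_chance(self, fold_data):
        data, _ = fold_data
        cfg = TrainConfig(epochs=8, batch_size=16)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = S.train_diagnosis_reference(
                data["diag_train"], data["diag_val"], BackboneConfig(), cfg, np.random.default_rng(1)
            )
        best = max(e["val_diagnosis_balacc"] for e in model.training_log)
        assert best > 1.0 / 5.0

    def test_audit_covers_only_training_pool(self, fold_data):
        data, fold = fold_data
        cfg = TrainConfig(epochs=1, batch_size=16)
        model = S.train_diagnosis_reference(
            data["diag_train"], data["diag_val"], BackboneConfig(), cfg, np.random.default_rng(2)
        )
        assert model.audit.train_scan_ids == set(data["diag_train"].scan_ids)
        assert not model.audit.train_scan_ids & set(data["diag_test"].scan_ids)


class TestPrognosisSingleTask:
    def test_pretrained_trunk_bit_identical_at_epoch_zero(self, fold_data, small_backbone):
        data, _ = fold_data
        cfg = TrainConfig(epochs=1, batch_size=16)
        ref = S.train_diagnosis_reference(
            data["diag_train"], data["diag_val"], small_backbone, cfg, np.random.default_rng(3)
        )
        # zero training steps: an empty batch plan leaves the initialization untouched
        model = S.TwoHeadCNN(small_backbone, np.random.default_rng(4))
        model.copy_trunk_and_diag_from(ref.model)
        for key, value in ref.model.params.items():
            if key.startswith(("conv", "fc", "head_diag")):
                np.testing.assert_array_equal(model.params[key], value)

    def test_zero_training_steps_predictions_unchanged(self, fold_data, small_backbone):
        data, _ = fold_data
        cfg = TrainConfig(epochs=1, batch_size=16)
        model = S.TwoHeadCNN(small_backbone, np.random.default_rng(5))
        before_probs, before_scores = model.predict(data["prog_val"].images)
        audit = S.TrainAudit()
        log, sel, states = S._train_loop(
            model,
            lambda epoch, rng: iter(()),  # no batches
            cfg,
            np.random.default_rng(6),
            val_diag=None,
            val_prog=data["prog_val"],
            class_weights=None,
            criterion="val_prognosis_auroc",
            audit=audit,
        )
        model.load_state_dict(states[sel])
        after_probs, after_scores = model.predict(data["prog_val"].images)
        np.testing.assert_array_equal(before_probs, after_probs)
        np.testing.assert_array_equal(before_scores, after_scores)

    def test_learnable_above_chance(self, tmp_path):
        """Strong-signal cohort: random-init single-task prognosis beats
        chance for every seed (the frozen benchmark config is exercised at
        full scale in the acceptance suite)."""
        from dxprog.cohorts import build_cohorts
        from dxprog.config import GeneratorConfig

        gen = GeneratorConfig(
            n_patients=120,
            scans_per_patient_range=(2, 2),
            prognosis_cohort_fraction=1.0,
            severity_progression_correlation=0.8,
            progression_severity_coef=2.0,
            progression_rate_coef=1.0,
            pixel_noise_sd=0.02,
            seed=5,
        )
        bundle = build_cohorts(gen, tmp_path / "easy")
        ds = S.dataset_from_bundle(bundle)
        plan = make_split_plan(bundle, k=5, seed=0)
        data = S.fold_datasets(ds, plan.folds[0])
        cfg = TrainConfig(epochs=8, batch_size=16)
        aurocs = []
        for seed in range(3):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = S.train_prognosis_single_task(
                    data["prog_train"],
                    data["prog_val"],
                    "random",
                    BackboneConfig(),
                    cfg,
                    np.random.default_rng(seed),
                )
            _, scores = model.model.predict(data["prog_test"].images)
            aurocs.append(auroc(scores, data["prog_test"].prog_labels.astype(int)))
        assert all(a > 0.5 for a in aurocs)

    def test_requires_labels(self, fold_data, small_backbone):
        data, _ = fold_data
        cfg = TrainConfig(epochs=1)
        with pytest.raises(ValueError):
            S.train_prognosis_single_task(
                data["diag_train"], data["prog_val"], "random", small_backbone, cfg, np.random.default_rng(0)
            )

    def test_pretrained_requires_phase1(self, fold_data, small_backbone):
        data, _ = fold_data
        with pytest.raises(ConfigError):
            S.train_prognosis_single_task(
                data["prog_train"],
                data["prog_val"],
                "diagnosis_pretrained",
                small_backbone,
                TrainConfig(epochs=1),
                np.random.default_rng(0),
                pretrained=None,
            )


class TestMultitask:
    @pytest.fixture()
    def trained_ref(self, fold_data, small_backbone):
        data, _ = fold_data
        cfg = TrainConfig(epochs=1, batch_size=16)
        return S.train_diagnosis_reference(
            data["diag_train"], data["diag_val"], small_backbone, cfg, np.random.default_rng(7)
        )

    def test_single_cohort_mt_data_access_restricted(self, fold_data, small_backbone):
        data, fold = fold_data
        cfg = TrainConfig(epochs=2, batch_size=16)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = S.train_multitask(
                StrategySpec("single_cohort_mt"),
                data["prog_train"],
                data["diag_train"],
                data["prog_val"],
                data["diag_val"],
                small_backbone,
                cfg,
                np.random.default_rng(8),
            )
        assert model.audit.train_scan_ids <= set(data["prog_train"].scan_ids)

    def test_seq_replay_p1_never_reads_diagnosis(self, fold_data, small_backbone, trained_ref):
        data, _ = fold_data
        cfg = TrainConfig(epochs=2, batch_size=16, replay_probability=1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = S.train_multitask(
                StrategySpec("seq_replay", init="diagnosis_pretrained"),
                data["prog_train"],
                data["diag_train"],
                data["prog_val"],
                data["diag_val"],
                small_backbone,
                cfg,
                np.random.default_rng(9),
                pretrained=trained_ref,
            )
        assert model.audit.train_scan_ids <= set(data["prog_train"].scan_ids)

    def test_seq_replay_p0_only_diagnosis_batches(self, fold_data, small_backbone, trained_ref):
        data, _ = fold_data
        cfg = TrainConfig(epochs=1, batch_size=16, replay_probability=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = S.train_multitask(
                StrategySpec("seq_replay", init="diagnosis_pretrained"),
                data["prog_train"],
                data["diag_train"],
                data["prog_val"],
                data["diag_val"],
                small_backbone,
                cfg,
                np.random.default_rng(10),
                pretrained=trained_ref,
            )
        assert model.audit.train_scan_ids <= set(data["diag_train"].scan_ids)

    def test_missing_phase1_errors(self, fold_data, small_backbone):
        data, _ = fold_data
        with pytest.raises(ConfigError):
            S.train_multitask(
                StrategySpec("seq_replay", init="diagnosis_pretrained"),
                data["prog_train"],
                data["diag_train"],
                data["prog_val"],
                data["diag_val"],
                small_backbone,
                TrainConfig(epochs=1),
                np.random.default_rng(0),
                pretrained=None,
            )

    def test_reproducible_training_log(self, fold_data, small_backbone, trained_ref):
        data, _ = fold_data
        cfg = TrainConfig(epochs=2, batch_size=16)
        logs = []
        for _ in range(2):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = S.train_multitask(
                    StrategySpec("seq_replay", init="diagnosis_pretrained"),
                    data["prog_train"],
                    data["diag_train"],
                    data["prog_val"],
                    data["diag_val"],
                    small_backbone,
                    cfg,
                    np.random.default_rng(11),
                    pretrained=trained_ref,
                )
            logs.append(model.training_log)
        assert logs[0] == logs[1]

    def test_non_multitask_strategy_rejected(self, fold_data, small_backbone):
        data, _ = fold_data
        with pytest.raises(ConfigError):
            S.train_multitask(
                StrategySpec("prognosis_single_task"),
                data["prog_train"],
                data["diag_train"],
                data["prog_val"],
                data["diag_val"],
                small_backbone,
                TrainConfig(epochs=1),
                np.random.default_rng(0),
            )


class TestFoldDatasets:
    def test_partitions(self, fold_data, tiny_dataset):
        data, fold = fold_data
        assert not set(data["diag_train"].patient_ids) & set(data["diag_test"].patient_ids)
        assert not set(data["diag_train"].patient_ids) & set(data["diag_val"].patient_ids)
        assert set(data["prog_train"].patient_ids) <= fold.train_patients
        assert np.isnan(data["prog_train"].prog_labels).sum() == 0

    def test_prog_scans_subset_of_diag(self, fold_data):
        data, _ = fold_data
        assert set(data["prog_test"].scan_ids) <= set(data["diag_test"].scan_ids)
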