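# dxprog

A desk-scale benchmark for **sequential diagnosis-to-prognosis learning with
experience replay** on fully synthetic imaging cohorts.

The package generates paired cohorts that mimic the statistical structure of
clinical imaging studies — a large cross-sectional *diagnosis* cohort with an
imbalanced ordinal severity grade per scan (including a rare top grade), and a
small longitudinal *prognosis* cohort drawn from the same patient population
with a binary progression-within-horizon label — and then compares six
training regimes for a small two-headed CNN under a leakage-safe, patient-level
5-fold cross-validation protocol:

| strategy | init | data |
|---|---|---|
| `diagnosis_reference` | random | full diagnosis pool (Phase 1 / pretraining) |
| `prognosis_single_task` | random **or** diagnosis-pretrained | prognosis cohort |
| `single_cohort_mt` | random | prognosis cohort, both heads |
| `diag_pretrained_mt` | diagnosis-pretrained | prognosis cohort, both heads, no replay |
| `concurrent_mt` | random | both cohorts, per-batch p=0.5 sampling |
| `seq_replay` | diagnosis-pretrained | prognosis cohort + diagnosis experience replay (p=0.5) |

Evaluation covers AUROC/AUPRC, balanced accuracy, macro/micro one-vs-rest
AUROC, Youden-index operating points transferred from validation to test,
per-scan fold ensembling, the DeLong test for correlated ROC curves, confusion
matrices, rare-class forgetting and clinical-subgroup (incidence vs
progression) analyses.

Because the generative model is known, the attainable discrimination is
computable in closed form (`cohorts.oracle_auroc_closed_form`), which is used
to calibrate the default configuration into a learnable-but-imperfect regime.
The neural-network stack (conv layers, backprop, Adam + cosine annealing,
augmentation) is implemented in NumPy — no deep-learning framework is
required, and the full benchmark trains in minutes on one CPU core.

## Test

```bash
python -m pytest -q tests/                      # full suite incl. the benchmark (~15 min)
python -m pytest -q tests/ --skip-benchmark     # fast suite (~1 min)
```

`tests/test_acceptance.py` holds the acceptance criteria: metric-oracle
equivalence at 1e-12, DeLong vs a 20,000-resample paired bootstrap, Youden
exhaustive-search equivalence, the end-to-end leakage audit, the calibrated
qualitative findings (diagnostic pretraining helps prognosis; replay prevents
catastrophic forgetting), and byte-level determinism.

## CLI

```bash
dxprog generate --out cohort/ --seed 1                 # synthetic cohort (PNGs + CSVs)
dxprog split --cohort cohort/ --seed 0 --out plan.csv  # patient-level 5-fold plan
dxprog train --cohort cohort/ --splits plan.csv --strategy seq_replay --fold 0 --out models/
dxprog evaluate --predictions preds.csv --cohort cohort/ --out report/
dxprog run --config experiment.yaml                    # full experiment
```

`experiment.yaml` accepts any subset of the dataclass fields in
`dxprog.config` (generator, backbone, train, strategies, seeds, …); defaults
reproduce the frozen calibrated benchmark. `dxprog run` writes, per seed:
the cohort, the split plan, per-strategy training logs, a predictions CSV
(every reported number is traceable to it), the three comparison tables,
DeLong results, subgroup AUROCs and confusion matrices — all under a
config-hash-named directory, byte-reproducibly.

## Layout

```
src/dxprog/
  config.py      experiment/generator/training configuration dataclasses + YAML
  cohorts.py     synthetic cohort generator + closed-form AUROC oracles
  splits.py      patient-level k-fold plan, pretraining holdout, subgroups
  nn/            NumPy CNN, Adam + cosine schedule, batch augmentation
  strategies.py  the six training regimes, replay sampler, data-access audit
  metrics.py     AUROC/AUPRC/balanced accuracy/Youden/DeLong/ensembling
  reports.py     metric reports, comparison tables, forgetting & subgroups
  pipeline.py    end-to-end orchestration, seed derivation, leakage audit
  cli.py         click command group
```
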