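"""Declarative configuration objects for generation, training and experiments.

All configs are plain dataclasses with a ``validate()`` method raising
:class:`~dxprog.exceptions.ConfigError`, plus YAML round-trip helpers so a
single experiment file drives the whole pipeline.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from dxprog.exceptions import ConfigError

#: Grade cutpoints on the standard-normal severity scale giving marginal grade
#: priors (0.35, 0.30, 0.20, 0.12, 0.03) — a rare top grade so that forgetting
#: of rare classes is observable.
DEFAULT_GRADE_CUTPOINTS = (
    -0.3853204664075677,
    0.3853204664075677,
    1.0364333894937898,
    1.8807936081512509,
)

STRATEGY_NAMES = (
    "diagnosis_reference",
    "prognosis_single_task",
    "single_cohort_mt",
    "concurrent_mt",
    "diag_pretrained_mt",
    "seq_replay",
)

CHECKPOINT_CRITERIA = ("val_prognosis_auroc", "val_total_loss", "val_diagnosis_balacc")
AUGMENTATIONS = ("none", "flips+crops+rotations")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    The generative model: patient severity ``s ~ N(0,1)``; progression rate
    ``r = rho*s + sqrt(1-rho^2)*z`` with independent ``z ~ N(0,1)``; ordinal
    grade by thresholding ``s`` at ``grade_cutpoints``; binary progression
    label ``~ Bernoulli(sigmoid(alpha + beta_s*s + beta_r*r))``.
    """

    n_patients: int = 600
    scans_per_patient_range: tuple[int, int] = (2, 2)
    n_grades: int = 5
    grade_cutpoints: tuple[float, ...] = DEFAULT_GRADE_CUTPOINTS
    severity_progression_correlation: float = 0.5  # rho
    progression_intercept: float = -0.9  # alpha
    progression_severity_coef: float = 0.8  # beta_s
    progression_rate_coef: float = 1.2  # beta_r
    horizon_label: str = "4y"
    image_size: int = 64
    gap_width_range: tuple[int, int] = (4, 20)
    lesion_count_rate: float = 8.0
    texture_amplitude_coef: float = 4.0
    pixel_noise_sd: float = 0.08
    prognosis_cohort_fraction: float = 0.2
    #: scale of the non-negative severity drift used to simulate the
    #: follow-up grade from which incidence/progression subgroups derive
    followup_drift_scale: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        lo, hi = self.scans_per_patient_range
        if not (1 <= lo <= hi):
            raise ConfigError("scans_per_patient_range must satisfy 1 <= lo <= hi")
        if self.n_grades < 2:
            raise ConfigError("n_grades must be >= 2")
        cuts = self.grade_cutpoints
        if len(cuts) != self.n_grades - 1:
            raise ConfigError("grade_cutpoints must have length n_grades - 1")
        if any(not math.isfinite(c) for c in cuts):
            raise ConfigError("grade_cutpoints must be finite")
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ConfigError("grade_cutpoints must be strictly increasing")
        rho = self.severity_progression_correlation
        if not math.isfinite(rho) or abs(rho) > 1:
            raise ConfigError("severity_progression_correlation must be finite in [-1, 1]")
        for name in ("progression_intercept", "progression_severity_coef", "progression_rate_coef"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")
        if self.image_size < 32:
            raise ConfigError("image_size must be >= 32")
        glo, ghi = self.gap_width_range
        if not (0 < glo <= ghi):
            raise ConfigError("gap_width_range must satisfy 0 < lo <= hi")
        if ghi >= self.image_size // 2:
            raise ConfigError("gap_width_range too large for image_size")
        if self.pixel_noise_sd < 0:
            raise ConfigError("pixel_noise_sd must be >= 0")
        if not (0 < self.prognosis_cohort_fraction <= 1):
            raise ConfigError("prognosis_cohort_fraction must be in (0, 1]")
        if self.followup_drift_scale < 0:
            raise ConfigError("followup_drift_scale must be >= 0")


@dataclass
class BackboneConfig:
    """Shared-trunk, two-headed convolutional network shape."""

    conv_channels: tuple[int, ...] = (8, 16, 32)
    kernel_size: int = 3
    pooling: str = "avg2"
    embedding_dim: int = 64
    diagnosis_classes: int = 5
    prognosis_outputs: int = 1
    #: images are average-pooled by this factor before the first convolution
    #: (on top of the half-resolution dataset loading)
    input_downsample: int = 2

    def validate(self) -> None:
        if len(self.conv_channels) < 1:
            raise ConfigError("conv_channels must be non-empty")
        if self.kernel_size % 2 != 1:
            raise ConfigError("kernel_size must be odd")
        if self.prognosis_outputs != 1:
            raise ConfigError("prognosis head is a single logit")


@dataclass
class TrainConfig:
    """Optimization protocol shared by all training regimes."""

    lr: float = 3e-3
    betas: tuple[float, float] = (0.9, 0.999)
    lr_min: float = 1e-5
    #: learning-rate multiplier for strategies fine-tuning from
    #: diagnosis-pretrained weights (standard reduced-lr fine-tuning)
    finetune_lr_scale: float = 0.25
    epochs: int = 20
    batch_size: int = 32
    replay_probability: float = 0.5
    weighted_ce: bool = True
    augmentation: str = "flips+crops+rotations"
    checkpoint_criterion: str = "val_prognosis_auroc"
    early_stop_patience: int = 15
    seed: int = 0

    def validate(self) -> None:
        if self.lr <= 0:
            raise ConfigError("lr must be positive")
        if self.finetune_lr_scale <= 0:
            raise ConfigError("finetune_lr_scale must be positive")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if not (0.0 <= self.replay_probability <= 1.0):
            raise ConfigError("replay_probability must be in [0, 1]")
        if self.augmentation not in AUGMENTATIONS:
            raise ConfigError(f"augmentation must be one of {AUGMENTATIONS}")
        if self.checkpoint_criterion not in CHECKPOINT_CRITERIA:
            raise ConfigError(f"checkpoint_criterion must be one of {CHECKPOINT_CRITERIA}")
        if self.early_stop_patience < 1:
            raise ConfigError("early_stop_patience must be >= 1")


@dataclass(frozen=True)
class StrategySpec:
    """Which training regime to run and from which initialization."""

    name: str
    init: str = "random"  # "random" | "diagnosis_pretrained"

    def __post_init__(self) -> None:
        if self.name not in STRATEGY_NAMES:
            raise ConfigError(f"unknown strategy {self.name!r}")
        if self.init not in ("random", "diagnosis_pretrained"):
            raise ConfigError(f"unknown init {self.init!r}")
        if self.name in ("seq_replay", "diag_pretrained_mt") and self.init != "diagnosis_pretrained":
            raise ConfigError(f"{self.name} requires init='diagnosis_pretrained'")
        if self.name in ("concurrent_mt", "single_cohort_mt") and self.init != "random":
            raise ConfigError(f"{self.name} requires init='random'")

    @property
    def key(self) -> str:
        """Unique label used in logs, file names and report columns."""
        if self.name == "prognosis_single_task":
            suffix = "pretrained" if self.init == "diagnosis_pretrained" else "random"
            return f"{self.name}_{suffix}"
        return self.name

    @property
    def needs_pretrained(self) -> bool:
        return self.init == "diagnosis_pretrained"

    @property
    def is_multitask(self) -> bool:
        return self.name in ("single_cohort_mt", "concurrent_mt", "diag_pretrained_mt", "seq_replay")


def default_strategies() -> list[StrategySpec]:
    """The full comparison set: reference, both single-task inits, four MT regimes."""
    return [
        StrategySpec("diagnosis_reference"),
        StrategySpec("prognosis_single_task", init="random"),
        StrategySpec("prognosis_single_task", init="diagnosis_pretrained"),
        StrategySpec("single_cohort_mt"),
        StrategySpec("concurrent_mt"),
        StrategySpec("diag_pretrained_mt", init="diagnosis_pretrained"),
        StrategySpec("seq_replay", init="diagnosis_pretrained"),
    ]


@dataclass
class ExperimentConfig:
    """One reproducible end-to-end experiment (possibly several seed replicates)."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    strategies: list[StrategySpec] = field(default_factory=default_strategies)
    split_seed: int = 0
    n_folds: int = 5
    seeds: list[int] = field(default_factory=lambda: [1, 2, 3])
    output_dir: str = "runs"
    #: optional transfer-style cohort generated from a shifted configuration
    #: and scored by all fold models (probability-averaged)
    external: dict | None = field(
        default_factory=lambda: {
            "n_patients": 150,
            "pixel_noise_sd": 0.08,
            "prognosis_cohort_fraction": 1.0,
        }
    )

    def validate(self) -> None:
        self.generator.validate()
        self.backbone.validate()
        self.train.validate()
        if not self.strategies:
            raise ConfigError("strategies must be non-empty")
        if not self.seeds:
            raise ConfigError("seeds must be non-empty")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if self.backbone.diagnosis_classes != self.generator.n_grades:
            raise ConfigError("backbone.diagnosis_classes must equal generator.n_grades")

    def external_generator(self, seed: int) -> GeneratorConfig | None:
        if self.external is None:
            return None
        cfg = dataclasses.replace(self.generator, **self.external)
        cfg.seed = seed
        return cfg


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------

def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def config_to_dict(cfg) -> dict:
    return _to_plain(cfg)


def _tupled(cls, data: dict):
    kwargs = {}
    hints = {f.name: f for f in dataclasses.fields(cls)}
    for key, value in data.items():
        if key not in hints:
            raise ConfigError(f"unknown {cls.__name__} field {key!r}")
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def experiment_from_dict(data: dict) -> ExperimentConfig:
    data = dict(data)
    cfg = ExperimentConfig(
        generator=_tupled(GeneratorConfig, data.pop("generator", {})),
        backbone=_tupled(BackboneConfig, data.pop("backbone", {})),
        train=_tupled(TrainConfig, data.pop("train", {})),
        strategies=[
            StrategySpec(**s) if isinstance(s, dict) else StrategySpec(s)
            for s in data.pop("strategies", [dataclasses.asdict(s) for s in default_strategies()])
        ],
        **data,
    )
    cfg.validate()
    return cfg


def load_experiment(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return experiment_from_dict(data)


def save_experiment(cfg: ExperimentConfig, path: str | Path) -> None:
    plain = config_to_dict(cfg)
    plain["strategies"] = [
        {"name": s.name, "init": s.init} for s in cfg.strategies
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(plain, fh, sort_keys=True)
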