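"""Synthetic paired diagnosis/prognosis imaging cohorts with a known generative model.

A patient is a pair of correlated standard-normal latents: *severity* ``s``
and *progression rate* ``r`` (correlation ``rho``). The ordinal grade is
``s`` thresholded at fixed cutpoints; the binary progression label is
Bernoulli with logit ``alpha + beta_s*s + beta_r*r``. Images carry three
signals: a bright-band gap whose width decreases with severity
(joint-space-narrowing analog), a Poisson count of bright spots whose rate
increases with severity (osteophyte analog), and band-edge texture whose
amplitude increases with the progression rate — the only image signal that
carries prognostic information beyond severity.

Because the generative model is known, the attainable discrimination of any
estimator can be computed in closed form (:func:`oracle_auroc_closed_form`),
which is used to calibrate configurations into a learnable-but-imperfect
regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from PIL import Image
from scipy import stats

from dxprog.config import GeneratorConfig
from dxprog.exceptions import ConfigError, GenerationError

METADATA_COLUMNS = ["scan_id", "patient_id", "visit_index", "grade", "progression_label", "image_path"]
GROUND_TRUTH_COLUMNS = [
    "patient_id",
    "severity",
    "progression_rate",
    "event_probability",
    "baseline_grade",
    "followup_grade",
    "in_prognosis_cohort",
]

# stream tags for deriving independent per-stage rngs from the one seed
_TAG_LATENTS = 0
_TAG_SCAN_COUNTS = 1
_TAG_PROG_SELECT = 2
_TAG_LABELS = 3
_TAG_IMAGES = 100


class LatentPatient(NamedTuple):
    patient_id: str
    severity: float
    progression_rate: float


@dataclass
class CohortBundle:
    """Generated cohorts: all graded scans, the labeled subset, and ground truth."""

    diagnosis_scans: pd.DataFrame
    prognosis_scans: pd.DataFrame
    patients: pd.DataFrame
    generator_config: GeneratorConfig
    root: Path | None = None

    def __post_init__(self) -> None:
        assert set(self.prognosis_scans["scan_id"]) <= set(self.diagnosis_scans["scan_id"])


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, *tags)))


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# Latents and labels
# ---------------------------------------------------------------------------

def sample_patients(config: GeneratorConfig, rng: np.random.Generator) -> list[LatentPatient]:
    """Draw ``n_patients`` latent pairs (severity, progression_rate) at correlation rho."""
    config.validate()
    n = config.n_patients
    rho = config.severity_progression_correlation
    severity = rng.standard_normal(n)
    z = rng.standard_normal(n)
    rate = rho * severity + math.sqrt(1.0 - rho * rho) * z
    width = max(4, len(str(n - 1)))
    return [
        LatentPatient(f"P{i:0{width}d}", float(severity[i]), float(rate[i]))
        for i in range(n)
    ]


def assign_grade(severity, cutpoints) -> np.ndarray | int:
    """Ordinal grade = number of cutpoints strictly below severity."""
    cuts = np.asarray(cutpoints, dtype=float)
    if np.any(np.diff(cuts) <= 0):
        raise ConfigError("cutpoints must be strictly increasing")
    sev = np.asarray(severity, dtype=float)
    if not np.all(np.isfinite(sev)):
        raise ValueError("severity must be finite")
    grade = np.searchsorted(cuts, sev, side="left")
    return int(grade) if np.isscalar(severity) else grade


def progression_probability(severity, progression_rate, config: GeneratorConfig) -> np.ndarray:
    """Bernoulli event probability sigmoid(alpha + beta_s*s + beta_r*r)."""
    eta = (
        config.progression_intercept
        + config.progression_severity_coef * np.asarray(severity, dtype=float)
        + config.progression_rate_coef * np.asarray(progression_rate, dtype=float)
    )
    return _sigmoid(eta)


def assign_progression(severity, progression_rate, config: GeneratorConfig, rng: np.random.Generator):
    """Binary progression-within-horizon label drawn at the logistic probability."""
    for name in ("progression_intercept", "progression_severity_coef", "progression_rate_coef"):
        if not math.isfinite(getattr(config, name)):
            raise ConfigError(f"{name} must be finite")
    p = progression_probability(severity, progression_rate, config)
    draw = rng.random(np.shape(p)) < p
    if np.isscalar(severity):
        return int(draw)
    return draw.astype(int)


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------

def render_image(
    severity: float,
    progression_rate: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one grayscale image in [0,1] carrying the three generative signals.

    Deterministic given the rng state; the rng consumption order is fixed
    (texture phases, spot count, spot positions, pixel noise) so that
    ablating a signal's coefficient does not shift the other draws.
    """
    size = config.image_size
    if size < 32:
        raise ConfigError("image_size must be >= 32")
    glo, ghi = config.gap_width_range
    if ghi >= size // 2:
        raise ConfigError("gap_width_range does not fit image_size")

    sev_cdf = stats.norm.cdf(severity)
    gap = ghi - (ghi - glo) * sev_cdf  # narrower gap at higher severity
    amplitude = config.texture_amplitude_coef * float(_sigmoid(progression_rate))
    wavelength = size / 3.0
    phase_top, phase_bot = rng.uniform(0.0, 2.0 * np.pi, size=2)
    # per-scan nuisance variation: vertical position and band thickness jitter
    # (severity must be read from the edge-to-edge relation, not absolute rows
    # or brightness profiles)
    center = size / 2.0 + rng.uniform(-size * 0.1, size * 0.1)
    thickness = size * rng.uniform(0.16, 0.22)
    band_level = rng.uniform(0.65, 0.9)  # per-scan contrast jitter
    bg_level = rng.uniform(0.05, 0.18)
    lam_spots = config.lesion_count_rate * float(_sigmoid(severity))
    n_spots = int(rng.poisson(lam_spots))
    spot_xy = rng.uniform(0.0, 1.0, size=(n_spots, 2))
    noise = rng.normal(0.0, 1.0, size=(size, size)) * config.pixel_noise_sd

    y = np.arange(size, dtype=float)[:, None]
    x = np.arange(size, dtype=float)[None, :]
    edge_top = center - gap / 2.0 - amplitude * np.sin(2.0 * np.pi * x / wavelength + phase_top)
    edge_bot = center + gap / 2.0 + amplitude * np.sin(2.0 * np.pi * x / wavelength + phase_bot)

    img = np.full((size, size), bg_level)
    band_top = (y >= edge_top - thickness) & (y <= edge_top)
    band_bot = (y >= edge_bot) & (y <= edge_bot + thickness)
    img[band_top | band_bot] = band_level

    if n_spots:
        # spots sit at the outer band faces, brighter than the band plateau
        for fx, fy in spot_xy:
            cx = fx * (size - 8) + 4
            if fy < 0.5:
                cy = center - gap / 2.0 - thickness * (0.15 + 1.4 * fy)
            else:
                cy = center + gap / 2.0 + thickness * (0.15 + 1.4 * (fy - 0.5))
            mask = (y - cy) ** 2 + (x - cx) ** 2 <= 2.25
            img[mask] = min(band_level + 0.25, 1.0)

    img = img + noise
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def build_cohorts(config: GeneratorConfig, out_dir: str | Path | None = None) -> CohortBundle:
    """Generate the full diagnosis cohort and the labeled prognosis subset.

    All randomness derives from ``config.seed``. If ``out_dir`` is given,
    images are written as 8-bit grayscale PNGs and metadata/ground truth as
    CSVs (byte-stable across reruns with the same config).
    """
    config.validate()
    seed = config.seed
    patients = sample_patients(config, _rng(seed, _TAG_LATENTS))
    n = len(patients)
    max_grade = config.n_grades - 1

    severity = np.array([p.severity for p in patients])
    rate = np.array([p.progression_rate for p in patients])
    grades = assign_grade(severity, config.grade_cutpoints)
    probs = progression_probability(severity, rate, config)
    labels = assign_progression(severity, rate, config, _rng(seed, _TAG_LABELS))

    followup_sev = severity + config.followup_drift_scale * np.log1p(np.exp(rate))
    followup_grades = assign_grade(followup_sev, config.grade_cutpoints)

    lo, hi = config.scans_per_patient_range
    n_scans_per = _rng(seed, _TAG_SCAN_COUNTS).integers(lo, hi + 1, size=n)

    n_prog = max(1, round(config.prognosis_cohort_fraction * n))
    prog_idx = _rng(seed, _TAG_PROG_SELECT).choice(n, size=n_prog, replace=False)
    in_prog = np.zeros(n, dtype=bool)
    in_prog[prog_idx] = True

    rows = []
    scan_counter = 0
    for i, patient in enumerate(patients):
        labeled = in_prog[i] and grades[i] < max_grade  # maximal-grade exclusion
        for visit in range(n_scans_per[i]):
            rows.append(
                {
                    "scan_id": f"S{scan_counter:06d}",
                    "patient_id": patient.patient_id,
                    "visit_index": visit,
                    "grade": int(grades[i]),
                    "progression_label": int(labels[i]) if labeled else pd.NA,
                    "image_path": f"images/S{scan_counter:06d}.png",
                    "_severity": severity[i],
                    "_rate": rate[i],
                }
            )
            scan_counter += 1

    meta = pd.DataFrame(rows)
    meta["progression_label"] = meta["progression_label"].astype("Int64")
    prognosis = meta[meta["progression_label"].notna()]
    if prognosis.empty:
        raise GenerationError(
            "prognosis cohort is empty after maximal-grade exclusion; "
            "increase prognosis_cohort_fraction or lower the top cutpoint"
        )

    ground_truth = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "severity": severity,
            "progression_rate": rate,
            "event_probability": probs,
            "baseline_grade": grades.astype(int),
            "followup_grade": followup_grades.astype(int),
            "in_prognosis_cohort": in_prog.astype(int),
        }
    )

    root = Path(out_dir) if out_dir is not None else None
    if root is not None:
        root.mkdir(parents=True, exist_ok=True)
        (root / "images").mkdir(exist_ok=True)
        for row in rows:
            img = render_image(row["_severity"], row["_rate"], config, _rng(seed, _TAG_IMAGES, int(row["scan_id"][1:])))
            arr = np.round(img * 255.0).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(root / row["image_path"])

    meta = meta[METADATA_COLUMNS]
    prognosis = prognosis[METADATA_COLUMNS]

    if root is not None:
        meta.to_csv(root / "metadata.csv", index=False)
        ground_truth.to_csv(root / "ground_truth.csv", index=False, float_format="%.12g")
        import yaml

        from dxprog.config import config_to_dict

        with open(root / "generator.yaml", "w") as fh:
            yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)

    return CohortBundle(meta, prognosis, ground_truth, config, root)


def load_cohort(root: str | Path) -> CohortBundle:
    """Load a previously generated cohort directory."""
    import yaml

    from dxprog.config import _tupled

    root = Path(root)
    with open(root / "generator.yaml") as fh:
        config = _tupled(GeneratorConfig, yaml.safe_load(fh))
    meta = pd.read_csv(root / "metadata.csv", dtype={"progression_label": "Int64"})
    ground_truth = pd.read_csv(root / "ground_truth.csv")
    prognosis = meta[meta["progression_label"].notna()]
    return CohortBundle(meta, prognosis, ground_truth, config, root)


def load_image_stack(bundle: CohortBundle, downsample: int = 1) -> np.ndarray:
    """Read all cohort images into a float32 stack, optionally average-pooled."""
    if bundle.root is None:
        raise GenerationError("cohort was generated without an output directory; images unavailable")
    imgs = []
    for path in bundle.diagnosis_scans["image_path"]:
        arr = np.asarray(Image.open(bundle.root / path), dtype=np.float32) / 255.0
        if downsample > 1:
            s = arr.shape[0] // downsample
            arr = arr.reshape(s, downsample, s, downsample).mean(axis=(1, 3))
        imgs.append(arr)
    return np.stack(imgs)


# ---------------------------------------------------------------------------
# Closed-form calibration oracles
# ---------------------------------------------------------------------------

def _weighted_auroc(scores: np.ndarray, w_pos: np.ndarray, w_neg: np.ndarray) -> float:
    """AUROC of a discrete weighted score distribution, ties counted 1/2."""
    order = np.argsort(scores, kind="stable")
    s, wp, wn = scores[order], w_pos[order], w_neg[order]
    # group equal scores
    boundary = np.empty(len(s), dtype=bool)
    boundary[0] = True
    boundary[1:] = s[1:] != s[:-1]
    group = np.cumsum(boundary) - 1
    gp = np.bincount(group, weights=wp)
    gn = np.bincount(group, weights=wn)
    cum_neg_below = np.concatenate(([0.0], np.cumsum(gn)[:-1]))
    num = np.sum(gp * (cum_neg_below + 0.5 * gn))
    return float(num / (wp.sum() * wn.sum()))


def _latent_grid(config: GeneratorConfig, n_grid: int = 361, span: float = 6.0):
    s = np.linspace(-span, span, n_grid)
    z = np.linspace(-span, span, n_grid)
    ws = stats.norm.pdf(s)
    wz = stats.norm.pdf(z)
    S, Z = np.meshgrid(s, z, indexing="ij")
    W = np.outer(ws, wz)
    W /= W.sum()
    rho = config.severity_progression_correlation
    R = rho * S + math.sqrt(1.0 - rho * rho) * Z
    p = progression_probability(S, R, config)
    return S, R, W, p


def oracle_auroc_closed_form(config: GeneratorConfig, n_grid: int = 361) -> float:
    """AUROC of the Bayes score eta = alpha + beta_s*s + beta_r*r, by numerical integration."""
    S, R, W, p = _latent_grid(config, n_grid)
    eta = (
        config.progression_intercept
        + config.progression_severity_coef * S
        + config.progression_rate_coef * R
    )
    return _weighted_auroc(eta.ravel(), (W * p).ravel(), (W * (1.0 - p)).ravel())


def oracle_auroc_severity_only(config: GeneratorConfig, n_grid: int = 361) -> float:
    """AUROC of the best severity-only score (monotone in s) for the progression label."""
    rho = config.severity_progression_correlation
    slope = config.progression_severity_coef + config.progression_rate_coef * rho
    S, _, W, p = _latent_grid(config, n_grid)
    score = slope * S  # optimal given s alone: posterior is monotone in slope*s
    return _weighted_auroc(score.ravel(), (W * p).ravel(), (W * (1.0 - p)).ravel())
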