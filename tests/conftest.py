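import dataclasses

import numpy as np
import pytest

from dxprog.config import BackboneConfig, GeneratorConfig, TrainConfig


@pytest.fixture(scope="session")
def tiny_generator() -> GeneratorConfig:
    """Small cohort config used by training-level tests (images rendered)."""
    return GeneratorConfig(
        n_patients=80,
        scans_per_patient_range=(1, 2),
        prognosis_cohort_fraction=0.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort_dir(tmp_path_factory, tiny_generator):
    from dxprog.cohorts import build_cohorts

    out = tmp_path_factory.mktemp("tiny_cohort")
    build_cohorts(tiny_generator, out)
    return out


@pytest.fixture(scope="session")
def tiny_bundle(tiny_cohort_dir):
    from dxprog.cohorts import load_cohort

    return load_cohort(tiny_cohort_dir)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_bundle):
    from dxprog.strategies import dataset_from_bundle

    return dataset_from_bundle(tiny_bundle)


@pytest.fixture()
def quick_train() -> TrainConfig:
    return TrainConfig(epochs=3, batch_size=16, early_stop_patience=5)


@pytest.fixture()
def small_backbone() -> BackboneConfig:
    return BackboneConfig(conv_channels=(4, 8), embedding_dim=16)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)


@pytest.fixture(scope="session")
def latents_only_generator() -> GeneratorConfig:
    """Config for label-distribution tests that never render images."""
    return GeneratorConfig(n_patients=10000, seed=11)


def pytest_addoption(parser):
    parser.addoption(
        "--skip-benchmark",
        action="store_true",
        default=False,
        help="skip the full calibrated benchmark in tests/test_acceptance.py",
    )


def make_generator(**kwargs) -> GeneratorConfig:
    return dataclasses.replace(GeneratorConfig(), **kwargs)
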