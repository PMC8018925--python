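"""Shared fixtures.

The expensive artifacts (a 20-case training cohort, the two trained
detectors) are session-scoped so detector-dependent tests share one
training run.
"""

import numpy as np
import pytest

from autoref import acf
from autoref.phantom import PhantomSpec, generate_cohort, generate_phantom
from autoref.pipeline import prepare_training_cases

TRAIN_COHORT_SEED = 7
HELDOUT_COHORT_SEED = 1007


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def small_spec():
    """A small grid for tests that only need plausible anatomy quickly."""
    return PhantomSpec(shape=(12, 96, 96), spacing=(3.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def phantom_case(default_spec):
    return generate_phantom(default_spec, seed=123)


@pytest.fixture(scope="session")
def train_cases(default_spec):
    """20 preprocessed phantoms with annotation boxes on the 0.5 mm grid."""
    return prepare_training_cases(
        generate_cohort(default_spec, 20, seed=TRAIN_COHORT_SEED))


@pytest.fixture(scope="session")
def heldout_cases(default_spec):
    """10 preprocessed held-out phantoms for detector evaluation."""
    return prepare_training_cases(
        generate_cohort(default_spec, 10, seed=HELDOUT_COHORT_SEED))


@pytest.fixture(scope="session")
def detectors(train_cases):
    return {
        "fat": acf.train_detector(train_cases, "fat", seed=1),
        "muscle": acf.train_detector(train_cases, "muscle", seed=2),
    }


@pytest.fixture(scope="session")
def model_paths(detectors, tmp_path_factory):
    d = tmp_path_factory.mktemp("models")
    paths = {}
    for tissue, model in detectors.items():
        p = d / f"{tissue}.acf"
        model.save(str(p))
        paths[tissue] = str(p)
    return paths


@pytest.fixture
def rng():
    return np.random.default_rng(0)
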