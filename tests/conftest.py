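"""Shared fixtures: tiny cohorts and one fully trained study.

The expensive session fixture (`study`) runs the complete pipeline once —
QC, stratified split, AE pre-training, SOM pre-training with restarts and
joint fine-tuning — on the default synthetic cohort at reduced epoch
counts, and is shared by the evaluation, attribution and acceptance tests.
"""

from pathlib import Path

import numpy as np
import pytest

from dnmap.config import DNMConfig, TrainConfig
from dnmap.synthetic import SynthConfig, generate_cohort, generate_minimal_fixture
from dnmap.workflow import run_dnm_study

DATA_DIR = Path(__file__).parent / "data"

#: seed of the reference synthetic study used across the suite
STUDY_SEED = 1

#: reduced epoch counts used for all trained-model tests
FAST_TRAIN = dict(ae_epochs=300, som_epochs=150, joint_epochs=100)


def fast_config(**overrides) -> DNMConfig:
    train = TrainConfig(**FAST_TRAIN, **overrides.pop("train", {}))
    return DNMConfig(lattice_height=6, lattice_width=6, train=train, **overrides)


@pytest.fixture(scope="session")
def minimal_cohort():
    return generate_minimal_fixture()


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(SynthConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def study(default_cohort):
    raw, truth = default_cohort
    result = run_dnm_study(raw, truth.ontology, fast_config(), seed=STUDY_SEED)
    return result, truth
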