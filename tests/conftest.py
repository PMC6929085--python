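import numpy as np
import pytest

from posefit import data, recognize, synth
from posefit.body import CalibrationSet


@pytest.fixture(scope="session")
def cal() -> CalibrationSet:
    return CalibrationSet.trivial()


@pytest.fixture(scope="session")
def small_spec() -> synth.PerturbationSpec:
    """Generator settings scaled down for fast unit tests."""
    return synth.PerturbationSpec(duration_range=(1.0, 1.5))


@pytest.fixture(scope="session")
def small_db(small_spec):
    return synth.generate_database(3, 4, spec=small_spec, seed=11)


@pytest.fixture(scope="session")
def small_split(small_db):
    return data.split_database(small_db, 0.5, seed=3)


@pytest.fixture(scope="session")
def small_model(small_split, cal):
    train_db, _ = small_split
    return recognize.train_two_stage(train_db, cal)


@pytest.fixture(scope="session")
def templates():
    return synth.make_templates(5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
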