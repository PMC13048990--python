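"""Shared fixtures: small synthetic stacks generated once per session."""

import numpy as np
import pytest

import coccosims as cs
from coccosims import preprocess


@pytest.fixture(scope="session")
def tiny_truth():
    return cs.default_scenario("tiny_clean", seed=11)


@pytest.fixture(scope="session")
def tiny_stack(tiny_truth):
    return cs.generate_stack(tiny_truth)


@pytest.fixture(scope="session")
def clean_truth():
    return cs.default_scenario("clean", seed=21)


@pytest.fixture(scope="session")
def clean_stack(clean_truth):
    return cs.generate_stack(clean_truth)


@pytest.fixture(scope="session")
def salt_truth():
    return cs.default_scenario("salt_speckled", seed=31)


@pytest.fixture(scope="session")
def salt_stack(salt_truth):
    return cs.generate_stack(salt_truth)


@pytest.fixture(scope="session")
def salt_roi(salt_stack):
    return preprocess.segment(preprocess.accumulate(salt_stack))


@pytest.fixture(scope="session")
def tiny_roi(tiny_stack):
    return preprocess.segment(preprocess.accumulate(tiny_stack))


@pytest.fixture(scope="session")
def calibration():
    return cs.default_calibration()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
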