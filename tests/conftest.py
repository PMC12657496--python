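"""Shared fixtures: synthetic cohorts are generated once per session."""

import numpy as np
import pytest

from fhstrat.config import GeneratorConfig
from fhstrat.simulate import generate_cohort
from fhstrat import clustering as cl


@pytest.fixture(scope="session")
def fhsup_cohort():
    """Default 5-profile FHSU-P cohort, n=2000, fixed seed."""
    cfg = GeneratorConfig(n_participants=2000, fhsu_positive_fraction=1.0, seed=1)
    return generate_cohort(cfg, include_mid=False).cohort


@pytest.fixture(scope="session")
def feature_matrix(fhsup_cohort):
    return cl.preprocess_features(fhsup_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
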