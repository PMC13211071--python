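"""Shared fixtures: synthetic sessions and cohorts with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from comfortfuse.pipeline import build_feature_matrix, process_bundle
from comfortfuse.synth import SynthConfig, generate_cohort, generate_session


@pytest.fixture(scope="session")
def default_session():
    """One mixed-state session from the default study conditions."""
    return generate_session(SynthConfig(seed=7), 1)


@pytest.fixture(scope="session")
def cohort():
    """Full 18-session cohort under the default study conditions
    (8 single-class sessions, one session spanning midnight)."""
    return generate_cohort(SynthConfig(seed=3))


@pytest.fixture(scope="session")
def cohort_processed(cohort):
    return [process_bundle(bundle) for bundle, _ in cohort]


@pytest.fixture(scope="session")
def cohort_matrix(cohort_processed):
    """Normalised 55-feature matrix for the default cohort."""
    return build_feature_matrix(cohort_processed)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
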