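"""Shared fixtures: a mid-size simulated cohort reused by the slower
integration tests, and derandomized hypothesis settings."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from connrel.cohort import SESSIONS
from connrel.connectome import build_edge_panel, correlation_matrix
from connrel.preprocess import preprocess_session
from connrel.synthetic import CohortSpec, generate_timeseries_cohort

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

COHORT_SEED = 11


def panels_for(cohort, gsr: bool):
    """Preprocess a cohort and return the (session1, session2) edge panels."""
    matrices = {s: [] for s in SESSIONS}
    for subject in cohort.subjects:
        for session in SESSIONS:
            ts = preprocess_session(subject.sessions[session], gsr=gsr)
            matrices[session].append(
                correlation_matrix(ts, subject.subject_id, session)
            )
    return build_edge_panel(matrices[1]), build_edge_panel(matrices[2])


@pytest.fixture(scope="session")
def cohort100():
    """100 default-parameter subjects: the study-scale synthetic cohort."""
    return generate_timeseries_cohort(CohortSpec(n_subjects=100, seed=COHORT_SEED))


@pytest.fixture(scope="session")
def panels100(cohort100):
    """Edge panels of the study-scale cohort, keyed by GSR mode."""
    return {gsr: panels_for(cohort100, gsr) for gsr in (False, True)}


@pytest.fixture()
def rng():
    return np.random.default_rng(20250925)
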