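"""Shared fixtures: small synthetic cohorts and derived decompositions.

Session-scoped so the pooled matrix, basis and scores are computed once and
reused across test modules.
"""

import numpy as np
import pytest

import pmgait


@pytest.fixture(scope="session")
def cohort_spec():
    return pmgait.SyntheticCohortSpec(
        n_subjects=4, duration_s=10.0, noise_sd_mm=0.5, seed=7,
    )


@pytest.fixture(scope="session")
def cohort(cohort_spec):
    return pmgait.generate_cohort(cohort_spec)


@pytest.fixture(scope="session")
def pooled(cohort):
    return pmgait.pool([pmgait.preprocess_trial(t) for t in cohort])


@pytest.fixture(scope="session")
def basis(pooled):
    return pmgait.fit_basis(pooled)


@pytest.fixture(scope="session")
def scores(basis, pooled):
    return [pmgait.principal_accelerations(s)
            for s in pmgait.project_pooled(basis, pooled)]


@pytest.fixture(scope="session")
def lorenz_60s():
    """60 s of Lorenz x at 150 Hz, doubled time axis; no oracle run."""
    series, ref = pmgait.lorenz_trajectory(
        duration_s=60.0, fs_hz=150.0, seed=3, timescale=2.0,
        compute_oracle=False,
    )
    return series, ref


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
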