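"""Shared fixtures: simulated phantom studies at two scales.

The session-scoped ten-subject cohort is simulated and preprocessed once
and shared by the segmentation, robustness, and acceptance tests; smaller
per-module fixtures keep unit tests fast.
"""

from __future__ import annotations

import pytest

from stxseg.phantom import make_cohort, make_phantom, simulate_study
from stxseg.preprocess import preprocess_study
from stxseg.segmentation import segment_cohort

COHORT_SEED = 7
COHORT_N = 10


@pytest.fixture(scope="session")
def cohort10():
    """Ten-subject phantom cohort at default generator settings,
    simulated and preprocessed: ``(truths, studies)``."""
    truths = make_cohort(COHORT_N, seed=COHORT_SEED)
    studies = [preprocess_study(simulate_study(t)) for t in truths]
    return truths, studies


@pytest.fixture(scope="session")
def cohort_segmentation(cohort10):
    """Whole-cohort segmentation with the optimized protocol (3 ICs)."""
    _truths, studies = cohort10
    return segment_cohort(studies, "t1t2_high_b1", k_ics=3, k_clusters=5, seed=0)


@pytest.fixture(scope="session")
def phantom_small():
    """One 32x32 phantom truth (default corruption settings)."""
    return make_phantom(shape=(32, 32), seed=3)


@pytest.fixture(scope="session")
def study_small(phantom_small):
    """Fully corrupted simulated study for the small phantom."""
    return simulate_study(phantom_small)


@pytest.fixture(scope="session")
def study_small_clean(phantom_small):
    """Noise-, drift-, and B0-free simulation of the small phantom."""
    return simulate_study(phantom_small, apply_b0=False, apply_drift=False,
                          apply_noise=False)
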