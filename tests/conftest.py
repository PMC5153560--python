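import numpy as np
import pytest

from striatex import (
    ClinicalRecord,
    PhantomParams,
    Volume,
    clinical_frame,
    extract_features,
    make_masks,
    simulate_cohort,
)


def make_record(severity, subject_id="X01", group=None, side="L"):
    """A minimal valid clinical record for a given latent severity."""
    if group is None:
        group = "PD" if severity > 0 else "HC"
    return ClinicalRecord(
        subject_id=subject_id,
        group=group,
        updrs3=5.0 + 45.0 * severity,
        dd_diag_months=60.0 * severity,
        dd_sympt_months=60.0 * severity + 12.0,
        moca=28.0 - 6.0 * severity,
        age=61.0,
        latent_severity=severity,
        more_affected_side=side,
    )


@pytest.fixture(scope="session")
def default_params():
    return PhantomParams(seed=7)


@pytest.fixture(scope="session")
def default_masks(default_params):
    return make_masks(default_params)


@pytest.fixture(scope="session")
def small_params():
    """A smaller grid that still holds every region; fast to simulate."""
    return PhantomParams(grid_shape=(48, 48, 32), seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(small_params):
    """6 PD + 4 HC on the small grid, with features and clinical table."""
    cohort = simulate_cohort(small_params, n_pd=6, n_hc=4)
    features = extract_features(
        cohort.volumes, cohort.masks, [r.subject_id for r in cohort.records]
    )
    return cohort, features, clinical_frame(cohort.records)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def constant_volume():
    return Volume(np.full((8, 8, 8), 7.0), np.diag([2.0, 2.0, 2.0, 1.0]))
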