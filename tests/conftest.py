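import warnings

import pytest
from hypothesis import HealthCheck, settings

from mpras import (
    CohortParams,
    EyeMeasurements,
    GapWarning,
    PatientRecord,
    simulate_cohort,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_gap_warnings():
    """Gap-band warnings are expected on random lag values; keep tests quiet."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", GapWarning)
        yield


@pytest.fixture
def full_record():
    """A hand-built patient with every measurement present (both eyes)."""
    eye = EyeMeasurements(
        ser_d=-4.25,
        ser_change_d_per_yr=-0.60,
        al_change_mm_per_yr=0.12,
        rpr_nasal_d=0.30,
        rpr_temporal_d=-0.10,
        near_phoria_pd=3.0,
        accom_error_d=0.80,
    )
    return PatientRecord(
        patient_id="P001",
        age_at_presentation_yr=12.0,
        age_of_onset_yr=8.0,
        myopic_parents=1,
        outdoors_h_per_day=1.5,
        nearwork_h_per_day=8.0,
        right_eye=eye,
        left_eye=eye,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-patient synthetic cohort at shipped defaults (fixed seed)."""
    return simulate_cohort(CohortParams(n=300, seed=42))
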