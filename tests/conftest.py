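import numpy as np
import pytest

from tacdose.data import LabSeries, PatientRecord, StaticCovariates
from tacdose.pk_core import DoseEvent, TroughObservation
from tacdose.synthdata import CohortConfig, simulate_cohort


def make_static(**overrides) -> StaticCovariates:
    base = dict(
        age=52.0, sex="M", race="Caucasian", height_cm=172.0, weight_kg=87.0,
        bmi=29.4, bsa=2.03, smoking=0, alcohol=0, cyp3a_inhibitor=0,
        cyp3a_inducer=0,
    )
    base.update(overrides)
    return StaticCovariates(**base)


def make_labs(window_hours: float = 168.0) -> dict[str, LabSeries]:
    times = np.arange(0.0, window_hours + 1, 24.0)
    base = {"hematocrit": 28.0, "albumin": 3.5, "alt": 30.0, "ast": 32.0,
            "creatinine": 3.5}
    return {
        a: LabSeries(a, times.copy(), np.full(times.size, v))
        for a, v in base.items()
    }


def make_patient(
    pid="P1",
    dose_mg=6.0,
    trough_times=(23.9, 47.9),
    trough_concs=(8.0, 10.0),
) -> PatientRecord:
    doses = [DoseEvent(t, dose_mg) for t in np.arange(0.0, 168.0, 12.0)]
    troughs = [
        TroughObservation(t, c) for t, c in zip(trough_times, trough_concs)
    ]
    return PatientRecord(pid, doses, troughs, make_labs(), make_static())


@pytest.fixture(scope="session")
def small_cohort():
    """60 virtual patients with ground truth; session-scoped for speed."""
    return simulate_cohort(CohortConfig(n_patients=60, seed=7))


@pytest.fixture(scope="session")
def recovery_cohort():
    """The 500-patient recovery-experiment cohort (seed 42, 15% error)."""
    return simulate_cohort(CohortConfig(n_patients=500, seed=42, prop_error_sd=0.15))
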