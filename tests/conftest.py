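import numpy as np
import pytest

from vitalrep import GeneratorConfig, PatientRecord, VitalSeries, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Small labelled synthetic cohort shared by fast tests."""
    return simulate_cohort(GeneratorConfig(n_pos=6, n_neg=12, seed=11))


@pytest.fixture(scope="session")
def default_cohort():
    """The default-design cohort (84 positive, 168 negative), effect 1."""
    return simulate_cohort(GeneratorConfig(seed=7))


def make_record(values_by_indicator, label=0, patient_id="P0", dt=60.0):
    """Build a PatientRecord from plain value lists on a regular grid."""
    series = {}
    for ind, values in values_by_indicator.items():
        times = np.arange(len(values), dtype=float) * dt
        series[ind] = VitalSeries(ind, times, np.asarray(values, dtype=float))
    return PatientRecord(patient_id, label, series)


@pytest.fixture
def complete_record():
    """A handmade complete record with mild variation on every channel."""
    rng = np.random.default_rng(5)
    n = 30
    vals = {
        "hr": 75 + rng.normal(0, 5, n),
        "nisysbp": 120 + rng.normal(0, 8, n),
        "nidiasbp": 70 + rng.normal(0, 5, n),
        "spo2": np.clip(98 + rng.normal(0, 0.8, n), 0, 100),
    }
    vals["pp"] = vals["nisysbp"] - vals["nidiasbp"]
    return make_record(vals)
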