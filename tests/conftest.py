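import pytest

from steptrack.cohort import Cohort, PatientMeta, StepSeries


@pytest.fixture
def make_meta():
    def _make(pid, ecog=0, age=58.0, sex="M", chemo_type="metastatic"):
        return PatientMeta(
            patient_id=pid, ecog=ecog, age=age, sex=sex, chemo_type=chemo_type
        )

    return _make


@pytest.fixture
def make_series():
    def _make(pid, records):
        return StepSeries(patient_id=pid, records=dict(records))

    return _make


@pytest.fixture
def make_cohort(make_meta, make_series):
    """Build a cohort from {pid: (records, meta_overrides)} or {pid: records}."""

    def _make(spec, msas_pre=None, msas_post=None):
        patients, series = [], []
        for pid, value in spec.items():
            if isinstance(value, tuple):
                records, overrides = value
            else:
                records, overrides = value, {}
            patients.append(make_meta(pid, **overrides))
            series.append(make_series(pid, records))
        return Cohort(
            patients=patients,
            steps=series,
            msas_pre=msas_pre or {},
            msas_post=msas_post or {},
        )

    return _make


def all_full_records(days, steps=5000):
    return {d: steps for d in days}


@pytest.fixture
def adequate_records():
    """A wear log passing the inclusion rule in both phases."""
    records = {d: 5000 for d in range(-7, 0)}
    records.update({d: 6000 for d in range(1, 15)})
    return records
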