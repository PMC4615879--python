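import warnings

import pytest

from gdft_impact import (EffectSize, PatientRecord, StudyFrame, default_spec,
                         generate_cohort)


@pytest.fixture
def study_frame():
    """Aggregate frame of the studied cohort: 204,680 patients, 76,807 with
    complications, $11,824 mean excess cost, 2.5-year window."""
    return StudyFrame(n_total=204_680, n_complications=76_807,
                      cost_diff=11_824, period_years=2.5)


@pytest.fixture
def effect():
    return EffectSize()  # OR 0.71-0.83, count scaling


@pytest.fixture(scope="session")
def small_cohort():
    """Synthetic cohort at 2% scale (~4k records), fixed seed."""
    return generate_cohort(default_spec(seed=11), scale=0.02)


@pytest.fixture(scope="session")
def medium_cohort():
    """Synthetic cohort at 30% scale (~61k records), fixed seed."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(default_spec(seed=5), scale=0.30)


def make_record(**kwargs) -> PatientRecord:
    base = dict(patient_id="p0", procedure="colectomy", age=60.0,
                gender="female", elective=True, cci=1, complication=False,
                cost=10_000.0, cost_valid=True, los=4, readmit_30d=False)
    base.update(kwargs)
    return PatientRecord(**base)


@pytest.fixture
def record_factory():
    return make_record
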