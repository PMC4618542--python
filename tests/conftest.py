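from __future__ import annotations

import pytest

from mrruf.records import AdmissionRecord, Cohort


def rec(
    inst="A",
    year=2005,
    age=0,
    los=10,
    charges=100_000.0,
    died=False,
) -> AdmissionRecord:
    return AdmissionRecord(
        institution_id=inst,
        year=year,
        age_years=age,
        los_days=los,
        billed_charges=charges,
        died=died,
    )


@pytest.fixture
def tiny_cohort() -> Cohort:
    """Three admissions: one survivor (LOS 10), two deaths (LOS 5 each)."""
    return Cohort.from_records(
        [
            rec(los=10, charges=200_000.0, died=False),
            rec(los=5, charges=50_000.0, died=True),
            rec(los=5, charges=150_000.0, died=True),
        ]
    )


@pytest.fixture
def two_hospital_cohort() -> Cohort:
    """Hospital A: 10 admissions, 1 death; hospital B: 30 admissions, 3 deaths."""
    records = [rec(inst="A", died=(i == 0)) for i in range(10)]
    records += [rec(inst="B", died=(i < 3)) for i in range(30)]
    return Cohort.from_records(records)
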