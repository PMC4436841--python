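from datetime import date, time, timedelta

import pytest

from orplan import (
    CaseProfile,
    MasterSchedule,
    ORBlock,
    Patient,
    Session,
    default_parameters,
    default_template,
    default_urg_table,
    expand_template,
)

REFERENCE = date(2012, 6, 18)  # a Monday
TARGET_MONDAY = date(2012, 7, 23)  # five weeks later


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def urg_table():
    return default_urg_table()


@pytest.fixture(scope="session")
def default_week():
    """Default MSS template expanded over the target week (30 blocks)."""
    return expand_template(default_template(), TARGET_MONDAY, 1)


def make_patient(
    pid: str,
    specialty: str = "Urology",
    urg: str = "B",
    registered: date = REFERENCE,
    eot: float = 60,
    anesthesia: str = "A",
    **case_kwargs,
) -> Patient:
    return Patient(
        id=pid,
        specialty=specialty,
        urg=urg,
        registration_date=registered,
        case=CaseProfile(eot_min=eot, anesthesia=anesthesia, **case_kwargs),
    )


def make_week(block_specs, monday: date = TARGET_MONDAY) -> MasterSchedule:
    """Small custom MSS: block_specs is a list of (specialty, duration_min)
    laid out one per (day, session) slot from Monday morning on."""
    blocks = []
    slots = [
        (d, s)
        for d in range(5)
        for s in (Session.MORNING, Session.AFTERNOON)
    ]
    for i, (specialty, duration) in enumerate(block_specs):
        day, session = slots[i]
        blocks.append(
            ORBlock(
                room="OR1",
                date=monday + timedelta(days=day),
                session=session,
                start_time=time(8, 0) if session is Session.MORNING else time(14, 0),
                duration_min=duration,
                specialty=specialty,
            )
        )
    specialties = sorted({s for s, _ in block_specs})
    return MasterSchedule(blocks=blocks, specialty_list=specialties)
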