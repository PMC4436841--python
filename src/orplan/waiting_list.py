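"""Waiting-list representation and need-adjusted waiting cost.

Patients awaiting elective surgery are classified into five Urgency Related
Groups (URG): AA, A, B, C, D, in decreasing clinical priority. Each class
carries a maximum acceptable wait and an urgency coefficient; the cost of a
patient's wait is expressed in Need Adjusted Waiting Days (NAWD):

    NAWD(patient, t) = urgency_coefficient * elapsed waiting days at t

NAWD is the objective currency of the block-assignment optimization.
"""
from __future__ import annotations

import csv
from datetime import date
from enum import Enum
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .pathway import AnesthesiaCode, CaseProfile, Destination


class URGCode(str, Enum):
    AA = "AA"
    A = "A"
    B = "B"
    C = "C"
    D = "D"


#: decreasing clinical priority
URG_ORDER: tuple[URGCode, ...] = (
    URGCode.AA,
    URGCode.A,
    URGCode.B,
    URGCode.C,
    URGCode.D,
)


class URGClass(BaseModel):
    model_config = ConfigDict(frozen=True)

    code: URGCode
    max_wait_days: int = Field(gt=0)
    urgency_coefficient: float = Field(gt=0)


class URGTable(BaseModel):
    """The five URG classes; coefficients strictly decrease and maximum
    waits strictly increase from AA down to D."""

    model_config = ConfigDict(frozen=True)

    classes: dict[URGCode, URGClass]

    @model_validator(mode="after")
    def _check_order(self) -> "URGTable":
        missing = [c.value for c in URG_ORDER if c not in self.classes]
        if missing:
            raise ValueError(f"missing URG classes: {missing}")
        coeffs = [self.classes[c].urgency_coefficient for c in URG_ORDER]
        waits = [self.classes[c].max_wait_days for c in URG_ORDER]
        if not all(a > b for a, b in zip(coeffs, coeffs[1:])):
            raise ValueError("urgency coefficients must strictly decrease AA > A > B > C > D")
        if not all(a < b for a, b in zip(waits, waits[1:])):
            raise ValueError("maximum waits must strictly increase from AA to D")
        return self

    def coefficient(self, code: URGCode) -> float:
        return self.classes[code].urgency_coefficient

    def max_wait(self, code: URGCode) -> int:
        return self.classes[code].max_wait_days


@lru_cache(maxsize=1)
def default_urg_table() -> URGTable:
    rows = yaml.safe_load(
        resources.files("orplan.data").joinpath("urg_defaults.yaml").read_text()
    )
    return URGTable(
        classes={URGCode(r["code"]): URGClass(**r) for r in rows}
    )


class Patient(BaseModel):
    model_config = ConfigDict(frozen=True)

    id: str
    specialty: str
    urg: URGCode
    registration_date: date
    case: CaseProfile


class WaitingList(BaseModel):
    patients: list[Patient]
    reference_date: date

    @model_validator(mode="after")
    def _check(self) -> "WaitingList":
        ids = [p.id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient ids: {dupes[:5]}")
        late = [p.id for p in self.patients if p.registration_date > self.reference_date]
        if late:
            raise ValueError(
                f"patients registered after the reference date: {late[:5]}"
            )
        return self

    def __len__(self) -> int:
        return len(self.patients)


class InvalidDateError(ValueError):
    pass


def nawd(patient: Patient, at_date: date, urg_table: URGTable | None = None) -> float:
    """Need Adjusted Waiting Days of a patient at a given date."""
    urg_table = urg_table or default_urg_table()
    elapsed = (at_date - patient.registration_date).days
    if elapsed < 0:
        raise InvalidDateError(
            f"{at_date} precedes registration date {patient.registration_date} "
            f"of patient {patient.id}"
        )
    return urg_table.coefficient(patient.urg) * elapsed


def eligible(
    waiting_list: WaitingList | Sequence[Patient], phase_urgs: Iterable[URGCode]
) -> list[Patient]:
    """Patients whose URG class is admitted in a planning phase.

    Order-stable by (class priority, registration date, id).
    """
    patients = (
        waiting_list.patients
        if isinstance(waiting_list, WaitingList)
        else list(waiting_list)
    )
    urgs = {URGCode(u) for u in phase_urgs}
    rank = {c: i for i, c in enumerate(URG_ORDER)}
    chosen = [p for p in patients if p.urg in urgs]
    chosen.sort(key=lambda p: (rank[p.urg], p.registration_date, p.id))
    return chosen


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

CSV_COLUMNS = (
    "patient_id",
    "specialty",
    "urg",
    "registration_date",
    "eot_min",
    "anesthesia",
    "risks",
    "same_building",
    "use_prep_room",
    "destination",
)

_BOOL = {"true": True, "false": False, "1": True, "0": False}


class WaitingListFormatError(ValueError):
    pass


def _parse_row(row: dict[str, str], lineno: int) -> Patient:
    def fail(msg: str):
        raise WaitingListFormatError(f"line {lineno}: {msg}")

    try:
        risks = frozenset(
            r.strip() for r in row["risks"].split(";") if r.strip()
        )
        same_building = _BOOL.get(row["same_building"].strip().lower())
        use_prep = _BOOL.get(row["use_prep_room"].strip().lower())
        if same_building is None or use_prep is None:
            fail("same_building / use_prep_room must be true or false")
        case = CaseProfile(
            eot_min=float(row["eot_min"]),
            anesthesia=AnesthesiaCode(row["anesthesia"].strip()),
            risks=risks,
            same_building=same_building,
            use_prep_room=use_prep,
            destination=Destination(row["destination"].strip()),
        )
        return Patient(
            id=row["patient_id"].strip(),
            specialty=row["specialty"].strip(),
            urg=URGCode(row["urg"].strip()),
            registration_date=date.fromisoformat(row["registration_date"].strip()),
            case=case,
        )
    except WaitingListFormatError:
        raise
    except (ValueError, KeyError) as exc:
        fail(str(exc))


def read_waiting_list_csv(path, reference_date: date | None = None) -> WaitingList:
    """Read the waiting-list CSV dialect with strict schema validation.

    ``reference_date`` defaults to the latest registration date present.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != CSV_COLUMNS:
            raise WaitingListFormatError(
                f"header must be {','.join(CSV_COLUMNS)}, got "
                f"{','.join(reader.fieldnames or [])}"
            )
        patients = [_parse_row(row, i) for i, row in enumerate(reader, start=2)]
    if reference_date is None:
        if not patients:
            raise WaitingListFormatError("empty waiting list and no reference date")
        reference_date = max(p.registration_date for p in patients)
    return WaitingList(patients=patients, reference_date=reference_date)


def write_waiting_list_csv(waiting_list: WaitingList | Sequence[Patient], path) -> None:
    patients = (
        waiting_list.patients
        if isinstance(waiting_list, WaitingList)
        else list(waiting_list)
    )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for p in patients:
            writer.writerow(
                [
                    p.id,
                    p.specialty,
                    p.urg.value,
                    p.registration_date.isoformat(),
                    p.case.eot_min,
                    p.case.anesthesia.value,
                    ";".join(sorted(p.case.risks)),
                    str(p.case.same_building).lower(),
                    str(p.case.use_prep_room).lower(),
                    p.case.destination.value,
                ]
            )
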