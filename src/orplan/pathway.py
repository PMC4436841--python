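"""Parameterized surgical-pathway duration model.

A patient's journey from ward to ward is decomposed into a fixed sequence of
tasks (transport, entry into the operating sector, optional preparation room,
theatre entry, anesthesia induction, the surgical act itself, emergence,
theatre exit, recovery or intensive care, transport back). Each task carries
a parameterized execution time; the anesthesia type (A-D) and a set of
patient risk flags modulate the induction, operating and awakening phases.

From these parameters the module computes three quantities for any case:

* the three risk-adjusted phase times (induction / operating / awakening),
* the **OR occupation time** — the full interval the case holds the theatre,
  including entry, exit and the post-case cleaning charged to the block,
* the **total pathway time** — the patient's ward-to-ward elapsed time
  (cleaning excluded: the patient has already left the theatre).

All durations are minutes; fractional minutes from percentage adjustments
are kept exact.
"""
from __future__ import annotations

import math
from enum import Enum
from functools import lru_cache
from importlib import resources
from typing import Literal, NamedTuple, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class ConfigurationError(ValueError):
    """A parameter table or case profile is inconsistent with the model."""


class AnesthesiaCode(str, Enum):
    A = "A"  # no intubation
    B = "B"  # general anesthesia with intubation
    C = "C"  # B + one procedure
    D = "D"  # B + more than one procedure


class PrepRoomUse(str, Enum):
    NEVER = "never"
    OPTIONAL = "optional"


class Destination(str, Enum):
    WARD = "ward"
    RECOVERY = "recovery_room"
    ICU = "intensive_care"


#: Risk flags with a printed incidence on induction/operating/awakening time.
RISK_NAMES = (
    "Premature",
    "Baby",
    "HeartDisease",
    "Coagulopathy",
    "PsychoMotorPathology",
    "Allergies",
    "ParticularSyndromes",
    "NeuromuscularPathology",
)


class AnesthesiaProfile(BaseModel):
    """Timing and staffing parameters attached to one anesthesia type."""

    model_config = ConfigDict(frozen=True)

    code: AnesthesiaCode
    intubation: bool
    uses_prep_room: PrepRoomUse
    induction_staff: int = Field(ge=1)
    operating_staff: int = Field(ge=1)
    recovery_staff: int = Field(ge=1)
    anesthesia_task_min: float = Field(gt=0)
    end_anesthesia_task_min: float = Field(gt=0)
    prep_room_task_min: Optional[float] = Field(default=None, gt=0)
    prep_cleaning_min: float = Field(gt=0)
    #: combined induction time as printed alongside the staffing head counts;
    #: kept for reference, the task-level decomposition above is canonical.
    reference_induction_min: float = Field(gt=0)

    @model_validator(mode="after")
    def _check_consistency(self) -> "AnesthesiaProfile":
        if self.code is AnesthesiaCode.A and self.intubation:
            raise ValueError("anesthesia type A never intubates")
        if self.code is not AnesthesiaCode.A and not self.intubation:
            raise ValueError(f"anesthesia type {self.code.value} requires intubation")
        expected_prep = (
            PrepRoomUse.OPTIONAL
            if self.code in (AnesthesiaCode.C, AnesthesiaCode.D)
            else PrepRoomUse.NEVER
        )
        if self.uses_prep_room is not expected_prep:
            raise ValueError(
                f"anesthesia type {self.code.value}: preparation-room use must be "
                f"{expected_prep.value}"
            )
        return self


class RiskFactor(BaseModel):
    """Percentage incidence of one risk flag on the three case phases."""

    model_config = ConfigDict(frozen=True)

    name: str
    induction_pct: float = Field(ge=0)
    operating_pct: float = Field(ge=0)
    awakening_pct: float = Field(ge=0)


class TaskTimingTable(BaseModel):
    """Fixed execution times (minutes) of the ancillary pathway tasks."""

    model_config = ConfigDict(frozen=True)

    transport_same_building_min: float = Field(default=10, gt=0)
    transport_diff_building_min: float = Field(default=20, gt=0)
    enter_sector_min: float = Field(default=10, gt=0)
    enter_theatre_min: float = Field(default=10, gt=0)
    exit_to_icu_min: float = Field(default=10, gt=0)
    exit_to_recovery_min: float = Field(default=5, gt=0)
    recovery_stay_min: float = Field(default=30, gt=0)
    transport_icu_min: float = Field(default=10, gt=0)
    transport_ward_same_min: float = Field(default=10, gt=0)
    transport_ward_diff_min: float = Field(default=20, gt=0)
    #: exit time for a direct-to-ward discharge; defaults to the
    #: recovery-room exit value when unset.
    exit_to_ward_min: Optional[float] = Field(default=None, gt=0)

    @property
    def ward_exit_min(self) -> float:
        return (
            self.exit_to_ward_min
            if self.exit_to_ward_min is not None
            else self.exit_to_recovery_min
        )


class CaseProfile(BaseModel):
    """One patient's surgical characteristics, from which durations derive.

    ``eot_min`` is the Expected Operating Time declared by the surgeon for
    the surgical act alone. ``eot_is_risk_adjusted`` declares that the
    surgeon's EOT already accounts for the patient's risks, in which case
    the operating-time incidences are not applied again.
    """

    model_config = ConfigDict(frozen=True)

    eot_min: float = Field(gt=0)
    anesthesia: AnesthesiaCode
    risks: frozenset[str] = frozenset()
    same_building: bool = True
    use_prep_room: bool = False
    destination: Destination = Destination.RECOVERY
    eot_is_risk_adjusted: bool = False

    @model_validator(mode="after")
    def _check_prep_room(self) -> "CaseProfile":
        if self.use_prep_room and self.anesthesia not in (
            AnesthesiaCode.C,
            AnesthesiaCode.D,
        ):
            raise ValueError(
                "the preparation room is only used with anesthesia types C and D"
            )
        return self


class PathwayParameters(BaseModel):
    """Complete parameter set: anesthesia profiles, risk table, task timings."""

    model_config = ConfigDict(frozen=True)

    anesthesia: dict[AnesthesiaCode, AnesthesiaProfile]
    risks: dict[str, RiskFactor]
    timings: TaskTimingTable = TaskTimingTable()
    risk_strategy: Literal["additive", "multiplicative"] = "additive"

    @model_validator(mode="after")
    def _check_complete(self) -> "PathwayParameters":
        missing = [c.value for c in AnesthesiaCode if c not in self.anesthesia]
        if missing:
            raise ValueError(f"missing anesthesia profiles: {missing}")
        for code, prof in self.anesthesia.items():
            if prof.code is not code:
                raise ValueError(f"profile keyed {code.value} has code {prof.code.value}")
        return self

    @classmethod
    def from_dict(cls, raw: dict) -> "PathwayParameters":
        anesthesia = {
            AnesthesiaCode(code): AnesthesiaProfile(code=AnesthesiaCode(code), **fields)
            for code, fields in raw["anesthesia"].items()
        }
        risks = {
            name: RiskFactor(name=name, **fields)
            for name, fields in raw["risks"].items()
        }
        timings = TaskTimingTable(**raw.get("task_timings", {}))
        return cls(
            anesthesia=anesthesia,
            risks=risks,
            timings=timings,
            risk_strategy=raw.get("risk_strategy", "additive"),
        )

    @classmethod
    def from_yaml(cls, path) -> "PathwayParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@lru_cache(maxsize=1)
def default_parameters() -> PathwayParameters:
    """The parameter set shipped with the package."""
    raw = yaml.safe_load(
        resources.files("orplan.data").joinpath("pathway_defaults.yaml").read_text()
    )
    return PathwayParameters.from_dict(raw)


class PhaseTimes(NamedTuple):
    induction: float
    operating: float
    awakening: float


def _multiplier(pcts: list[float], strategy: str) -> float:
    if strategy == "multiplicative":
        return math.prod(1 + p / 100 for p in pcts)
    return 1 + sum(pcts) / 100


def adjusted_phase_times(
    case: CaseProfile, params: PathwayParameters | None = None
) -> PhaseTimes:
    """Risk-adjusted induction, operating and awakening times for a case.

    Each phase time is its base (anesthesia task, declared EOT, end-anesthesia
    task) scaled by the combined incidence of the case's risks on that phase.
    Risks combine additively by default: ``base * (1 + sum(pct)/100)``.
    """
    params = params or default_parameters()
    prof = params.anesthesia[case.anesthesia]
    factors = []
    for name in sorted(case.risks):
        try:
            factors.append(params.risks[name])
        except KeyError:
            raise ConfigurationError(
                f"risk {name!r} not present in the risk table"
            ) from None
    induction = prof.anesthesia_task_min * _multiplier(
        [f.induction_pct for f in factors], params.risk_strategy
    )
    if case.eot_is_risk_adjusted:
        operating = case.eot_min
    else:
        operating = case.eot_min * _multiplier(
            [f.operating_pct for f in factors], params.risk_strategy
        )
    awakening = prof.end_anesthesia_task_min * _multiplier(
        [f.awakening_pct for f in factors], params.risk_strategy
    )
    return PhaseTimes(induction, operating, awakening)


def _exit_time(case: CaseProfile, params: PathwayParameters) -> float:
    t = params.timings
    if case.destination is Destination.ICU:
        return t.exit_to_icu_min
    if case.destination is Destination.RECOVERY:
        return t.exit_to_recovery_min
    return t.ward_exit_min


def or_occupation_time(
    case: CaseProfile, params: PathwayParameters | None = None
) -> float:
    """Minutes the case holds the operating theatre, cleaning included.

    Theatre entry + adjusted induction + adjusted operating + adjusted
    awakening + exit (to ICU or recovery room per destination) + the
    anesthesia-type-specific preparation-and-cleaning time charged to the
    block after the patient leaves.
    """
    params = params or default_parameters()
    prof = params.anesthesia[case.anesthesia]
    phases = adjusted_phase_times(case, params)
    return (
        params.timings.enter_theatre_min
        + sum(phases)
        + _exit_time(case, params)
        + prof.prep_cleaning_min
    )


def pathway_tasks(
    case: CaseProfile, params: PathwayParameters | None = None
) -> dict[str, float]:
    """Ordered per-task minutes of the patient's ward-to-ward pathway.

    Cleaning is excluded — it belongs to block occupancy, not to the
    patient's elapsed time.
    """
    params = params or default_parameters()
    t = params.timings
    prof = params.anesthesia[case.anesthesia]
    phases = adjusted_phase_times(case, params)
    tasks: dict[str, float] = {}
    tasks["transport_in"] = (
        t.transport_same_building_min if case.same_building else t.transport_diff_building_min
    )
    tasks["enter_sector"] = t.enter_sector_min
    if case.use_prep_room:
        if prof.prep_room_task_min is None:
            raise ConfigurationError(
                f"anesthesia type {case.anesthesia.value} has no preparation-room time"
            )
        tasks["preparation_room"] = prof.prep_room_task_min
    tasks["enter_theatre"] = t.enter_theatre_min
    tasks["anesthesia"] = phases.induction
    tasks["surgical_operation"] = phases.operating
    tasks["end_anesthesia"] = phases.awakening
    if case.destination is Destination.ICU:
        tasks["exit_theatre"] = t.exit_to_icu_min
        tasks["transport_icu"] = t.transport_icu_min
    else:
        tasks["exit_theatre"] = (
            t.exit_to_recovery_min
            if case.destination is Destination.RECOVERY
            else t.ward_exit_min
        )
        if case.destination is Destination.RECOVERY:
            tasks["recovery_stay"] = t.recovery_stay_min
        tasks["transport_ward"] = (
            t.transport_ward_same_min if case.same_building else t.transport_ward_diff_min
        )
    return tasks


def total_pathway_time(
    case: CaseProfile, params: PathwayParameters | None = None
) -> float:
    """Ward-to-ward elapsed minutes for the case (cleaning excluded)."""
    return sum(pathway_tasks(case, params).values())
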