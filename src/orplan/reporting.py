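"""Utilization reporting and the first-come-first-served baseline.

The baseline mirrors open booking: patients taken strictly in registration
order, each placed into the earliest compatible block with room left.
``compare`` measures the optimized plan against it in throughput (planned
patients) and mean block utilization.
"""
from __future__ import annotations

import csv
import json
from datetime import date
from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field

from .mss import MasterSchedule, ORBlock, Session, monday_of, specialty_capacity
from .pathway import PathwayParameters
from .scheduler import (
    Assignment,
    AssignmentStatus,
    Schedule,
    case_load,
    verify_schedule,
)
from .waiting_list import Patient, URGCode, WaitingList


class ReportError(ValueError):
    pass


class UtilizationReport(BaseModel):
    model_config = ConfigDict(frozen=True)

    block_load_min: dict[str, float]
    block_utilization: dict[str, float]
    specialty_load_min: dict[str, float]
    specialty_utilization: dict[str, float]
    planned_by_urg: dict[URGCode, int]
    planned_by_phase: dict[int, int]
    n_planned: int
    n_postponed: int
    n_cancelled: int
    n_unscheduled: int
    mean_block_utilization: float = Field(ge=0, le=1)

    def to_json(self) -> str:
        payload = self.model_dump()
        payload["planned_by_urg"] = {k.value: v for k, v in self.planned_by_urg.items()}
        return json.dumps(payload, indent=2, sort_keys=True)


def report(
    schedule: Schedule,
    mss: MasterSchedule,
    *,
    include_idle_blocks: bool = False,
) -> UtilizationReport:
    """Per-block and per-specialty utilization of a solved schedule.

    Mean utilization is taken over opened blocks (those holding at least
    one patient) unless ``include_idle_blocks`` is set.
    """
    violations = verify_schedule(schedule, mss)
    if violations:
        raise ReportError("schedule inconsistent with MSS: " + "; ".join(violations))
    block_by_key = {b.key: b for b in mss.blocks}
    loads: dict[str, float] = {}
    utilization: dict[str, float] = {}
    weeks = set()
    for a in schedule.scheduled():
        label = a.block.label()
        loads[label] = loads.get(label, 0.0) + a.load_min
        weeks.add(monday_of(a.block.date))
    for b in mss.blocks:
        label = b.label()
        if label in loads:
            utilization[label] = loads[label] / b.duration_min
        elif include_idle_blocks:
            loads[label] = 0.0
            utilization[label] = 0.0

    spec_load: dict[str, float] = {}
    for a in schedule.scheduled():
        spec_load[a.specialty] = spec_load.get(a.specialty, 0.0) + a.load_min
    spec_util = {}
    for spec, load in spec_load.items():
        capacity = sum(specialty_capacity(mss, spec, w) for w in weeks) or 1.0
        spec_util[spec] = load / capacity

    by_urg: dict[URGCode, int] = {}
    by_phase: dict[int, int] = {}
    for a in schedule.scheduled():
        by_urg[a.urg] = by_urg.get(a.urg, 0) + 1
        by_phase[a.phase] = by_phase.get(a.phase, 0) + 1
    n_planned = len(schedule.scheduled())
    fractions = list(utilization.values())
    return UtilizationReport(
        block_load_min=loads,
        block_utilization=utilization,
        specialty_load_min=spec_load,
        specialty_utilization=spec_util,
        planned_by_urg=by_urg,
        planned_by_phase=by_phase,
        n_planned=n_planned,
        n_postponed=sum(
            1 for a in schedule.assignments if a.status is AssignmentStatus.POSTPONED
        ),
        n_cancelled=sum(
            1 for a in schedule.assignments if a.status is AssignmentStatus.CANCELLED
        ),
        n_unscheduled=sum(
            1 for a in schedule.assignments if a.status is AssignmentStatus.UNSCHEDULED
        ),
        mean_block_utilization=(sum(fractions) / len(fractions)) if fractions else 0.0,
    )


def fcfs_baseline(
    waiting_list: WaitingList | Sequence[Patient],
    mss: MasterSchedule,
    *,
    params: PathwayParameters | None = None,
    load_mode: str = "occupation",
) -> Schedule:
    """Open-booking baseline: first come, first served, first fit.

    Patients in (registration date, id) order, each placed in the earliest
    compatible block (by date, session, room) with remaining capacity;
    skipped patients stay unscheduled. Deterministic.
    """
    patients = (
        waiting_list.patients
        if isinstance(waiting_list, WaitingList)
        else list(waiting_list)
    )
    order = sorted(patients, key=lambda p: (p.registration_date, p.id))
    blocks = sorted(
        mss.blocks, key=lambda b: (b.date, b.session is Session.AFTERNOON, b.room)
    )
    remaining = {b.key: b.duration_min for b in blocks}
    assignments = []
    for p in order:
        load = case_load(p, params, load_mode)
        placed: Optional[ORBlock] = None
        for b in blocks:
            if b.specialty == p.specialty and remaining[b.key] >= load - 1e-9:
                placed = b
                remaining[b.key] -= load
                break
        assignments.append(
            Assignment(
                patient_id=p.id,
                specialty=p.specialty,
                urg=p.urg,
                load_min=load,
                block=placed,
                status=AssignmentStatus.PLANNED
                if placed
                else AssignmentStatus.UNSCHEDULED,
                phase=0,
            )
        )
    return Schedule(assignments=assignments, phase=0)


class GainMetrics(BaseModel):
    model_config = ConfigDict(frozen=True)

    planned_optimized: int
    planned_baseline: int
    throughput_gain_pct: Optional[float]
    mean_utilization_optimized: float
    mean_utilization_baseline: float
    utilization_delta_pp: float


def compare(
    optimized: Schedule, baseline: Schedule, mss: MasterSchedule
) -> GainMetrics:
    """Throughput and utilization gains of the optimized plan over the
    baseline; the throughput gain is undefined (None) when the baseline
    plans nobody."""
    rep_opt = report(optimized, mss)
    rep_base = report(baseline, mss)
    n_opt, n_base = rep_opt.n_planned, rep_base.n_planned
    gain = None if n_base == 0 else (n_opt - n_base) / n_base * 100.0
    return GainMetrics(
        planned_optimized=n_opt,
        planned_baseline=n_base,
        throughput_gain_pct=gain,
        mean_utilization_optimized=rep_opt.mean_block_utilization,
        mean_utilization_baseline=rep_base.mean_block_utilization,
        utilization_delta_pp=100.0
        * (rep_opt.mean_block_utilization - rep_base.mean_block_utilization),
    )


# ---------------------------------------------------------------------------
# schedule / changelog serialization
# ---------------------------------------------------------------------------

SCHEDULE_COLUMNS = (
    "patient_id",
    "specialty",
    "urg",
    "room",
    "date",
    "session",
    "status",
    "phase",
    "load_min",
)


def write_schedule_csv(schedule: Schedule, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SCHEDULE_COLUMNS)
        for a in sorted(
            schedule.assignments,
            key=lambda a: (a.block is None, a.block.key if a.block else (), a.patient_id),
        ):
            writer.writerow(
                [
                    a.patient_id,
                    a.specialty,
                    a.urg.value,
                    a.block.room if a.block else "",
                    a.block.date.isoformat() if a.block else "",
                    a.block.session.value if a.block else "",
                    a.status.value,
                    a.phase,
                    f"{a.load_min:.3f}",
                ]
            )


def read_schedule_csv(path, mss: MasterSchedule) -> Schedule:
    block_by_key = {b.key: b for b in mss.blocks}
    assignments = []
    last_phase = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if tuple(reader.fieldnames or ()) != SCHEDULE_COLUMNS:
            raise ReportError(
                f"schedule header must be {','.join(SCHEDULE_COLUMNS)}"
            )
        for i, row in enumerate(reader, start=2):
            block = None
            if row["room"]:
                key = (row["room"], date.fromisoformat(row["date"]), Session(row["session"]))
                block = block_by_key.get(key)
                if block is None:
                    raise ReportError(f"line {i}: block {key} not found in the MSS")
            assignments.append(
                Assignment(
                    patient_id=row["patient_id"],
                    specialty=row["specialty"],
                    urg=URGCode(row["urg"]),
                    load_min=float(row["load_min"]),
                    block=block,
                    status=AssignmentStatus(row["status"]),
                    phase=int(row["phase"]),
                )
            )
            last_phase = max(last_phase, int(row["phase"]))
    return Schedule(assignments=assignments, phase=last_phase)


def write_changelog_csv(changelog, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["phase", "patient_id", "kind", "from_block", "to_block"])
        for e in changelog:
            writer.writerow([e.phase, e.patient_id, e.kind, e.from_block, e.to_block or ""])
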