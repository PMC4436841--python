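"""0-1 assignment of waiting-list patients to OR blocks.

The planning problem: given the eligible patients of a phase and the target
week's Master Surgical Schedule blocks, choose a binary variable x[i,b] for
every (patient, compatible block) pair — compatible meaning the block is
reserved for the patient's specialty and long enough to hold the case —
subject to

* C1  each patient is assigned at most one block,
* C2  the summed case load in a block never exceeds the block duration
      (no overtime at the planning stage),
* C3  each specialty's scheduled load in the week stays below the phase's
      cumulative utilization cap times the specialty's a-priori MSS
      capacity (no "cannibalism" of one specialty's blocks by another
      phase's backlog).

The objective minimizes total patient cost in Need Adjusted Waiting Days:
an unscheduled patient is charged NAWD at the planning horizon's end (the
last block date plus a review interval — the earliest they could plausibly
be operated on instead); a scheduled patient is charged coefficient x wait
to the block date; moving or dropping a patient planned in an earlier phase
costs a postponement or cancellation penalty.

Re-optimization runs three times — 5, 3 and 1 weeks ahead — admitting
progressively more urgent classes (B/C/D, then A, then AA) under cumulative
utilization caps of 50/75/100 %, carrying earlier assignments as soft
constraints.

The case load entering C2/C3 defaults to the pathway model's OR occupation
time; ``load_mode="eot"`` reproduces the bare expected-operating-time
variant.
"""
from __future__ import annotations

import contextlib
import logging
import os
import statistics
import time as _time
from dataclasses import dataclass, field
from datetime import date, timedelta
from enum import Enum
from functools import lru_cache
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .mss import MasterSchedule, ORBlock, monday_of, specialty_capacity
from .pathway import ConfigurationError, PathwayParameters, or_occupation_time
from .waiting_list import (
    Patient,
    URGCode,
    URGTable,
    WaitingList,
    default_urg_table,
    eligible,
    nawd,
)

logger = logging.getLogger(__name__)

#: tie-break perturbation scale (earlier registration, then smaller id, wins
#: among equal-cost optima)
TIEBREAK_EPS = 1e-6


class SolverError(RuntimeError):
    pass


@contextlib.contextmanager
def _quiet_native_stdout():
    """Mute the solver library's direct writes to file descriptor 1."""
    try:
        saved = os.dup(1)
    except OSError:
        yield
        return
    try:
        with open(os.devnull, "wb") as devnull:
            os.dup2(devnull.fileno(), 1)
            try:
                yield
            finally:
                # flush C-level stdio while fd 1 still points at devnull,
                # or buffered solver chatter surfaces after restoration
                try:
                    import ctypes

                    ctypes.CDLL(None).fflush(None)
                except Exception:
                    pass
    finally:
        os.dup2(saved, 1)
        os.close(saved)


class InfeasibleModelError(SolverError):
    def __init__(self, message: str, violated: list[str] | None = None):
        super().__init__(message)
        self.violated = violated or []


class AssignmentStatus(str, Enum):
    PLANNED = "planned"
    POSTPONED = "postponed"  # scheduled, but moved off an earlier phase's block
    CANCELLED = "cancelled"  # dropped after having been planned
    UNSCHEDULED = "unscheduled"


class Assignment(BaseModel):
    model_config = ConfigDict(frozen=True)

    patient_id: str
    specialty: str
    urg: URGCode
    load_min: float
    block: Optional[ORBlock] = None
    status: AssignmentStatus
    phase: int

    @property
    def scheduled(self) -> bool:
        return self.status in (AssignmentStatus.PLANNED, AssignmentStatus.POSTPONED)


class Schedule(BaseModel):
    assignments: list[Assignment]
    phase: int
    metrics: dict = Field(default_factory=dict)

    def by_id(self) -> dict[str, Assignment]:
        return {a.patient_id: a for a in self.assignments}

    def scheduled(self) -> list[Assignment]:
        return [a for a in self.assignments if a.scheduled]

    def block_loads(self) -> dict[tuple, float]:
        loads: dict[tuple, float] = {}
        for a in self.scheduled():
            loads[a.block.key] = loads.get(a.block.key, 0.0) + a.load_min
        return loads


class ChangeEvent(BaseModel):
    model_config = ConfigDict(frozen=True)

    phase: int
    patient_id: str
    kind: str  # "postponed" | "cancelled"
    from_block: str
    to_block: Optional[str] = None


class PhaseConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    index: int = Field(ge=1)
    weeks_ahead: int = Field(ge=1)
    eligible_urgs: frozenset[URGCode]
    fill_urgs: frozenset[URGCode] = frozenset()
    cumulative_utilization_cap: float = Field(gt=0, le=1)
    postpone_penalty: Optional[float] = Field(default=None, ge=0)
    cancel_penalty: Optional[float] = Field(default=None, ge=0)


@lru_cache(maxsize=1)
def default_phases() -> tuple[PhaseConfig, ...]:
    rows = yaml.safe_load(
        resources.files("orplan.data").joinpath("phases_default.yaml").read_text()
    )
    return tuple(PhaseConfig(**r) for r in rows)


def load_phases_yaml(path) -> tuple[PhaseConfig, ...]:
    with open(path) as fh:
        rows = yaml.safe_load(fh)
    phases = tuple(PhaseConfig(**r) for r in rows)
    caps = [p.cumulative_utilization_cap for p in phases]
    if any(a > b for a, b in zip(caps, caps[1:])):
        raise ConfigurationError("cumulative utilization caps must be nondecreasing")
    return phases


def case_load(
    patient: Patient,
    params: PathwayParameters | None = None,
    load_mode: str = "occupation",
) -> float:
    """Minutes a case charges against block capacity."""
    if load_mode == "eot":
        return patient.case.eot_min
    if load_mode == "occupation":
        return or_occupation_time(patient.case, params)
    raise ConfigurationError(f"unknown load mode {load_mode!r}")


@dataclass
class ModelSpec:
    """Declarative 0-1 model: variables, costs, capacities, prior links."""

    patients: list[Patient]
    blocks: list[ORBlock]
    phase: PhaseConfig
    var_pairs: list[tuple[int, int]]  # (patient index, block index)
    lp_cost: np.ndarray
    loads: np.ndarray  # per patient
    coeffs: np.ndarray  # per patient urgency coefficient
    unsched_cost: np.ndarray  # per patient NAWD at horizon end
    horizon_end: date
    prior_block: dict[int, int]  # patient idx -> prior block idx
    must_schedule: set[int] = field(default_factory=set)  # Σ_b x[i,b] == 1
    fixed_vars: set[int] = field(default_factory=set)  # var idx with x == 1
    postpone_penalty: float = 0.0
    cancel_penalty: float = 0.0
    specialty_caps: dict[str, float] = field(default_factory=dict)

    @property
    def n_vars(self) -> int:
        return len(self.var_pairs)


def build_model(
    patients: Sequence[Patient],
    mss: MasterSchedule,
    phase: PhaseConfig,
    prior: Schedule | None = None,
    *,
    target_week: date | None = None,
    run_date: date | None = None,
    urg_table: URGTable | None = None,
    params: PathwayParameters | None = None,
    load_mode: str = "occupation",
    review_interval_days: int = 7,
) -> ModelSpec:
    """Assemble the phase's 0-1 assignment model.

    ``prior`` carries the schedule of the previous phase; its patients enter
    as soft constraints whose displacement costs the phase's postponement /
    cancellation penalties (``inf`` hardens them into fixed assignments).
    """
    urg_table = urg_table or default_urg_table()
    patients = list(patients)
    if target_week is None:
        if not mss.blocks:
            raise ConfigurationError("empty master schedule")
        target_week = monday_of(min(b.date for b in mss.blocks))
    blocks = mss.blocks_in_week(target_week)
    if not blocks:
        raise ConfigurationError(f"no MSS blocks in week of {target_week}")
    if run_date is None:
        run_date = target_week - timedelta(weeks=phase.weeks_ahead)
    horizon_end = max(b.date for b in blocks) + timedelta(days=review_interval_days)

    n = len(patients)
    loads = np.array([case_load(p, params, load_mode) for p in patients])
    coeffs = np.array([urg_table.coefficient(p.urg) for p in patients])
    unsched = np.array(
        [nawd(p, horizon_end, urg_table) for p in patients]
    )

    # penalties default to 1x / 5x the median candidate NAWD at the run date
    if phase.postpone_penalty is None or phase.cancel_penalty is None:
        med = (
            statistics.median(nawd(p, run_date, urg_table) for p in patients)
            if patients
            else 0.0
        )
        med = max(med, 1.0)
    postpone = phase.postpone_penalty if phase.postpone_penalty is not None else med
    cancel = phase.cancel_penalty if phase.cancel_penalty is not None else 5 * med

    block_index = {b.key: j for j, b in enumerate(blocks)}
    prior_block: dict[int, int] = {}
    if prior is not None:
        prior_by_id = {a.patient_id: a for a in prior.scheduled()}
        for i, p in enumerate(patients):
            a = prior_by_id.get(p.id)
            if a is not None:
                j = block_index.get(a.block.key)
                if j is None:
                    raise ConfigurationError(
                        f"prior block {a.block.label()} of patient {p.id} is outside "
                        f"the target week {target_week}"
                    )
                prior_block[i] = j

    # tie-break: earlier registration then smaller id gets a larger bonus
    order = sorted(range(n), key=lambda i: (patients[i].registration_date, patients[i].id))
    rank = {i: r for r, i in enumerate(order)}
    var_pairs: list[tuple[int, int]] = []
    lp_cost: list[float] = []
    must_schedule: set[int] = set()
    fixed_vars: set[int] = set()

    for i, p in enumerate(patients):
        compat = [
            j
            for j, b in enumerate(blocks)
            if b.specialty == p.specialty and loads[i] <= b.duration_min + 1e-9
        ]
        j0 = prior_block.get(i)
        if j0 is not None:
            if np.isinf(postpone) and np.isinf(cancel):
                var_pairs.append((i, j0))
                lp_cost.append(0.0)  # cost immaterial, variable fixed
                fixed_vars.add(len(var_pairs) - 1)
                continue
            if np.isinf(postpone):
                compat = [j0]
            if np.isinf(cancel):
                must_schedule.add(i)
        bonus = TIEBREAK_EPS * coeffs[i] * (n - rank[i]) / max(n, 1)
        for j in compat:
            b = blocks[j]
            c = coeffs[i] * (b.date - p.registration_date).days - unsched[i] - bonus
            if j0 is not None:
                if j != j0:
                    c += postpone
                if not np.isinf(cancel):
                    c -= cancel
            var_pairs.append((i, j))
            lp_cost.append(c)

    caps = {
        spec: phase.cumulative_utilization_cap
        * specialty_capacity(mss, spec, target_week)
        for spec in sorted({p.specialty for p in patients} & set(mss.specialty_list))
    }

    return ModelSpec(
        patients=patients,
        blocks=blocks,
        phase=phase,
        var_pairs=var_pairs,
        lp_cost=np.asarray(lp_cost, dtype=float),
        loads=loads,
        coeffs=coeffs,
        unsched_cost=unsched,
        horizon_end=horizon_end,
        prior_block=prior_block,
        must_schedule=must_schedule,
        fixed_vars=fixed_vars,
        postpone_penalty=float(postpone),
        cancel_penalty=float(cancel),
        specialty_caps=caps,
    )


def schedule_objective(model: ModelSpec, chosen: dict[int, Optional[int]]) -> float:
    """True objective of an assignment (patient idx -> block idx or None)."""
    total = 0.0
    for i, p in enumerate(model.patients):
        j = chosen.get(i)
        j0 = model.prior_block.get(i)
        if j is None:
            total += model.unsched_cost[i]
            if j0 is not None:
                total += model.cancel_penalty
        else:
            total += model.coeffs[i] * (model.blocks[j].date - p.registration_date).days
            if j0 is not None and j != j0:
                total += model.postpone_penalty
    return total


def _empty_solution(model: ModelSpec) -> dict[int, Optional[int]]:
    return {i: None for i in range(len(model.patients))}


def solve_phase(
    model: ModelSpec,
    *,
    time_limit: float = 60.0,
    mip_rel_gap: float = 1e-6,
) -> Schedule:
    """Solve the phase model to (near-)optimality with the HiGHS MILP solver.

    Deterministic for a fixed model; among equal-cost optima the tie-break
    perturbation prefers earlier-registered, smaller-id patients.
    """
    t0 = _time.perf_counter()
    chosen = _empty_solution(model)
    nv = model.n_vars
    if nv:
        rows, cols, vals = [], [], []
        con_lb, con_ub = [], []
        row = 0
        # C1: at most (exactly, if must_schedule) one block per patient
        by_patient: dict[int, list[int]] = {}
        by_block: dict[int, list[int]] = {}
        for k, (i, j) in enumerate(model.var_pairs):
            by_patient.setdefault(i, []).append(k)
            by_block.setdefault(j, []).append(k)
        for i, ks in sorted(by_patient.items()):
            for k in ks:
                rows.append(row)
                cols.append(k)
                vals.append(1.0)
            con_lb.append(1.0 if i in model.must_schedule else -np.inf)
            con_ub.append(1.0)
            row += 1
        # C2: no overtime in any block
        for j, ks in sorted(by_block.items()):
            for k in ks:
                rows.append(row)
                cols.append(k)
                vals.append(model.loads[model.var_pairs[k][0]])
            con_lb.append(-np.inf)
            con_ub.append(model.blocks[j].duration_min)
            row += 1
        # C3: per-specialty cumulative utilization cap
        for spec, cap in sorted(model.specialty_caps.items()):
            ks = [
                k
                for k, (i, j) in enumerate(model.var_pairs)
                if model.patients[i].specialty == spec
            ]
            if not ks:
                continue
            for k in ks:
                rows.append(row)
                cols.append(k)
                vals.append(model.loads[model.var_pairs[k][0]])
            con_lb.append(-np.inf)
            con_ub.append(cap)
            row += 1

        A = sparse.csr_matrix((vals, (rows, cols)), shape=(row, nv))
        lb = np.zeros(nv)
        for k in model.fixed_vars:
            lb[k] = 1.0
        with _quiet_native_stdout():
            res = milp(
                c=model.lp_cost,
                constraints=LinearConstraint(A, np.array(con_lb), np.array(con_ub)),
                integrality=np.ones(nv),
                bounds=Bounds(lb, np.ones(nv)),
                options={"time_limit": time_limit, "mip_rel_gap": mip_rel_gap},
            )
        if res.status == 2:
            violated = [
                f"fixed prior assignment: patient "
                f"{model.patients[model.var_pairs[k][0]].id} -> "
                f"{model.blocks[model.var_pairs[k][1]].label()}"
                for k in sorted(model.fixed_vars)
            ] + [
                f"must-schedule patient {model.patients[i].id}"
                for i in sorted(model.must_schedule)
            ]
            raise InfeasibleModelError(
                "phase model infeasible (prior assignments cannot be kept within "
                "capacity)",
                violated=violated,
            )
        if res.x is None:
            raise SolverError(f"solver failed with status {res.status}: {res.message}")
        if res.status != 0:
            logger.warning("solver stopped early (%s); using incumbent", res.message)
        x = np.round(res.x)
        for k, (i, j) in enumerate(model.var_pairs):
            if x[k] > 0.5:
                chosen[i] = j

    assignments = []
    for i, p in enumerate(model.patients):
        j = chosen[i]
        j0 = model.prior_block.get(i)
        if j is not None:
            status = (
                AssignmentStatus.POSTPONED
                if j0 is not None and j != j0
                else AssignmentStatus.PLANNED
            )
            block = model.blocks[j]
        else:
            status = (
                AssignmentStatus.CANCELLED if j0 is not None else AssignmentStatus.UNSCHEDULED
            )
            block = None
        assignments.append(
            Assignment(
                patient_id=p.id,
                specialty=p.specialty,
                urg=p.urg,
                load_min=float(model.loads[i]),
                block=block,
                status=status,
                phase=model.phase.index,
            )
        )
    schedule = Schedule(assignments=assignments, phase=model.phase.index)
    spec_load: dict[str, float] = {}
    for a in schedule.scheduled():
        spec_load[a.specialty] = spec_load.get(a.specialty, 0.0) + a.load_min
    schedule.metrics = {
        "objective": schedule_objective(model, chosen),
        "n_variables": nv,
        "n_planned": sum(1 for a in assignments if a.scheduled),
        "specialty_load_min": spec_load,
        "specialty_cap_min": dict(model.specialty_caps),
        "solve_seconds": _time.perf_counter() - t0,
    }
    logger.info(
        "phase %d: %d vars, %d planned, objective %.2f (%.2fs)",
        model.phase.index,
        nv,
        schedule.metrics["n_planned"],
        schedule.metrics["objective"],
        schedule.metrics["solve_seconds"],
    )
    return schedule


def plan_three_phase(
    waiting_list: WaitingList,
    arrivals: Iterable[Patient],
    mss: MasterSchedule,
    phases: Sequence[PhaseConfig] | None = None,
    *,
    urg_table: URGTable | None = None,
    params: PathwayParameters | None = None,
    load_mode: str = "occupation",
    review_interval_days: int = 7,
    time_limit: float = 60.0,
    mip_rel_gap: float = 1e-6,
) -> tuple[Schedule, list[ChangeEvent]]:
    """Run the moving-target planning: three successive (re-)optimizations.

    Phase 1 runs on the waiting list's reference date, targeting the week
    ``weeks_ahead`` weeks later; later phases rerun closer to surgery with
    the arrivals registered in between, carrying earlier assignments as
    soft constraints. Patients selected in a phase leave the candidate
    pool; a cancellation returns its patient to the pool.
    """
    phases = list(phases or default_phases())
    if any(
        a.weeks_ahead <= b.weeks_ahead for a, b in zip(phases, phases[1:])
    ):
        raise ConfigurationError("phases must be ordered by decreasing weeks_ahead")
    urg_table = urg_table or default_urg_table()
    target_week = monday_of(
        waiting_list.reference_date + timedelta(weeks=phases[0].weeks_ahead)
    )

    pool: dict[str, Patient] = {p.id: p for p in waiting_list.patients}
    arrivals = sorted(arrivals, key=lambda p: (p.registration_date, p.id))
    arrival_cursor = 0

    planned: dict[str, tuple[Patient, Assignment]] = {}
    first_phase: dict[str, int] = {}
    ever_moved: set[str] = set()
    cancelled_at: dict[str, int] = {}
    changelog: list[ChangeEvent] = []
    prior: Schedule | None = None
    phase_metrics: dict[int, dict] = {}

    for phase in phases:
        run_date = target_week - timedelta(weeks=phase.weeks_ahead)
        while (
            arrival_cursor < len(arrivals)
            and arrivals[arrival_cursor].registration_date <= run_date
        ):
            p = arrivals[arrival_cursor]
            if p.id in pool or p.id in planned:
                raise ConfigurationError(f"duplicate arrival id {p.id}")
            pool[p.id] = p
            arrival_cursor += 1

        admitted = phase.eligible_urgs | phase.fill_urgs
        candidates = eligible(list(pool.values()), admitted)
        carried = [pat for pat, _ in planned.values()]
        model = build_model(
            candidates + carried,
            mss,
            phase,
            prior,
            target_week=target_week,
            run_date=run_date,
            urg_table=urg_table,
            params=params,
            load_mode=load_mode,
            review_interval_days=review_interval_days,
        )
        schedule = solve_phase(model, time_limit=time_limit, mip_rel_gap=mip_rel_gap)
        phase_metrics[phase.index] = schedule.metrics

        prior_planned = dict(planned)
        for a in schedule.assignments:
            pid = a.patient_id
            if a.scheduled:
                patient = pool.pop(pid, None) or prior_planned[pid][0]
                if pid not in first_phase:
                    first_phase[pid] = phase.index
                if a.status is AssignmentStatus.POSTPONED:
                    ever_moved.add(pid)
                    old = prior_planned[pid][1]
                    changelog.append(
                        ChangeEvent(
                            phase=phase.index,
                            patient_id=pid,
                            kind="postponed",
                            from_block=old.block.label(),
                            to_block=a.block.label(),
                        )
                    )
                planned[pid] = (patient, a)
                cancelled_at.pop(pid, None)
            elif a.status is AssignmentStatus.CANCELLED:
                patient, old = prior_planned[pid]
                changelog.append(
                    ChangeEvent(
                        phase=phase.index,
                        patient_id=pid,
                        kind="cancelled",
                        from_block=old.block.label(),
                    )
                )
                del planned[pid]
                first_phase.pop(pid, None)
                cancelled_at[pid] = phase.index
                pool[patient.id] = patient
        prior = Schedule(
            assignments=[a for _, a in planned.values()],
            phase=phase.index,
        )

    last = phases[-1].index
    final_assignments: list[Assignment] = []
    for pid, (patient, a) in planned.items():
        status = AssignmentStatus.POSTPONED if pid in ever_moved else AssignmentStatus.PLANNED
        final_assignments.append(
            a.model_copy(update={"status": status, "phase": first_phase[pid]})
        )
    for pid, patient in pool.items():
        status = (
            AssignmentStatus.CANCELLED if pid in cancelled_at else AssignmentStatus.UNSCHEDULED
        )
        final_assignments.append(
            Assignment(
                patient_id=pid,
                specialty=patient.specialty,
                urg=patient.urg,
                load_min=case_load(patient, params, load_mode),
                block=None,
                status=status,
                phase=cancelled_at.get(pid, last),
            )
        )
    final = Schedule(assignments=final_assignments, phase=last)
    final.metrics = {
        "phases": phase_metrics,
        "target_week": target_week.isoformat(),
        "n_planned": sum(1 for a in final_assignments if a.scheduled),
        "n_postponements": sum(1 for e in changelog if e.kind == "postponed"),
        "n_cancellations": sum(1 for e in changelog if e.kind == "cancelled"),
    }
    return final, changelog


def verify_schedule(
    schedule: Schedule,
    mss: MasterSchedule,
    *,
    cap: float | None = None,
    target_week: date | None = None,
) -> list[str]:
    """Feasibility audit; returns a list of violation descriptions (empty
    when the schedule is feasible)."""
    violations: list[str] = []
    block_by_key = {b.key: b for b in mss.blocks}
    seen: dict[str, int] = {}
    loads: dict[tuple, float] = {}
    spec_load: dict[str, float] = {}
    for a in schedule.scheduled():
        seen[a.patient_id] = seen.get(a.patient_id, 0) + 1
        b = block_by_key.get(a.block.key)
        if b is None:
            violations.append(f"{a.patient_id}: block {a.block.label()} not in MSS")
            continue
        if b.specialty != a.specialty:
            violations.append(
                f"{a.patient_id} ({a.specialty}) assigned a {b.specialty} block"
            )
        loads[b.key] = loads.get(b.key, 0.0) + a.load_min
        spec_load[a.specialty] = spec_load.get(a.specialty, 0.0) + a.load_min
    for pid, count in seen.items():
        if count > 1:
            violations.append(f"{pid} assigned {count} blocks")
    for key, load in loads.items():
        b = block_by_key[key]
        if load > b.duration_min + 1e-6:
            violations.append(
                f"block {b.label()} overloaded: {load:.1f} > {b.duration_min}"
            )
    if cap is not None:
        if target_week is None and loads:
            target_week = monday_of(min(k[1] for k in loads))
        for spec, load in spec_load.items():
            limit = cap * specialty_capacity(mss, spec, target_week)
            if load > limit + 1e-6:
                violations.append(
                    f"specialty {spec} over cap: {load:.1f} > {limit:.1f}"
                )
    return violations
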