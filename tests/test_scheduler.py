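"""0-1 assignment model: constraints, optimality, three-phase behavior."""
from datetime import timedelta

import numpy as np
import pytest

from orplan import (
    AssignmentStatus,
    InfeasibleModelError,
    PhaseConfig,
    Schedule,
    WaitingList,
    build_model,
    case_load,
    default_phases,
    plan_three_phase,
    solve_phase,
    verify_schedule,
)
from orplan.pathway import ConfigurationError

from conftest import REFERENCE, TARGET_MONDAY, make_patient, make_week
from instances import random_small_model
from oracles import assignment_cost, brute_force_optimum

ALL_URGS = frozenset({"AA", "A", "B", "C", "D"})


def phase_cfg(cap=1.0, postpone=0.0, cancel=0.0, index=1, weeks_ahead=5, urgs=ALL_URGS):
    return PhaseConfig(
        index=index,
        weeks_ahead=weeks_ahead,
        eligible_urgs=urgs,
        cumulative_utilization_cap=cap,
        postpone_penalty=postpone,
        cancel_penalty=cancel,
    )


def chosen_of(schedule, model):
    by_id = schedule.by_id()
    block_idx = {b.key: j for j, b in enumerate(model.blocks)}
    return {
        i: (block_idx[by_id[p.id].block.key] if by_id[p.id].scheduled else None)
        for i, p in enumerate(model.patients)
    }


# ---------------------------------------------------------------------------
# build_model basics
# ---------------------------------------------------------------------------


def test_single_patient_fits_and_is_planned():
    mss = make_week([("S1", 360)])
    p = make_patient("p1", specialty="S1", eot=60)
    model = build_model([p], mss, phase_cfg(), target_week=TARGET_MONDAY)
    assert model.n_vars == 1
    schedule = solve_phase(model)
    assert schedule.by_id()["p1"].status is AssignmentStatus.PLANNED


def test_patient_without_compatible_block_is_unscheduled():
    mss = make_week([("S1", 360)])
    p = make_patient("p1", specialty="S2")
    model = build_model([p], mss, phase_cfg(), target_week=TARGET_MONDAY)
    assert model.n_vars == 0
    schedule = solve_phase(model)
    assert schedule.by_id()["p1"].status is AssignmentStatus.UNSCHEDULED


def test_block_capacity_limits_count():
    """Three 200-min loads cannot share one 360-min block."""
    mss = make_week([("S1", 360)])
    patients = [
        make_patient(f"p{k}", specialty="S1", eot=200, anesthesia="A",
                     destination="recovery_room")
        for k in range(3)
    ]
    model = build_model(
        patients, mss, phase_cfg(), target_week=TARGET_MONDAY, load_mode="eot"
    )
    schedule = solve_phase(model)
    assert len(schedule.scheduled()) == 1
    assert not verify_schedule(schedule, mss)


def test_all_fit_instance_plans_everyone():
    mss = make_week([("S1", 360), ("S1", 360)])
    patients = [make_patient(f"p{k}", specialty="S1", eot=40) for k in range(4)]
    model = build_model(patients, mss, phase_cfg(), target_week=TARGET_MONDAY)
    schedule = solve_phase(model)
    assert len(schedule.scheduled()) == 4


def test_specialty_cap_binds():
    """A 0.5 cap over two 360-min blocks leaves room for one 200-min load."""
    mss = make_week([("S1", 360), ("S1", 360)])
    patients = [
        make_patient(f"p{k}", specialty="S1", eot=200) for k in range(3)
    ]
    model = build_model(
        patients, mss, phase_cfg(cap=0.5), target_week=TARGET_MONDAY, load_mode="eot"
    )
    schedule = solve_phase(model)
    assert len(schedule.scheduled()) == 1
    assert sum(a.load_min for a in schedule.scheduled()) <= 0.5 * 720


def test_load_mode_occupation_exceeds_eot():
    p = make_patient("p1", eot=100, anesthesia="D", destination="intensive_care")
    assert case_load(p, load_mode="eot") == 100
    assert case_load(p, load_mode="occupation") == pytest.approx(210)
    with pytest.raises(ConfigurationError):
        case_load(p, load_mode="nonsense")


# ---------------------------------------------------------------------------
# optimality against exhaustive enumeration
# ---------------------------------------------------------------------------


def test_solver_matches_brute_force_on_random_instances(urg_table):
    """Sampled miniature instances: MILP optimum == enumeration optimum."""
    rng = np.random.default_rng(42)
    for _ in range(150):
        model = random_small_model(rng)
        best_cost, _ = brute_force_optimum(model, urg_table)
        schedule = solve_phase(model)
        got = assignment_cost(model, chosen_of(schedule, model), urg_table)
        assert got == pytest.approx(best_cost, abs=1e-3)


def test_tie_break_prefers_earlier_registration():
    """Identical patients, one slot: the older registration wins."""
    mss = make_week([("S1", 360)])
    newer = make_patient("a-newer", specialty="S1", eot=300, registered=REFERENCE)
    older = make_patient("b-older", specialty="S1", eot=300,
                         registered=REFERENCE - timedelta(days=10))
    # same URG, same load: identical objective contribution up to the tie-break
    model = build_model([newer, older], mss, phase_cfg(), target_week=TARGET_MONDAY,
                        load_mode="eot")
    schedule = solve_phase(model)
    assert schedule.by_id()["b-older"].scheduled
    assert not schedule.by_id()["a-newer"].scheduled


def test_urgency_dominance_never_violated(urg_table):
    """No optimum leaves an urgent patient waiting while a compatible,
    no-lighter, less urgent one is planned: swapping them would strictly
    reduce cost, so the configuration must never occur in a solution."""
    rng = np.random.default_rng(7)
    informative = 0
    for _ in range(80):
        model = random_small_model(rng, allow_prior=False)
        schedule = solve_phase(model)
        chosen = chosen_of(schedule, model)
        for i, pi in enumerate(model.patients):
            if chosen[i] is not None:
                continue
            for j, pj in enumerate(model.patients):
                if chosen[j] is None or pi.specialty != pj.specialty:
                    continue
                informative += 1
                dominated = (
                    model.loads[i] <= model.loads[j]
                    and model.coeffs[i] > model.coeffs[j]
                )
                if dominated:
                    swapped = dict(chosen)
                    swapped[i], swapped[j] = chosen[j], None
                    assert assignment_cost(
                        model, swapped, urg_table
                    ) > assignment_cost(model, chosen, urg_table), (
                        "optimum admits a strictly improving urgency swap"
                    )
    assert informative > 0  # the sample did exercise unscheduled/planned pairs


def test_cap_monotonicity():
    """Raising the utilization cap never plans fewer patients."""
    mss = make_week([("S1", 360), ("S1", 360), ("S2", 360)])
    rng = np.random.default_rng(3)
    patients = [
        make_patient(
            f"p{k}",
            specialty=["S1", "S2"][int(rng.integers(0, 2))],
            urg=["A", "B", "C", "D"][int(rng.integers(0, 4))],
            eot=float(rng.uniform(30, 250)),
            registered=REFERENCE - timedelta(days=int(rng.integers(0, 90))),
        )
        for k in range(15)
    ]
    counts = []
    for cap in (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0):
        schedule = solve_phase(
            build_model(patients, mss, phase_cfg(cap=cap), target_week=TARGET_MONDAY)
        )
        counts.append(len(schedule.scheduled()))
    assert counts == sorted(counts)


# ---------------------------------------------------------------------------
# priors, penalties, infeasibility
# ---------------------------------------------------------------------------


def test_resolve_with_infinite_penalties_is_identity():
    mss = make_week([("S1", 360), ("S1", 360)])
    patients = [make_patient(f"p{k}", specialty="S1", eot=100) for k in range(4)]
    first = solve_phase(
        build_model(patients, mss, phase_cfg(), target_week=TARGET_MONDAY)
    )
    again = solve_phase(
        build_model(
            patients,
            mss,
            phase_cfg(postpone=float("inf"), cancel=float("inf"), index=2),
            prior=first,
            target_week=TARGET_MONDAY,
        )
    )
    assert {a.patient_id: a.block.key for a in again.scheduled()} == {
        a.patient_id: a.block.key for a in first.scheduled()
    }


def test_infeasible_prior_reports_violations():
    """Two fixed prior patients cannot share a block they overflow."""
    mss = make_week([("S1", 360)])
    block = mss.blocks[0]
    patients = [make_patient(f"p{k}", specialty="S1", eot=250) for k in range(2)]
    prior = Schedule(
        assignments=[
            make_assignment(p, block, load=250.0) for p in patients
        ],
        phase=1,
    )
    with pytest.raises(InfeasibleModelError) as err:
        solve_phase(
            build_model(
                patients,
                mss,
                phase_cfg(postpone=float("inf"), cancel=float("inf"), index=2),
                prior=prior,
                target_week=TARGET_MONDAY,
                load_mode="eot",
            )
        )
    assert any("p0" in v for v in err.value.violated)


def make_assignment(patient, block, load):
    from orplan import Assignment

    return Assignment(
        patient_id=patient.id,
        specialty=patient.specialty,
        urg=patient.urg,
        load_min=load,
        block=block,
        status=AssignmentStatus.PLANNED,
        phase=1,
    )


# ---------------------------------------------------------------------------
# three-phase moving-target planning
# ---------------------------------------------------------------------------


def hard_phases():
    """Default phase design with infinite disruption penalties."""
    return [
        p.model_copy(update={"postpone_penalty": float("inf"),
                             "cancel_penalty": float("inf")})
        for p in default_phases()
    ]


def test_three_phase_preserves_phase1_with_infinite_penalties(default_week):
    wl_patients = [
        make_patient(f"p{k}", specialty="Urology", urg=["B", "C", "D"][k % 3],
                     registered=REFERENCE - timedelta(days=30 + k), eot=60)
        for k in range(12)
    ]
    wl = WaitingList(patients=wl_patients, reference_date=REFERENCE)
    schedule, changelog = plan_three_phase(wl, [], default_week, hard_phases())
    assert changelog == []
    assert schedule.metrics["n_postponements"] == 0
    assert schedule.metrics["n_cancellations"] == 0
    phase1 = {a.patient_id for a in schedule.scheduled() if a.phase == 1}
    assert phase1  # phase 1 planned someone and nothing moved afterwards


def test_aa_arrival_planned_in_phase_3(default_week):
    wl = WaitingList(
        patients=[make_patient("p0", specialty="Urology", urg="B", eot=60)],
        reference_date=REFERENCE,
    )
    aa = make_patient("aa1", specialty="Urology", urg="AA", eot=60,
                      registered=REFERENCE + timedelta(weeks=4))
    schedule, _ = plan_three_phase(wl, [aa], default_week, hard_phases())
    a = schedule.by_id()["aa1"]
    assert a.status is AssignmentStatus.PLANNED and a.phase == 3


def test_urgent_load_forces_postponement():
    """A late A-patient that only fits the larger block displaces the
    B-patient planned there in phase 1 when postponement is cheap."""
    mss = make_week([("S1", 360), ("S1", 240)])
    b_patient = make_patient("b1", specialty="S1", urg="B", eot=200,
                             registered=REFERENCE - timedelta(days=40))
    a_patient = make_patient("a1", specialty="S1", urg="A", eot=300,
                             registered=REFERENCE + timedelta(days=10))
    phases = [
        phase_cfg(cap=1.0, postpone=10.0, cancel=10_000.0, index=1, weeks_ahead=5,
                  urgs=frozenset({"B", "C", "D"})),
        phase_cfg(cap=1.0, postpone=10.0, cancel=10_000.0, index=2, weeks_ahead=3,
                  urgs=frozenset({"A"})),
        phase_cfg(cap=1.0, postpone=10.0, cancel=10_000.0, index=3, weeks_ahead=1,
                  urgs=frozenset({"AA"})),
    ]
    wl = WaitingList(patients=[b_patient], reference_date=REFERENCE)
    schedule, changelog = plan_three_phase(
        wl, [a_patient], mss, phases, load_mode="eot"
    )
    moves = [e for e in changelog if e.kind == "postponed"]
    assert len(moves) == 1 and moves[0].patient_id == "b1" and moves[0].phase == 2
    by_id = schedule.by_id()
    assert by_id["a1"].block.duration_min == 360
    assert by_id["b1"].status is AssignmentStatus.POSTPONED
    assert by_id["b1"].block.duration_min == 240


def test_urgent_load_forces_cancellation():
    """When no alternative block can hold the displaced patient, they are
    cancelled back to the waiting list."""
    mss = make_week([("S1", 360), ("S1", 240)])
    b_patient = make_patient("b1", specialty="S1", urg="B", eot=300,
                             registered=REFERENCE - timedelta(days=40))
    a_patient = make_patient("a1", specialty="S1", urg="A", eot=350,
                             registered=REFERENCE + timedelta(days=10))
    phases = [
        phase_cfg(cap=1.0, postpone=10.0, cancel=20.0, index=1, weeks_ahead=5,
                  urgs=frozenset({"B", "C", "D"})),
        phase_cfg(cap=1.0, postpone=10.0, cancel=20.0, index=2, weeks_ahead=3,
                  urgs=frozenset({"A"})),
        phase_cfg(cap=1.0, postpone=10.0, cancel=20.0, index=3, weeks_ahead=1,
                  urgs=frozenset({"AA"})),
    ]
    wl = WaitingList(patients=[b_patient], reference_date=REFERENCE)
    schedule, changelog = plan_three_phase(
        wl, [a_patient], mss, phases, load_mode="eot"
    )
    kinds = {e.kind for e in changelog}
    assert kinds == {"cancelled"}
    by_id = schedule.by_id()
    assert by_id["b1"].status is AssignmentStatus.CANCELLED
    assert by_id["a1"].scheduled


def test_feasibility_on_random_weeks(urg_table):
    """Solved schedules satisfy every structural constraint (small sample;
    the full sweep runs in the acceptance suite)."""
    from orplan import arrivals, generate_waiting_list
    from orplan.mss import default_template, expand_template

    mss = expand_template(default_template(), REFERENCE, 6)
    for seed in range(5):
        wl = generate_waiting_list(120, REFERENCE, seed=seed)
        stream = arrivals(20, 4, seed=seed + 1000, start_date=REFERENCE)
        schedule, _ = plan_three_phase(
            wl, stream, mss, mip_rel_gap=1e-3, time_limit=10
        )
        assert not verify_schedule(schedule, mss, cap=1.0)
        for idx, m in schedule.metrics["phases"].items():
            for spec, load in m["specialty_load_min"].items():
                assert load <= m["specialty_cap_min"][spec] + 1e-6
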