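"""Random small scheduling instances shared by the solver tests."""
from __future__ import annotations

from datetime import timedelta

import numpy as np

from orplan import (
    Assignment,
    AssignmentStatus,
    PhaseConfig,
    Schedule,
    build_model,
    case_load,
)
from orplan.scheduler import ModelSpec

from conftest import REFERENCE, TARGET_MONDAY, make_patient, make_week

URGS = ("AA", "A", "B", "C", "D")


def random_small_model(
    rng: np.random.Generator,
    *,
    max_patients: int = 8,
    max_blocks: int = 3,
    allow_prior: bool = True,
) -> ModelSpec:
    n_blocks = int(rng.integers(1, max_blocks + 1))
    specs = ["S1", "S2"]
    block_specs = [
        (specs[int(rng.integers(0, 2))], float(rng.choice([120, 180, 240, 300, 360])))
        for _ in range(n_blocks)
    ]
    mss = make_week(block_specs)

    n = int(rng.integers(1, max_patients + 1))
    patients = [
        make_patient(
            f"q{k}",
            specialty=specs[int(rng.integers(0, 2))],
            urg=URGS[int(rng.integers(0, 5))],
            registered=REFERENCE - timedelta(days=int(rng.integers(0, 200))),
            eot=float(rng.uniform(20, 300)),
            anesthesia=["A", "B", "C", "D"][int(rng.integers(0, 4))],
        )
        for k in range(n)
    ]

    cap = float(rng.choice([0.5, 0.75, 1.0]))
    scenario = int(rng.integers(0, 4)) if allow_prior else 0
    penalties = {
        0: (0.0, 0.0),  # no prior
        1: (float(rng.uniform(0, 50)), float(rng.uniform(0, 200))),
        2: (float("inf"), float("inf")),
        3: (float(rng.uniform(0, 50)), float("inf")),
    }[scenario]
    phase = PhaseConfig(
        index=2,
        weeks_ahead=3,
        eligible_urgs=frozenset(URGS),
        cumulative_utilization_cap=cap,
        postpone_penalty=penalties[0],
        cancel_penalty=penalties[1],
    )

    prior = None
    if scenario > 0:
        # feasible prior: greedy fill respecting block capacity and the cap
        remaining = {b.key: b.duration_min for b in mss.blocks}
        spec_room = {
            s: cap * sum(b.duration_min for b in mss.blocks if b.specialty == s)
            for s in specs
        }
        assignments = []
        for p in patients:
            if rng.random() < 0.5:
                continue
            load = case_load(p)
            for b in mss.blocks:
                if (
                    b.specialty == p.specialty
                    and remaining[b.key] >= load
                    and spec_room[p.specialty] >= load
                ):
                    remaining[b.key] -= load
                    spec_room[p.specialty] -= load
                    assignments.append(
                        Assignment(
                            patient_id=p.id,
                            specialty=p.specialty,
                            urg=p.urg,
                            load_min=load,
                            block=b,
                            status=AssignmentStatus.PLANNED,
                            phase=1,
                        )
                    )
                    break
        prior = Schedule(assignments=assignments, phase=1)

    return build_model(patients, mss, phase, prior, target_week=TARGET_MONDAY)
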