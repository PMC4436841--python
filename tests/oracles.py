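"""Independent oracles for the scheduler tests.

The brute-force enumerator explores every feasible 0-1 assignment of a
small model instance (patients to compatible blocks or to none), checking
block capacity and per-specialty caps directly and pricing each assignment
from first principles (urgency coefficient x wait, plus disruption
penalties). It shares no code with the MILP path.
"""
from __future__ import annotations

import itertools
import math
from typing import Optional

from orplan import URGTable, default_urg_table
from orplan.scheduler import ModelSpec


def assignment_cost(
    model: ModelSpec,
    chosen: dict[int, Optional[int]],
    urg_table: URGTable | None = None,
) -> float:
    """Price an assignment from primitive data (independent arithmetic)."""
    urg_table = urg_table or default_urg_table()
    total = 0.0
    for i, p in enumerate(model.patients):
        coeff = urg_table.coefficient(p.urg)
        j = chosen.get(i)
        j0 = model.prior_block.get(i)
        if j is None:
            total += coeff * (model.horizon_end - p.registration_date).days
            if j0 is not None:
                total += model.cancel_penalty
        else:
            total += coeff * (model.blocks[j].date - p.registration_date).days
            if j0 is not None and j != j0:
                total += model.postpone_penalty
    return total


def brute_force_optimum(
    model: ModelSpec, urg_table: URGTable | None = None
) -> tuple[float, dict[int, Optional[int]]]:
    """Exhaustive enumeration of all feasible assignments of a small model."""
    urg_table = urg_table or default_urg_table()
    n = len(model.patients)
    options: list[list[Optional[int]]] = [[None] for _ in range(n)]
    for k, (i, j) in enumerate(model.var_pairs):
        if k in model.fixed_vars:
            options[i] = [j]
        else:
            options[i].append(j)
    for i in model.must_schedule:
        options[i] = [j for j in options[i] if j is not None]

    best_cost = math.inf
    best: dict[int, Optional[int]] = {}
    durations = [b.duration_min for b in model.blocks]
    for combo in itertools.product(*options):
        loads = [0.0] * len(model.blocks)
        spec_loads: dict[str, float] = {}
        feasible = True
        for i, j in enumerate(combo):
            if j is None:
                continue
            load = float(model.loads[i])
            loads[j] += load
            spec = model.patients[i].specialty
            spec_loads[spec] = spec_loads.get(spec, 0.0) + load
            if loads[j] > durations[j] + 1e-9:
                feasible = False
                break
        if feasible:
            for spec, load in spec_loads.items():
                if spec in model.specialty_caps and load > model.specialty_caps[spec] + 1e-9:
                    feasible = False
                    break
        if not feasible:
            continue
        chosen = dict(enumerate(combo))
        cost = assignment_cost(model, chosen, urg_table)
        if cost < best_cost - 1e-12:
            best_cost = cost
            best = chosen
    return best_cost, best


def greedy_pack_count(patients_with_loads, blocks) -> int:
    """Reference first-fit packer used to cross-check the FCFS baseline:
    items in given order, first block (given order) with room."""
    remaining = [b.duration_min for b in blocks]
    count = 0
    for specialty, load in patients_with_loads:
        for j, b in enumerate(blocks):
            if b.specialty == specialty and remaining[j] >= load - 1e-9:
                remaining[j] -= load
                count += 1
                break
    return count
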