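# orplan

Elective-surgery planning for a block-booked operating theatre: a
parameterized clinical-pathway duration model feeding a 0–1 optimization
that assigns waiting-list patients to operating-room (OR) blocks over a
three-phase rolling horizon.

The package is aimed at health-care operations analysts and schedulers who
need to turn a waiting list, a Master Surgical Schedule (MSS) and a handful
of per-task timing parameters into a concrete weekly theatre plan — and to
quantify what optimization buys over first-come-first-served booking.

## The model

**Pathway durations.** Every case is described by a profile: surgeon-declared
Expected Operating Time (EOT), anesthesia type (A–D), risk flags, logistics
(building, preparation room, post-operative destination). Risks inflate the
induction, operating and awakening phases multiplicatively on their base
times (additive combination of percentage incidences by default):

    t_phase = base_phase × (1 + Σ incidence/100)

From the per-task table the package assembles the **OR occupation time**
(theatre entry + induction + operating + awakening + exit + anesthesia-type
cleaning) — the load a case places on a block — and the ward-to-ward
**total pathway time**.

**Waiting cost.** Patients carry one of five Urgency Related Groups
(AA > A > B > C > D). The cost unit is Need Adjusted Waiting Days:
NAWD(i, t) = c_urg(i) × (t − registration_i).

**Assignment.** Binary variables x[i,b] over (patient, compatible block)
pairs minimize total NAWD-denominated cost subject to: at most one block
per patient; no block overtime (Σ load ≤ block duration, 360 min sessions);
and per-specialty cumulative utilization caps. Planning runs three times —
5, 3 and 1 weeks before the target week — admitting B/C/D, then A, then AA
patients (with opportunistic fill), at caps 50 %/75 %/100 %, carrying
earlier assignments as soft constraints priced by postponement and
cancellation penalties. The MILP backend is HiGHS via
`scipy.optimize.milp`.

## Worked example

```python
from datetime import date
import orplan as op

case = op.CaseProfile(eot_min=100, anesthesia="B",
                      risks=frozenset({"HeartDisease", "Coagulopathy"}))
print(op.adjusted_phase_times(case))   # induction/operating/awakening
print(op.or_occupation_time(case))     # block load in minutes

ref = date(2012, 6, 18)                # a Monday; target week = +5 weeks
wl = op.generate_waiting_list(630, ref, seed=1)
stream = op.arrivals(None, 4, seed=2, start_date=ref)
mss = op.expand_template(op.default_template(), ref, 6)
schedule, changelog = op.plan_three_phase(wl, stream, mss)
print({k: v for k, v in schedule.metrics.items() if k != "phases"})

week = op.MasterSchedule(blocks=mss.blocks_in_week(date(2012, 7, 23)),
                         specialty_list=mss.specialty_list)
base = op.fcfs_baseline(list(wl.patients) + stream, week)
print(op.compare(schedule, base, week))
```

prints

```
PhaseTimes(induction=37.5, operating=150.0, awakening=22.5)
245.0
{'target_week': '2012-07-23', 'n_planned': 94, 'n_postponements': 0,
 'n_cancellations': 0}
planned_optimized=94 planned_baseline=66 throughput_gain_pct=42.42...
mean_utilization_optimized=0.9207... mean_utilization_baseline=0.9085...
utilization_delta_pp=1.21...
```

The first two lines are the pathway model: a heart-disease + coagulopathy
case on general anesthesia takes 37.5 min to induce (15 × 2.5), operates
for 150 min (EOT 100 × 1.5) and holds the theatre 245 min including
entry, exit and cleaning. The planning block: of a 630-patient standing list plus four
weeks of arrivals, the three-phase optimization schedules 94 patients into
the target week — 42 % more than open booking packs from the same pool —
at 92 % mean utilization of opened blocks, with no patient postponed or
cancelled between phases.

The same pipeline is available from the shell:

```bash
orplan generate --size 630 --seed 1 --out wl.csv
orplan plan --waiting-list wl.csv --seed 1 --out-schedule schedule.csv
orplan baseline --waiting-list wl.csv --out base.csv
orplan compare --optimized schedule.csv --baseline base.csv \
    --reference-date 2012-06-18
```

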