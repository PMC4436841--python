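# Methods

## Scope

`orplan` couples two models: a deterministic clinical-pathway duration
model that converts a case profile into per-task minutes, and a 0–1
assignment model that plans waiting-list patients into Master Surgical
Schedule (MSS) blocks over a three-phase rolling horizon. The MSS itself is
tactical input, never optimized; within-block sequencing, staff rostering,
overtime and emergency arrivals are out of scope.

## Pathway duration model

The patient's journey is a fixed task sequence: transport in → operating
sector entry → optional preparation room (anesthesia C/D only) → theatre
entry → anesthesia induction → surgical operation → end of anesthesia →
theatre exit → recovery room / intensive care / ward → transport back.
Ancillary tasks carry fixed minutes (defaults in
`src/orplan/data/pathway_defaults.yaml`); three phases are case-dependent:

* induction = anesthesia-task time of the anesthesia type,
* operating = surgeon-declared Expected Operating Time (EOT),
* awakening = end-anesthesia-task time,

each scaled by the combined percentage incidence of the case's risk flags.
Durations are deterministic given the profile — the parameterization is the
variability model; there is no stochastic duration component.

Two derived quantities:

* **OR occupation time** (the capacity load of a case): theatre entry +
  three adjusted phases + exit + the anesthesia-type preparation-and-
  cleaning time. Cleaning is charged to the block, not to the patient.
* **Total pathway time** (ward to ward): transport and entry tasks + the
  optional preparation-room task + theatre tasks + destination branch,
  cleaning excluded.

Design choices where the source material is open:

* **Risk combination.** Per-risk incidences are published without a
  combination rule. Risks combine additively in the multiplier,
  `base × (1 + Σ pct/100)` — order-independent and the most conservative
  of the simple rules; a `multiplicative` strategy is available in
  `PathwayParameters.risk_strategy`.
* **Induction-time decomposition.** The staffing table prints combined
  induction times (A/B/C/D = 10/15/30/45 min) while the task table prints
  an anesthesia task of 10/15/15/15 min plus a separate preparation-room
  task of 30/45 min for C/D. The task-level decomposition is canonical
  here (it is the per-task execution-time table); the combined column is
  kept as `reference_induction_min` metadata only.
* **Direct-to-ward exits.** The task table gives exit times only to
  intensive care (10) and to the recovery room (5); direct-to-ward exits
  reuse the recovery-room value, overridable via
  `TaskTimingTable.exit_to_ward_min`.
* **EOT and operating-time risks.** Operating-time incidences (e.g.
  coagulopathy +50 %) inflate the surgeon's EOT by default; if the
  declared EOT already accounts for the patient's condition, set
  `CaseProfile.eot_is_risk_adjusted` and the operating phase is left at the
  declared value (induction/awakening are still adjusted).
* Fractional minutes from percentage adjustments are kept exact
  internally; only human-readable reports round.

## Waiting list and NAWD

Patients belong to five Urgency Related Groups (URG) AA/A/B/C/D with
strictly decreasing urgency and strictly increasing maximum acceptable
waits. The waiting cost is Need Adjusted Waiting Days:
`NAWD = coefficient × elapsed days` (whole calendar days).

The source prioritization system does not publish numeric coefficients.
The shipped convention is `max_wait_days = {AA:15, A:30, B:60, C:180,
D:360}` and `coefficient = 360 / max_wait_days` (AA 24, A 12, B 6, C 2,
D 1) — the inverse-of-maximum-wait construction, normalized so class D has
unit cost per day. All structural properties tested (feasibility,
optimality, dominance, throughput) are coefficient-agnostic; the specific
values only shape which patients win ties for scarce capacity.

## Assignment model

For a phase with candidate set P and target-week blocks B, binary
variables x[i,b] exist for compatible pairs (block specialty = patient
specialty, case load ≤ block duration). Constraints:

* C1: Σ_b x[i,b] ≤ 1 for every patient (= 1 for a carried patient under an
  infinite cancellation penalty);
* C2: Σ_i load_i · x[i,b] ≤ duration_b — no overtime at the planning stage;
* C3: per specialty, Σ load ≤ cap_phase × weekly MSS capacity of that
  specialty — the cumulative utilization cap that prevents one phase's
  backlog from cannibalizing another specialty's blocks.

The load defaults to the OR occupation time; `load_mode="eot"` reproduces
the bare-EOT variant of the capacity constraint.

**Objective.** The full objective of the source optimization model is not
published; the reconstruction here, term by term (every weight
configurable):

* an unscheduled patient costs their NAWD at the **horizon end** — the last
  block date plus a 7-day review interval (`review_interval_days`),
  i.e. the earliest plausible alternative surgery date. With a horizon end
  exactly at the target week's Friday, a Friday block would carry zero
  scheduling benefit, hence the look-ahead;
* a scheduled patient costs `coefficient × (block date − registration)` —
  earlier blocks and more urgent, longer-waiting patients are preferred;
* moving a previously planned patient to a different block costs
  `postpone_penalty`; dropping them costs `cancel_penalty`. Defaults
  resolve at run time to 1× and 5× the median per-patient NAWD of the
  phase's candidates (floored at 1), encoding cancel ≫ postpone; `inf`
  hardens the soft constraint into a fixed assignment.
* tie-break: an infinitesimal bonus `1e-6 × coefficient × rank` prefers
  earlier-registered, then smaller-id patients among equal-cost optima,
  making solutions reproducible.

**Solver.** HiGHS via `scipy.optimize.milp` behind `solve_phase`
(deterministic; relative gap 1e-6 and 60 s per phase by default). On
degenerate large instances the epsilon tie-breaks make the last gap
digits expensive to close; the large-scale test sweeps therefore run at
gap 1e-3–1e-4 with 10–20 s phase limits, which cannot change any of the
structural properties they assert. Infeasibility (only possible when prior
assignments are hardened) raises with the violated constraint set; on
timeout the best incumbent is used and a warning logged.

## Three-phase moving-target planning

Phases run at 5, 3 and 1 weeks before the target week (defaults in
`data/phases_default.yaml`):

| phase | weeks ahead | admitted | fill     | cumulative cap |
|-------|-------------|----------|----------|----------------|
| 1     | 5           | B, C, D  | —        | 50 %           |
| 2     | 3           | A        | B, C, D  | 75 %           |
| 3     | 1           | AA       | A,B,C,D  | 100 %          |

Patients planned in a phase leave the candidate pool and re-enter later
phases only as soft-constrained carried assignments; a cancellation
returns its patient to the pool. Arrivals registered between run dates
join the pool before the next phase. The fill columns implement the
opportunistic rule of extending to less urgent classes when priority
demand leaves capacity unused; extending it to phase 3 (beyond the
strictly-AA reading) is this package's choice — without it the final plan
would be structurally capped near 75 % utilization and a comparison
against full-capacity open booking would be meaningless.

## Synthetic data

The generator emulates one year of elective activity in a three-OR
pediatric operating area shared by nine specialties: 3112 annual cases
with published marginal distributions over specialty, URG class and EOT
histogram bins, a standing list of 630 patients, and a Poisson arrival
stream at 3112/52 ≈ 60 patients/week. Specialty, URG and EOT are drawn
independently (only marginals are published; a joint table can be supplied
by replacing the `CaseMixSpec`). EOT is uniform within its bin; the
open-ended top bin is capped at 360 min (the 12-h block bound). Standing-
list waits are uniform over `[0, max_wait]` of each class. Anesthesia mix
(A/B/C/D = 0.25/0.40/0.25/0.10), per-risk prevalence (0.05) and logistics
probabilities (same building 0.75, preparation room given C/D 0.5,
destination recovery/ward/ICU = 0.85/0.10/0.05) are synthetic conventions
with no published counterpart.

What passing tests on these data do **not** show about real data: real
case mixes correlate EOT with specialty and urgency, arrival rates are
seasonal, declared EOTs carry surgeon bias, and URG assignment drifts —
none of which the generator reproduces. The structural guarantees
(feasibility, optimality versus enumeration, cap monotonicity) are
data-independent; the throughput and utilization magnitudes are not.

## Problem sizes used in the test and acceptance runs

Solver-versus-enumeration equivalence uses 1,000 random instances with
≤ 8 patients and ≤ 3 blocks (exhaustive enumeration stays below 4^8
assignments). The structural-feasibility sweep runs 200 seeded synthetic
weeks with 100-patient lists and 20 arrivals/week; the throughput
comparison runs 20 seeded 630-patient lists with default arrivals, one
target week. `scripts/acceptance.py` runs one full-size (630 + 4 weeks of
arrivals) three-phase plan plus the FCFS baseline at default solver
settings.

## Known limitations

* The objective is a reconstruction; relative weights of disruption
  penalties against waiting cost shape postponement behavior and should be
  calibrated before operational use.
* Durations are deterministic; no recourse for overruns, so planned
  utilization near 100 % is optimistic in practice.
* Caps and capacities are weekly and per specialty; multi-week smoothing
  and block borrowing across specialties are not modeled.
* Cases whose occupation time exceeds 360 min can never be placed (no
  overtime, fixed session length) and remain unscheduled by construction.
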