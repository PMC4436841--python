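# Default pathway parameter tables: anesthesia types, risk incidences,
# fixed task execution times (all durations in minutes).
anesthesia:
  A:
    intubation: false
    uses_prep_room: never
    induction_staff: 1
    operating_staff: 1
    recovery_staff: 1
    anesthesia_task_min: 10
    end_anesthesia_task_min: 10
    prep_room_task_min: null
    prep_cleaning_min: 15
    reference_induction_min: 10
  B:
    intubation: true
    uses_prep_room: never
    induction_staff: 1
    operating_staff: 1
    recovery_staff: 1
    anesthesia_task_min: 15
    end_anesthesia_task_min: 15
    prep_room_task_min: null
    prep_cleaning_min: 20
    reference_induction_min: 15
  C:
    intubation: true
    uses_prep_room: optional
    induction_staff: 2
    operating_staff: 1
    recovery_staff: 1
    anesthesia_task_min: 15
    end_anesthesia_task_min: 15
    prep_room_task_min: 30
    prep_cleaning_min: 40
    reference_induction_min: 30
  D:
    intubation: true
    uses_prep_room: optional
    induction_staff: 2
    operating_staff: 2
    recovery_staff: 1
    anesthesia_task_min: 15
    end_anesthesia_task_min: 15
    prep_room_task_min: 45
    prep_cleaning_min: 60
    reference_induction_min: 45
risks:
  Premature: {induction_pct: 25, operating_pct: 0, awakening_pct: 25}
  Baby: {induction_pct: 25, operating_pct: 0, awakening_pct: 0}
  HeartDisease: {induction_pct: 100, operating_pct: 0, awakening_pct: 50}
  Coagulopathy: {induction_pct: 50, operating_pct: 50, awakening_pct: 0}
  PsychoMotorPathology: {induction_pct: 50, operating_pct: 0, awakening_pct: 50}
  Allergies: {induction_pct: 25, operating_pct: 0, awakening_pct: 25}
  ParticularSyndromes: {induction_pct: 25, operating_pct: 0, awakening_pct: 25}
  NeuromuscularPathology: {induction_pct: 25, operating_pct: 0, awakening_pct: 25}
task_timings:
  transport_same_building_min: 10
  transport_diff_building_min: 20
  enter_sector_min: 10
  enter_theatre_min: 10
  exit_to_icu_min: 10
  exit_to_recovery_min: 5
  recovery_stay_min: 30
  transport_icu_min: 10
  transport_ward_same_min: 10
  transport_ward_diff_min: 20
risk_strategy: additive
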