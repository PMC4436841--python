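# Case-mix specification for the synthetic waiting-list generator.
# specialty_weights, urg_weights and eot_bins reproduce the hospital's
# annual elective case load (3112 surgeries); anesthesia_weights,
# risk_prevalence and the logistics probabilities are synthetic
# conventions (no published marginals exist for them).
specialty_weights:
  Maxillo-Facial Plastic: 551
  Otolaryngology: 29
  General: 286
  Neurosurgery: 89
  Urology: 1447
  Neonatal: 82
  Orthopedy: 106
  Gastrointestinal: 457
  Hepatobiliary: 65
urg_weights: {AA: 173, A: 660, B: 736, C: 583, D: 960}
eot_bins:
  - {lower: 0, upper: 30, weight: 383}
  - {lower: 30, upper: 60, weight: 769}
  - {lower: 60, upper: 90, weight: 593}
  - {lower: 90, upper: 120, weight: 435}
  - {lower: 120, upper: 150, weight: 273}
  - {lower: 150, upper: 360, weight: 659}
anesthesia_weights: {A: 0.25, B: 0.40, C: 0.25, D: 0.10}
risk_prevalence:
  Premature: 0.05
  Baby: 0.05
  HeartDisease: 0.05
  Coagulopathy: 0.05
  PsychoMotorPathology: 0.05
  Allergies: 0.05
  ParticularSyndromes: 0.05
  NeuromuscularPathology: 0.05
p_same_building: 0.75
p_prep_room_given_cd: 0.5
destination_probs: {recovery_room: 0.85, ward: 0.10, intensive_care: 0.05}
arrival_rate_per_week: 59.85
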