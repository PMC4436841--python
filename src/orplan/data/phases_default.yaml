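# Three-phase moving-target planning design: run 5, 3 and 1 weeks before
# the target surgery week, admitting progressively more urgent classes up
# to cumulative per-specialty utilization caps of 50/75/100 %.
# fill_urgs are admitted opportunistically when the priority classes leave
# capacity unused. Null penalties are resolved at run time to 1x (postpone)
# and 5x (cancel) the median per-patient NAWD of the phase's candidates.
- index: 1
  weeks_ahead: 5
  eligible_urgs: [B, C, D]
  fill_urgs: []
  cumulative_utilization_cap: 0.50
  postpone_penalty: null
  cancel_penalty: null
- index: 2
  weeks_ahead: 3
  eligible_urgs: [A]
  fill_urgs: [B, C, D]
  cumulative_utilization_cap: 0.75
  postpone_penalty: null
  cancel_penalty: null
- index: 3
  weeks_ahead: 1
  eligible_urgs: [AA]
  fill_urgs: [A, B, C, D]
  cumulative_utilization_cap: 1.00
  postpone_penalty: null
  cancel_penalty: null
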