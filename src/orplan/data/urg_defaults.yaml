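# Urgency Related Groups. The urgency coefficients are a package convention
# (inverse of the maximum acceptable wait, normalized so class D = 1);
# the source prioritization system does not publish its numeric values.
- {code: AA, max_wait_days: 15, urgency_coefficient: 24.0}
- {code: A, max_wait_days: 30, urgency_coefficient: 12.0}
- {code: B, max_wait_days: 60, urgency_coefficient: 6.0}
- {code: C, max_wait_days: 180, urgency_coefficient: 2.0}
- {code: D, max_wait_days: 360, urgency_coefficient: 1.0}
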