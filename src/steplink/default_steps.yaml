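# Default four-step relaxation schedule for the indirect merge.
# Site, gender, birth year and birth month are always compared exactly;
# these entries govern the event (enrollment/admission) year and month.
steps:
  - {year_mode: EXACT, month_mode: EXACT}
  - {year_mode: EXACT, month_mode: IGNORED}
  - {year_mode: IGNORED, month_mode: IGNORED}
  - {year_mode: TOLERANCE, year_tolerance: 1, month_mode: IGNORED}
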