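# Questionnaire coding rules for the Generation R cohort.
# 1 = higher myopia risk, 0 = lower risk.
cohort: GenerationR
rules:
  outdoors:
    # Total weekly outdoor exposure in hours (play outside plus active
    # school travel).  More than 7 h/week is "high" (risk 0); at or below
    # 7 h/week is coded low outdoors -> risk 1.  The boundary value 7 is
    # assigned to the low-outdoors group.
    type: threshold
    op: le
    value: 7
    coded_when_true: 1
  reading:
    # Weekly reading time categories; 5+ h/week is "high" reading (risk 1).
    type: categorical
    mapping:
      "never": 0
      "less than 5 hours per week": 0
      "5 to 10 hours per week": 1
      "11 to 15 hours per week": 1
      "over 15 hours per week": 1
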