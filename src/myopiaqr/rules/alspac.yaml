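# Questionnaire coding rules for the ALSPAC cohort.
# Each rule maps questionnaire response categories to the binary risk
# coding used in the analysis (1 = higher myopia risk, 0 = lower risk).
cohort: ALSPAC
rules:
  outdoors:
    # Time outdoors on a summer weekend day; high time outdoors is
    # protective, so the "low" responses carry risk code 1.
    type: categorical
    mapping:
      "3 or more hours": 0
      "1-2 hours": 1
      "less than 1 hours": 1
      "not at all": 1
  reading:
    # Time reading books for pleasure on holiday days; high reading time
    # carries risk code 1.
    type: categorical
    mapping:
      "3 or more hours": 1
      "1-2 hours": 1
      "less than 1 hours": 0
      "not at all": 0
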