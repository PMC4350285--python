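# Default ATC-prefix mapping of medicines to expected end-of-life use.
# Longest-prefix match; unmapped codes are reported as `unmapped`, never
# silently defaulted.  The scheme is a starting point seeded from the
# category definitions (symptom management expected to increase; active
# treatment variable; essential unchanged; non-essential/preventative
# expected to decrease) and is intended to be replaced or extended by an
# expert-reviewed mapping supplied at run time.
symptom_management:
  - N02A   # opioid analgesics
  - N02B   # other analgesics and antipyretics
  - A04A   # antiemetics
  - A06A   # laxatives
  - N05B   # anxiolytics
  - N05C   # hypnotics and sedatives
active_treatment:
  - L01    # antineoplastic agents
  - L02    # endocrine therapy
  - L03    # immunostimulants
  - L04    # immunosuppressants
  - J01    # antibacterials
  - J02    # antimycotics
  - J04    # antimycobacterials
  - J05    # antivirals
essential:
  - N03    # antiepileptics
  - A10    # drugs used in diabetes
  - H03    # thyroid therapy
  - C01    # cardiac therapy
  - C03    # diuretics
  - C07    # beta blocking agents
  - C08    # calcium channel blockers
  - C09    # renin-angiotensin agents
  - B01    # antithrombotics
  - R03    # obstructive airway disease
non_essential:
  - C10    # lipid modifying agents (statins)
  - A11    # vitamins
  - A12    # mineral supplements
  - A13    # tonics
  - M05B   # bone disease / bisphosphonates
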