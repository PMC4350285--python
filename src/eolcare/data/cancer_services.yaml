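# Service items indicative of cancer treatment, used by step 3 of the
# non-cancer screening hierarchy (chemotherapy, radiation oncology,
# cancer surgery, multidisciplinary cancer case conference).  The real
# set was assembled by manual clinical review of claimed items and is a
# required user input; this default names the synthetic catalogue's
# cancer-indicative items.
cancer_indicative_items:
  - CHEMO01
  - RADONC01
  - SURG02
  - MDC01
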