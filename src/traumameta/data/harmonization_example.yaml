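# Example per-study covariate harmonization dictionary.
# Each top-level key is a study id; each field maps that study's raw codes
# onto the pooled risk-factor coding (sex -> female flag, marital -> single
# flag, education -> below-secondary flag, index/prior trauma categories).
example_er_study:
  sex: {male: false, female: true}
  marital: {married: false, cohabiting: false, single: true, divorced: true}
  education: {primary: true, some_secondary: true, secondary: false, university: false}
  index_trauma: {mva: MVA, work_accident: other_accident, fall: other_accident, assault: assault}
  prior_trauma_types:
    accident: non-interpersonal
    natural_disaster: non-interpersonal
    combat: interpersonal
    physical_assault: interpersonal
    sexual_assault: interpersonal
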