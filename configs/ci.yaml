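# Desk-scale profile: small deployment and reduced resampling sizes for
# quick end-to-end runs (minutes on one CPU).
simulate:
  n_animals: 4
  days: 10
fit:
  hfis: [neg_HS]
  s: 10
  reps: 10
  boot_reps: 10
  n: 2000
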