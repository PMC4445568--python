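# Full-scale profile: deployment and resampling sizes of a complete
# multi-month study (14 animals, ~6.2 months, s=100/reps=30/boot=100 at
# n=7000).  Expect hours of runtime on one CPU.
simulate:
  n_animals: 14
  days: 186
fit:
  hfis: [neg_HS, MT, invRT]
  s: 100
  reps: 30
  boot_reps: 100
  n: 7000
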