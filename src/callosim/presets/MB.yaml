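# Medium-beta cortical column (spectral peak in the 20-24 Hz sub-band).
band: MB
sigmoid:
  e0_pps: 2.5
  r_per_mv: 0.56
  s0_mv: 6.0
kernels:
  excitatory: {gain_mv: 3.9, rate_per_s: 75.0}
  slow_inhibitory: {gain_mv: 4.3, rate_per_s: 33.0}
  fast_inhibitory: {gain_mv: 25.0, rate_per_s: 330.0}
connectivity:
  C: 135.0
  Cep: 1.0
  Cpe: 0.8
  Csp: 0.25
  Cps: 0.25
  Cfp: 0.3
  Cfs: 0.1
  Cpf: 0.8
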