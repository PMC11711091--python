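# Single-round transcription gel time course: one pause band with a 182 s
# escape lifetime, two replicates, 5 % multiplicative band noise.
gel:
  pause_lifetimes: [182.0]
  amplitudes: [0.6]
  timepoints: [0, 10, 20, 30, 40, 60, 90, 120, 180, 240, 360, 600]
  noise_cv: 0.05
  n_replicates: 2
  fit_range: [10, 600]
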