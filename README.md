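# expressome

Quantitative analysis of single-molecule fluorescence experiments on
transcription–translation coupling: from multi-colour trace tables to
translation dwell kinetics, ribosome–RNAP coupling statistics,
transcription-time distributions and bulk pause-escape lifetimes — plus a
synthetic-trace generator with known ground truth, so that every stage of the
pipeline can be validated without laboratory data.

## Who this is for

Single-molecule biophysicists analysing camera-based (TIRF) smFRET movies of
coupled transcription–translation systems, where an *expressome* — an RNA
polymerase with a trailing ribosome on the same mRNA — is tracked through:

- **translation elongation**: the ribosome alternates between non-rotated
  (high-FRET) and rotated (low-FRET) intersubunit conformations; each
  completed cycle is one amino-acid incorporation;
- **ribosome–RNAP coupling**: a 30S–RNAP FRET pair separates uncoupled
  (E ≈ 0), loosely coupled (E ≈ 0.1) and coupled (E ≈ 0.3) complexes;
- **transcription**: single-step loss of the DNA-template signal marks
  termination;
- **bulk pause escape**: gel band intensities of single-round transcription
  assays decay exponentially as RNAPs escape pause sites.

The pipeline starts at per-molecule intensity trace tables (CSV + JSON
sidecar); spot detection and image processing are out of scope.

## The models

**FRET and corrections.** Apparent FRET efficiency is
`E = I_A / (γ·I_D + I_A)` after baseline subtraction, donor-bleedthrough
(`I_A ← I_A − l·I_D`) and, for ALEX data, acceptor direct-excitation
correction (`I_A ← I_A − d·I_AA`). States are assigned by a shared Gaussian
HMM (two-colour data; k-means-initialised Baum–Welch, number of states by
BIC) or by trace-specific thresholds (three-colour data).

**Dwell kinetics.** Maximal state runs become dwells; completed dwell times
are fitted through their ECDF to `1 − exp(−t/τ)` or a two-component mixture,
with the data classified single-exponential whenever the minor population is
below 10 %. Spontaneous intersubunit fluctuations are removed by the
5 %-tile rule: two consecutive non-rotated dwells below the elongating
5 %-tile (probability 0.05² = 0.25 % under genuine translation) stop the
translation count, and remaining sub-1 %-tile dwells are discarded.

**Transcription times** follow an exponentially modified Gaussian:
`T = N(μ, σ²) + Exp(τ)` — Gaussian transcription plus exponential 3′-end
stalling, mean `μ + τ`, fitted by maximum likelihood with an
erfcx-stabilised log-density.

**Pause escape.** `ln(P/T)` (pause band over total lane RNA) is linear in
time inside the pause-escape range; the slope `m` gives lifetime `−1/m`.

## Worked example

`examples/03_coupling_equilibrium.py` simulates 80 ALEX coupling traces from
a three-state chain whose uncoupled state empties at 1/10.1 s⁻¹, then runs
the full analysis:

```
configured occupancies (uncoupled/loose/coupled): [0.099 0.246 0.655]
mixture means: [0.003, 0.101, 0.3]
fraction coupled: 0.80 +/- 0.05
recoupling time constant: 10.9 s (configured 10.1 s)
median coupled lifetime: 34.4 s
```

The Gaussian-mixture means land on the configured FRET levels {0, 0.1, 0.3};
the coupled fraction (loose + coupled superclass) matches the stationary
occupancy within binomial error; and the single-exponential fit of uncoupled
dwell times recovers the configured 10.1 s recoupling time within 8 %.

The other examples cover trace simulation (`01`), translation dwell analysis
with the fluctuation filter (`02`), EMG transcription-time fitting (`04`) and
gel pause-escape fitting (`05`). A thin CLI wraps the same pipelines:

```bash
expressome translation --seed 1 --out runs/translation
expressome gel --config examples/gel.yaml --seed 1 --out runs/gel
```

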