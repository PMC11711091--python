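# Methods

This note documents the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that were genuinely open.

## Trace model and corrections

A trace is a per-molecule set of equal-length intensity series (donor
emission, acceptor emission, optional third dye and acceptor-direct channel
for ALEX), with 0-based frames, half-open windows `[start, end)` and
`time = frame × frame_time`. Corrections follow the standard smFRET
convention: per-channel baseline subtraction, donor→acceptor bleedthrough
`I_A ← I_A − l·I_D`, acceptor direct excitation `I_A ← I_A − d·I_AA`
(ALEX only), and the detection-sensitivity ratio γ applied in the FRET
denominator, `E = I_A/(γ·I_D + I_A)`, not to the stored intensities. The
choice of where γ acts is a convention, not physics; it is made once, here,
and the simulator emits intensities consistent with it, so a γ-aware
analysis recovers the configured state FRET exactly. Defaults are
`l = d = 0, γ = 1`: correction parameters are instrument properties that the
user must calibrate per dataset.

Corrected intensities may be negative (baseline-subtracted camera data);
frames where the γ-weighted total is ≤ 0 are flagged invalid rather than
clamped, and E is never clipped to [0, 1] — clamping is a classification
decision made only when states are assigned. A 3-point zero-phase smoother
is provided for plotting; analysis always runs on unsmoothed data.

**Photobleach detection** is a two-segment change-point: the split
maximising the between-segment sum of squares is accepted as a bleach only
if the post-step mean is below `accept_fraction = 0.25` of the pre-step
mean. The 0.25 default tolerates residual background while rejecting partial
quenching; on a clean step it is exact for any amplitude and position.

**Evaluation windows** run from the first frame to the earliest of donor
bleach, acceptor bleach and a user end. For ALEX selections, traces whose
acceptor-direct signal survives less than `min_alive_s` (default 100 s) are
rejected outright, so that apparent uncoupling cannot be confused with
acceptor photobleaching.

## State assignment

Two-colour FRET series are assigned with a Gaussian-emission hidden Markov
model shared across all molecules: emission means initialised by k-means on
the pooled E values, maximum-likelihood Baum–Welch (relative log-likelihood
tolerance 1e-6, ≤ 500 iterations, non-convergence flagged), states sorted by
ascending mean, number of states chosen by BIC over K = 1..K_max. This
ML + BIC combination is a deterministic, dependency-light stand-in for the
variational-Bayes consensus modelling used interactively in this field; for
the well-separated regimes tested the two select the same K, and the
interface leaves room for a VB backend. Decoding is Viterbi with ties broken
toward the lower state index.

Three-colour data, where spectral bleedthrough rules out HMMs, is assigned
by trace-specific thresholds (a frame's label is the number of thresholds
below its value), with runs shorter than `min_dwell_frames` merged into the
neighbour with the longer adjacent run (tie → earlier). The default
per-trace threshold is the midpoint between k-means level estimates, and it
is user-overridable, because no principled universal rule exists for
bleedthrough-limited channels.

Two automated curation steps replace manual trace inspection, and both log
every edit: (1) a candidate transition survives only if donor and acceptor
step in opposite directions at the boundary, each by more than
`step_sigma = 2` local noise SDs (real FRET transitions are
anti-correlated; blinks and drifts are not); (2) intermediate-FRET runs
flanked on both sides by high-FRET dwells are resolved to the high-FRET
state.

## Dwell kinetics and the fluctuation filter

Maximal state runs become dwells (`duration = frames × frame_time`); the
first dwell of each window is flagged left-censored, the last
right-censored. Censored dwells stay in the tables — photobleach-limited
final dwells carry information about stalling — but are excluded from rate
fits. Codon indices number successive non-rotated dwells; each completed
non-rotated → rotated cycle is one amino-acid incorporation.

The spontaneous-fluctuation filter removes fast intersubunit rotations that
masquerade as translation: scanning non-rotated dwells in order, the first
pair of consecutive dwells both below the 5 %-tile of the
elongating-condition reference stops the translation count (that pair and
every later non-rotated dwell are reassigned to rotated), and any surviving
dwell below the 1 %-tile is removed into its flanking rotated time. Under
genuine translation two consecutive sub-5 %-tile dwells occur with
probability 0.05² = 0.25 %, so the false-stop rate is negligible.
"Consecutive" means consecutive within the non-rotated subsequence — the
alternating path structure makes this the only consistent reading. The
thresholds must come from an elongating reference dataset, never from the
data being filtered (a colliding dataset's own percentiles would be inflated
by the slowdown). Two published threshold pairs for different donor dyes
ship as presets, `(2.18, 0.936)` s and `(0.936, 0.5834)` s; because the
mapping of pair to dye dataset is not fixed, thresholds are an explicit
input, with an `"auto"` mode that computes them from the dataset itself when
that dataset *is* the elongating reference. Quantiles use linear
interpolation between order statistics (type-7), a documented choice among
equally defensible conventions. The filter is idempotent and matches an
independent brute-force restatement on an exhaustive grid of dwell
sequences.

**Exponential fits.** Completed dwells are fitted through their ECDF by
non-linear least squares to `1 − exp(−t/τ)` and to a two-component mixture.
Classification follows the <10 % population rule: if the double fit's minor
population is below 10 % the data are single-exponential. Two numerical
safeguards make the rule stable: the population fraction is taken from a
maximum-likelihood EM fit of the exponential mixture (the unweighted ECDF
least-squares amplitude rides a flat ridge and over-weights the bulk), and a
second component is accepted only when it is resolvable — the mixture
likelihood must beat the single fit by more than a BIC penalty for its two
extra parameters, with time constants differing by at least ×1.2. The
reported time constants of an accepted double model come from the
EM-initialised least-squares polish. 95 % CIs are parametric bootstrap
(200 seeded resamples by default).

Per-codon statistics are box-plot summaries (median, quartiles, 1.5×IQR
whiskers) with rotated dwells inheriting the codon of the preceding
incorporation; condition comparisons use the two-sided
Wilcoxon–Mann–Whitney test from scipy.

## Coupling statistics

Pooled FRET histograms are fitted with a maximum-likelihood Gaussian mixture
(EM, k-means initialisation, 20 seeded restarts). Classification boundaries
default to (0.05, 0.2) — midway between the anchor levels 0, ≈0.1 and ≈0.3 —
and are config-exposed and recorded in output metadata, because unambiguous
assignment between the loose and coupled interfaces is not possible from E
alone. Negative E clamps to uncoupled at classification only. For dwell
analysis, loose and coupled pool into a single coupled superclass (E > 0).

`fraction coupled = coupled molecules / total molecules`, with binomial
standard error √(p(1−p)/n); the per-molecule indicator is the superclass of
the first decoded frame. When more than half the coupled dwells are
right-censored the completed-dwell median is unidentifiable, so the median
of the observed durations is reported flagged as a lower bound. Recoupling
kinetics are a forced single-exponential ECDF fit of completed uncoupled
(E = 0) dwells. Coupling at the end of transcription counts a molecule if
its 30S–DNA FRET indicator is ON within a window (default 10 s) *before* the
DNA-signal loss; an indicator that appears only afterwards is an artefact
and does not count.

## Transcription times

Per molecule, the transcription time is the single-step DNA-channel drop
minus the reagent-delivery time; traces without a drop are right-censored at
the trace end and excluded from fitting (the censoring treatment is this
package's choice; reported alongside). The completion-time density is the
exponentially modified Gaussian `N(μ,σ²) + Exp(τ)`, fitted by maximum
likelihood (Nelder–Mead on (μ, log σ, log τ); init μ₀ = median,
σ₀ = IQR/1.349, τ₀ = max(mean − median, frame_time)). ML on the density was
chosen over least squares on a histogram: it needs no binning decision and
its small-sample bias is measurably below 5 %. The log-density uses
`log erfcx(u/√2)` for `u = σ/τ − (x−μ)/σ ≥ 0` (the naive exp·erfc product
overflows for τ ≪ σ) and the direct `erfc` branch for `u < 0`, where the
exponent is provably negative. An average transcription rate
(template nt ÷ μ̂) is exposed as a convenience.

## Pause-escape kinetics

Band intensity P is divided by total lane RNA T (compensating pipetting
differences), and `ln(P/T)` is fitted by ordinary least squares within an
explicit, user-supplied pause-escape range — pause windows are
dataset-specific, so presets appear only in examples. Zero or negative P/T
points inside the range are excluded with a record. `lifetime = −1/slope`,
reported only for negative slopes. Replicates are fitted independently and
summarised as mean ± half-range. The estimate is invariant to global
rescaling of P (absorbed by the intercept) and exact on noiseless decays.

## Synthetic data: what it emulates, and what it does not

The generator is first-class, tested code; its defaults are the study
conditions the analyses are validated at.

- **Translation** (`translation_2state`): alternating non-rotated/rotated
  exponential dwells starting non-rotated; defaults 12.8 s and 5 s mean at
  0.2 s frames, state FRET 0.75/0.45 with emission SD 0.05 — the 12.8 s
  non-rotated mean matches the slow-translation (150 nM aa-tRNA) regime; the
  5 s rotated mean and the FRET levels are realistic choices for an
  intersubunit dye pair, set once. A per-codon multiplier schedule slows
  non-rotated dwells toward a stall codon (collision with a stalled RNAP);
  the schedule is a free config because only the qualitative "gradual
  increase" is constrained — the default ramp doubles the mean per codon
  over the last `slowdown_onset` codons. A `fluct_fraction = 1 %`
  subpopulation shows spontaneous non-rotated excursions out of rotated
  dwells at rates (0.5, 1.0) s⁻¹, inside the 0.3–2 s⁻¹ regime reported for
  such fluctuations; these carry no codon index in the ground truth.
- **Coupling** (`coupling_multistate`): a continuous-time Markov chain over
  coupling states (Gillespie-sampled), FRET means (0, 0.1, 0.3), emission SD
  0.03, initial state from the stationary distribution; ALEX interleaves
  donor/acceptor-excitation frames, and the acceptor-direct channel reports
  acceptor survival independent of FRET. The spec-level per-state dwell
  means are generalised to a full off-diagonal rate matrix, which a ≥2-state
  chain requires.
- **Photophysics**: one exponential-time single-step bleach per dye,
  independent of state; after donor bleach both emission channels fall to
  baseline (all FRET information lost), after acceptor bleach the donor
  inherits the full intensity budget. Total emitted intensity is constant
  across states (E partitions a fixed budget, the standard two-colour
  assumption). Additive Gaussian noise, bleedthrough `l`, direct excitation
  `d` and γ imbalance are applied exactly as the corrections assume, so the
  correction→FRET round trip is exact in the noiseless limit.
- **Dwell rendering**: continuous dwells map onto frames by the state
  occupied at each frame midpoint — simple and unbiased at small frame
  times.
- **Transcription times**: `N(μ,σ²) + Exp(τ)` truncated at zero by
  resampling. **Gel time courses**: each pause band decays as
  `A·exp(−t/lifetime)` with multiplicative lognormal noise of a given CV;
  the full-length band accumulates the complement; the default timepoint
  grid is the 0–600 s sampling of single-round assays.
- **Reproducibility**: one master seed, per-trace substreams derived
  deterministically from (seed, trace index); identical configs give
  bit-identical outputs.

Not emulated: camera images and point-spread functions, dye dark states and
blinking beyond the single bleach step, diffusion or stage drift,
non-exponential dwell mixtures within a state, sequence-dependent pause
sites in single-molecule traces, and day-to-day instrument variation.
Passing tests therefore demonstrate the correctness of the estimators under
the stated generative assumptions — not robustness to every artefact of
real microscope data.

## Problem sizes and runtime defaults

Validation ensembles are sized so the whole suite runs in a few minutes on
one core while keeping estimator error well inside the tested tolerances:
300 traces × 600 s for translation recovery, 80 traces × 600 s per coupling
ensemble, n = 2000 for transcription-time fits, 200 bootstrap resamples
(reduced in pipeline defaults where CIs are reported but not asserted).
These sizes are also representative of the per-condition molecule counts of
real datasets (hundreds of molecules, hundreds of dwells per codon).

## Known limitations

- The HMM is maximum-likelihood, not variational-Bayes: model-selection
  behaviour can differ from VB consensus on poorly separated states.
- The anticorrelation screen and intermediate-state resolution are automated
  surrogates for expert manual curation; they are logged but conservative.
- Right-censoring is handled by exclusion plus lower-bound flags, not by
  survival-likelihood fitting; completed-dwell rate estimates carry a small
  (few percent) downward bias from the censoring competition, visible in the
  recovery tests and well inside their tolerances.
- The EMG fit excludes censored times entirely, which biases μ downward if
  the movie length is comparable to typical transcription times; movies
  should be several times longer than μ + τ.
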