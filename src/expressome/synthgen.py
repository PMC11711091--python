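"""Synthetic single-molecule traces, transcription times and gel time courses.

Every downstream stage of the pipeline is verified against data generated
here with known ground truth.  Three trace-level kinetic schemes are
emulated:

* ``translation_2state`` — a translating ribosome alternating between the
  non-rotated (high-FRET) and rotated (low-FRET) intersubunit conformations
  with exponential dwells; each completed non-rotated -> rotated cycle is one
  amino-acid incorporation.  An optional per-codon schedule slows the
  non-rotated dwells as the ribosome runs into a stalled RNAP, halting at
  ``stall_codon``.  A small subpopulation of traces shows fast spontaneous
  intersubunit fluctuations (short non-rotated excursions out of the rotated
  state) that carry no codon index — these are what the downstream
  fluctuation filter must remove.
* ``coupling_multistate`` — a continuous-time Markov chain over
  ribosome-RNAP coupling states (uncoupled E~0, loosely coupled E~0.1,
  coupled E~0.3) imaged with alternating-laser excitation (ALEX): donor- and
  acceptor-excitation frames interleave, and the acceptor-excitation channel
  reports acceptor-dye survival independent of FRET.
* transcription signals — DNA-channel traces whose single-step signal loss
  marks transcription termination, with completion times drawn from a
  Gaussian (transcription) plus exponential (3'-end stalling) model.

Photophysics applied to all trace schemes: single-step exponential-time
photobleaching per dye (after donor bleach all FRET information is lost),
additive Gaussian intensity noise, donor->acceptor bleedthrough, acceptor
direct excitation and a detection-sensitivity (gamma) imbalance.  Total
emitted intensity is constant across states: E partitions a fixed photon
budget between the two emission channels.

Reproducibility: one master seed; each trace uses an independent substream
derived deterministically from (seed, trace_index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .traceio import Trace

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_translation_trace",
    "simulate_coupling_trace",
    "simulate_dataset",
    "simulate_transcription_times",
    "simulate_transcription_signal_trace",
    "simulate_end_coupling_dataset",
    "simulate_gel_timecourse",
    "stationary_distribution",
]

SCHEMES = ("translation_2state", "coupling_multistate", "transcription_signal")


@dataclass
class SimConfig:
    """Ground-truth parameters for one simulated dataset.

    Defaults reproduce the experimental regime of the slow-translation
    condition: 0.2 s frame time, non-rotated mean dwell 12.8 s and rotated
    mean 5 s, state FRET means 0.75 (non-rotated) / 0.45 (rotated), ~1 % of
    traces with fast (0.3-2 s^-1) spontaneous intersubunit fluctuations.
    """

    kinetic_scheme: str = "translation_2state"
    frame_time: float = 0.2
    n_frames: int = 3000
    n_traces: int = 1
    # emission model (FRET units); translation default: non-rotated first
    state_fret_means: tuple[float, ...] = (0.75, 0.45)
    state_fret_sd: tuple[float, ...] | float = 0.05
    # kinetics
    dwell_means: tuple[float, ...] = (12.8, 5.0)  # seconds, per state
    codon_schedule: tuple[float, ...] | None = None  # per-codon multiplier on NR dwell mean
    stall_codon: int | None = None
    slowdown_onset: int = 3
    rate_matrix: np.ndarray | None = None  # coupling scheme: off-diagonal rates, s^-1
    initial_probs: tuple[float, ...] | None = None
    # spontaneous intersubunit fluctuations
    fluct_fraction: float = 0.01
    fluct_rates: tuple[float, float] = (0.5, 1.0)  # (entry from rotated, exit) s^-1
    # photophysics
    bleach_mean_frames: dict[str, float] | None = None  # {"donor": .., "acceptor": ..}
    total_intensity: float = 1000.0
    leakage_l: float = 0.0
    direct_d: float = 0.0
    gamma: float = 1.0
    noise_sd: float = 0.0
    alex: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kinetic_scheme not in SCHEMES:
            raise ValueError(f"unknown kinetic_scheme {self.kinetic_scheme!r}")
        if self.n_frames <= 0 or self.n_traces <= 0:
            raise ValueError("n_frames and n_traces must be positive")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be > 0")
        if any(m <= 0 for m in self.dwell_means):
            raise ValueError("dwell means must be > 0")
        if not all(0.0 <= e <= 1.0 for e in self.state_fret_means):
            raise ValueError("state FRET means must lie in [0, 1]")
        if not (0.0 <= self.leakage_l < 1.0 and 0.0 <= self.direct_d < 1.0):
            raise ValueError("leakage/direct fractions must be in [0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.stall_codon is not None and self.stall_codon < 1:
            raise ValueError("stall_codon must be >= 1")
        if self.codon_schedule is not None and any(m <= 0 for m in self.codon_schedule):
            raise ValueError("codon_schedule multipliers must be > 0")
        if self.rate_matrix is not None:
            R = np.asarray(self.rate_matrix, dtype=float)
            off = R[~np.eye(R.shape[0], dtype=bool)]
            if np.any(off < 0):
                raise ValueError("rate matrix off-diagonal entries must be >= 0")

    def fret_sds(self) -> np.ndarray:
        sd = self.state_fret_sd
        K = len(self.state_fret_means)
        return np.full(K, float(sd)) if np.isscalar(sd) else np.asarray(sd, float)

    def rng_for_trace(self, trace_index: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, trace_index])


@dataclass
class GroundTruth:
    """True quantities behind one simulated trace."""

    path: np.ndarray                       # per-frame true state index
    dwells: pd.DataFrame                   # state, duration_s, codon_index, spurious
    bleach_frames: dict[str, int | None] = field(default_factory=dict)
    transcription_end_frame: int | None = None
    initial_state: int | None = None


# ---------------------------------------------------------------------------
# dwell-sequence machinery
# ---------------------------------------------------------------------------

def _codon_multiplier(cfg: SimConfig, codon: int) -> float:
    if cfg.codon_schedule is not None:
        idx = min(codon, len(cfg.codon_schedule)) - 1
        return cfg.codon_schedule[idx]
    if cfg.stall_codon is not None:
        # default ramp: NR dwell mean doubles per codon over the last
        # `slowdown_onset` codons before (and including) the stall codon
        return float(2.0 ** max(0, codon - (cfg.stall_codon - cfg.slowdown_onset)))
    return 1.0


def _render_path(starts: np.ndarray, states: np.ndarray, n_frames: int,
                 frame_time: float) -> np.ndarray:
    """Render continuous dwells onto frames: each frame takes the state
    occupied at its midpoint (unbiased at small frame_time)."""
    t_mid = (np.arange(n_frames) + 0.5) * frame_time
    idx = np.searchsorted(starts, t_mid, side="right") - 1
    return states[np.clip(idx, 0, len(states) - 1)]


def _translation_dwell_sequence(cfg: SimConfig, rng: np.random.Generator,
                                horizon: float):
    """(states, durations, codons, spurious) until the horizon is covered."""
    nr_mean, r_mean = cfg.dwell_means[0], cfg.dwell_means[1]
    fluctuator = rng.random() < cfg.fluct_fraction
    states, durations, codons, spurious = [], [], [], []
    t, codon = 0.0, 1

    def add(state, dur, cod, spur):
        states.append(state)
        durations.append(dur)
        codons.append(cod)
        spurious.append(spur)

    def rotated_period(dur, cod_for_excursions=None):
        """A rotated dwell, possibly interrupted by spontaneous short
        non-rotated excursions (fluctuator traces only)."""
        nonlocal t
        if not fluctuator:
            add(1, dur, None, False)
            t += dur
            return
        remaining = dur
        while remaining > 0:
            wait = rng.exponential(1.0 / cfg.fluct_rates[0])
            if wait >= remaining:
                add(1, remaining, None, False)
                t += remaining
                return
            add(1, wait, None, False)
            t += wait
            exc = rng.exponential(1.0 / cfg.fluct_rates[1])
            add(0, exc, None, True)  # spurious non-rotated excursion
            t += exc
            remaining -= wait

    while t < horizon:
        if cfg.stall_codon is not None and codon > cfg.stall_codon:
            rotated_period(horizon - t)  # halted after the stall codon
            break
        nr = rng.exponential(nr_mean * _codon_multiplier(cfg, codon))
        add(0, nr, codon, False)
        t += nr
        if t >= horizon:
            break
        rotated_period(rng.exponential(r_mean))
        codon += 1
    return (np.array(states), np.array(durations),
            np.array([c if c is not None else np.nan for c in codons]),
            np.array(spurious, dtype=bool))


def _bleach_frames(cfg: SimConfig, rng: np.random.Generator) -> dict[str, int | None]:
    out: dict[str, int | None] = {"donor": None, "acceptor": None}
    if cfg.bleach_mean_frames:
        for dye, mean_frames in cfg.bleach_mean_frames.items():
            if mean_frames is not None and np.isfinite(mean_frames):
                t = rng.exponential(mean_frames)
                out[dye] = int(t) if t < cfg.n_frames else None
    return out


def _emit_intensities(cfg: SimConfig, E_true: np.ndarray,
                      bleach: dict[str, int | None],
                      rng: np.random.Generator,
                      donor_excited: np.ndarray | None = None):
    """Map per-frame apparent FRET onto emission channels with photophysics.

    Inverse of the analysis convention E = Ia/(gamma*Id+Ia): Id = I0*(1-E),
    Ia = gamma*I0*E, so a gamma-aware analysis recovers E exactly.
    """
    n = len(E_true)
    I0 = cfg.total_intensity
    donor_alive = np.ones(n, dtype=bool)
    acceptor_alive = np.ones(n, dtype=bool)
    if bleach.get("donor") is not None:
        donor_alive[bleach["donor"]:] = False
    if bleach.get("acceptor") is not None:
        acceptor_alive[bleach["acceptor"]:] = False
    if donor_excited is None:
        donor_excited = np.ones(n, dtype=bool)

    donor = np.zeros(n)
    acceptor = np.zeros(n)
    both = donor_alive & acceptor_alive & donor_excited
    donor[both] = I0 * (1.0 - E_true[both])
    acceptor[both] = cfg.gamma * I0 * E_true[both]
    donor_only = donor_alive & ~acceptor_alive & donor_excited
    donor[donor_only] = I0  # full budget to the donor once the acceptor is dark
    # bleedthrough and direct excitation
    acceptor_direct = np.where(acceptor_alive & ~donor_excited, cfg.gamma * I0, 0.0)
    acceptor = acceptor + cfg.leakage_l * donor
    if cfg.direct_d:
        acceptor = acceptor + cfg.direct_d * np.where(acceptor_alive & donor_excited,
                                                      cfg.gamma * I0, 0.0)
    if cfg.noise_sd > 0:
        donor = donor + rng.normal(0.0, cfg.noise_sd, n)
        acceptor = acceptor + rng.normal(0.0, cfg.noise_sd, n)
        acceptor_direct = acceptor_direct + rng.normal(0.0, cfg.noise_sd, n)
    return donor, acceptor, acceptor_direct


def _apparent_E(cfg: SimConfig, path: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    means = np.asarray(cfg.state_fret_means, float)
    sds = cfg.fret_sds()
    E = means[path].astype(float)
    if np.any(sds > 0):
        E = E + rng.normal(0.0, 1.0, len(path)) * sds[path]
    return E


# ---------------------------------------------------------------------------
# trace simulators
# ---------------------------------------------------------------------------

def simulate_translation_trace(config: SimConfig, trace_index: int = 0
                               ) -> tuple[Trace, GroundTruth]:
    """One two-colour translation trace: alternating non-rotated (state 0,
    high FRET) / rotated (state 1, low FRET) exponential dwells starting
    non-rotated, optional collision slowdown and stall, photophysics applied.
    """
    if config.kinetic_scheme != "translation_2state":
        raise ValueError("config.kinetic_scheme must be 'translation_2state'")
    rng = config.rng_for_trace(trace_index)
    horizon = config.n_frames * config.frame_time
    states, durations, codons, spurious = _translation_dwell_sequence(config, rng, horizon)
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    path = _render_path(starts, states, config.n_frames, config.frame_time)
    bleach = _bleach_frames(config, rng)
    E = _apparent_E(config, path, rng)
    donor, acceptor, _ = _emit_intensities(config, E, bleach, rng)
    trace = Trace(
        molecule_id=f"sim{config.seed}_{trace_index:05d}",
        frame_time=config.frame_time,
        channels={"donor_em": donor, "acceptor_em": acceptor},
        metadata={"scheme": config.kinetic_scheme, "trace_index": trace_index},
    )
    truth = GroundTruth(
        path=path,
        dwells=pd.DataFrame({"state": states, "duration_s": durations,
                             "codon_index": codons, "spurious": spurious,
                             "start_s": starts}),
        bleach_frames=bleach,
    )
    return trace, truth


def stationary_distribution(rate_matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a CTMC given its off-diagonal rate matrix."""
    R = np.asarray(rate_matrix, dtype=float).copy()
    np.fill_diagonal(R, 0.0)
    Q = R.copy()
    np.fill_diagonal(Q, -R.sum(axis=1))
    # solve pi Q = 0, sum pi = 1
    A = np.vstack([Q.T, np.ones(Q.shape[0])])
    b = np.concatenate([np.zeros(Q.shape[0]), [1.0]])
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0, None)
    return pi / pi.sum()


def _ctmc_sequence(R: np.ndarray, pi0: np.ndarray, horizon: float,
                   rng: np.random.Generator):
    """Gillespie sampling of a CTMC until the horizon is covered."""
    K = R.shape[0]
    exit_rates = R.sum(axis=1)
    states, durations = [], []
    s = int(rng.choice(K, p=pi0))
    first = s
    t = 0.0
    while t < horizon:
        if exit_rates[s] <= 0:
            states.append(s)
            durations.append(horizon - t)
            break
        dur = rng.exponential(1.0 / exit_rates[s])
        states.append(s)
        durations.append(dur)
        t += dur
        s = int(rng.choice(K, p=R[s] / exit_rates[s]))
    return np.array(states), np.array(durations), first


def simulate_coupling_trace(config: SimConfig, trace_index: int = 0
                            ) -> tuple[Trace, GroundTruth]:
    """One ALEX coupling trace: CTMC over coupling FRET states sampled at the
    frame time, donor-/acceptor-excitation frames interleaved, the
    acceptor-excitation channel reporting acceptor survival independent of
    FRET."""
    if config.kinetic_scheme != "coupling_multistate":
        raise ValueError("config.kinetic_scheme must be 'coupling_multistate'")
    if config.rate_matrix is None:
        raise ValueError("coupling_multistate requires a rate_matrix")
    K = len(config.state_fret_means)
    R = np.asarray(config.rate_matrix, dtype=float)
    if R.shape != (K, K):
        raise ValueError("rate_matrix shape must match the number of states")
    rng = config.rng_for_trace(trace_index)
    pi0 = (np.asarray(config.initial_probs, float) if config.initial_probs is not None
           else stationary_distribution(R))
    horizon = config.n_frames * config.frame_time
    states, durations, first = _ctmc_sequence(R, pi0, horizon, rng)
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    path = _render_path(starts, states, config.n_frames, config.frame_time)
    bleach = _bleach_frames(config, rng)
    E = _apparent_E(config, path, rng)
    donor_excited = (np.arange(config.n_frames) % 2 == 0) if config.alex else None
    donor, acceptor, acceptor_direct = _emit_intensities(config, E, bleach, rng,
                                                         donor_excited)
    channels = {"donor_em": donor, "acceptor_em": acceptor}
    alex = None
    if config.alex:
        channels["acceptor_direct"] = acceptor_direct
        alex = np.array(["D", "A"])[np.arange(config.n_frames) % 2]
    trace = Trace(
        molecule_id=f"sim{config.seed}_{trace_index:05d}",
        frame_time=config.frame_time,
        channels=channels,
        alex=alex,
        metadata={"scheme": config.kinetic_scheme, "trace_index": trace_index},
    )
    truth = GroundTruth(
        path=path,
        dwells=pd.DataFrame({"state": states, "duration_s": durations,
                             "codon_index": np.nan, "spurious": False,
                             "start_s": starts}),
        bleach_frames=bleach,
        initial_state=first,
    )
    return trace, truth


def simulate_dataset(config: SimConfig) -> tuple[list[Trace], list[GroundTruth]]:
    """Simulate ``config.n_traces`` traces of the configured scheme."""
    sim = {"translation_2state": simulate_translation_trace,
           "coupling_multistate": simulate_coupling_trace,
           "transcription_signal": simulate_transcription_signal_trace}[config.kinetic_scheme]
    traces, truths = [], []
    for i in range(config.n_traces):
        tr, gt = sim(config, i)
        traces.append(tr)
        truths.append(gt)
    return traces, truths


# ---------------------------------------------------------------------------
# transcription times and signals
# ---------------------------------------------------------------------------

def simulate_transcription_times(n: int, mu: float, sigma: float, tau: float,
                                 seed: int = 0) -> np.ndarray:
    """Transcription completion times: Normal(mu, sigma^2) + Exp(tau),
    truncated at zero (negative draws are resampled)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if sigma < 0 or tau < 0:
        raise ValueError("sigma and tau must be >= 0")
    rng = np.random.default_rng(seed)
    out = np.empty(n)
    remaining = np.arange(n)
    while remaining.size:
        draw = rng.normal(mu, sigma, remaining.size)
        if tau > 0:
            draw = draw + rng.exponential(tau, remaining.size)
        out[remaining] = draw
        remaining = remaining[draw < 0]
    return out


def simulate_transcription_signal_trace(config: SimConfig, trace_index: int = 0,
                                        mu: float = 60.0, sigma: float = 8.0,
                                        tau: float = 15.0, start_s: float = 0.0
                                        ) -> tuple[Trace, GroundTruth]:
    """A DNA-channel trace whose single-step signal loss marks transcription
    termination; the dissociation time is EMG-distributed after ``start_s``."""
    rng = config.rng_for_trace(trace_index)
    t_end = start_s + float(simulate_transcription_times(1, mu, sigma, tau,
                                                         seed=int(rng.integers(2**31))))
    end_frame = int(t_end / config.frame_time)
    n = config.n_frames
    dna = np.where(np.arange(n) < end_frame, config.total_intensity, 0.0)
    if config.noise_sd > 0:
        dna = dna + rng.normal(0.0, config.noise_sd, n)
    zeros = np.zeros(n)
    trace = Trace(
        molecule_id=f"sim{config.seed}_{trace_index:05d}",
        frame_time=config.frame_time,
        channels={"donor_em": zeros, "acceptor_em": zeros.copy(), "third_em": dna},
        metadata={"scheme": "transcription_signal", "start_s": start_s},
    )
    truth = GroundTruth(
        path=(np.arange(n) >= end_frame).astype(int),
        dwells=pd.DataFrame({"state": [0], "duration_s": [t_end - start_s],
                             "codon_index": [np.nan], "spurious": [False],
                             "start_s": [start_s]}),
        transcription_end_frame=end_frame if end_frame < n else None,
    )
    return trace, truth


def simulate_end_coupling_dataset(n: int, p_coupled: float, n_frames: int,
                                  frame_time: float, seed: int = 0,
                                  onset_before_end_s: float = 5.0,
                                  mu: float = 60.0, sigma: float = 8.0,
                                  tau: float = 15.0):
    """Per-molecule 30S-DNA FRET indicator series and transcription-end frames.

    A fraction ``p_coupled`` of molecules shows the indicator ON from shortly
    before the end of transcription (coupled at the end); the rest stay OFF.
    Returns (indicators, end_frames, truth_flags).
    """
    rng = np.random.default_rng(seed)
    times = simulate_transcription_times(n, mu, sigma, tau, seed=seed + 1)
    indicators, end_frames, flags = [], [], []
    for i in range(n):
        end = min(int(times[i] / frame_time), n_frames - 1)
        coupled = bool(rng.random() < p_coupled)
        ind = np.zeros(n_frames, dtype=bool)
        if coupled:
            onset = max(0, end - int(onset_before_end_s / frame_time))
            ind[onset:end] = True
        indicators.append(ind)
        end_frames.append(end)
        flags.append(coupled)
    return indicators, np.array(end_frames), np.array(flags)


# ---------------------------------------------------------------------------
# gel time courses
# ---------------------------------------------------------------------------

def simulate_gel_timecourse(pause_lifetimes: Sequence[float],
                            amplitudes: Sequence[float],
                            timepoints: Sequence[float],
                            noise_cv: float = 0.0,
                            seed: int = 0,
                            n_replicates: int = 1,
                            total_rna: float = 100.0) -> pd.DataFrame:
    """Band-intensity time course of a single-round transcription assay.

    Each pause band decays as P/T(t) = amplitude * exp(-t / lifetime) with
    multiplicative lognormal noise of coefficient of variation ``noise_cv``;
    the full-length band accumulates the complement.  Columns:
    ``band, replicate, time_s, P, T``.
    """
    timepoints = np.asarray(timepoints, dtype=float)
    if timepoints.size == 0:
        raise ValueError("timepoints must be non-empty")
    if np.any(timepoints < 0) or np.any(np.diff(timepoints) < 0):
        raise ValueError("timepoints must be non-negative and sorted")
    lifetimes = np.asarray(pause_lifetimes, dtype=float)
    amps = np.asarray(amplitudes, dtype=float)
    if np.any(lifetimes <= 0):
        raise ValueError("pause lifetimes must be > 0")
    rng = np.random.default_rng(seed)
    sigma_ln = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0

    def noisy(ratio):
        if sigma_ln == 0:
            return ratio
        # lognormal with unit mean and CV = noise_cv
        return ratio * rng.lognormal(-0.5 * sigma_ln**2, sigma_ln, ratio.shape)

    rows = []
    for rep in range(1, n_replicates + 1):
        pause_sum = np.zeros_like(timepoints)
        for j, (lt, a) in enumerate(zip(lifetimes, amps), start=1):
            ratio = a * np.exp(-timepoints / lt)
            pause_sum += ratio
            rows.append(pd.DataFrame({"band": f"P{j}", "replicate": rep,
                                      "time_s": timepoints,
                                      "P": noisy(ratio) * total_rna,
                                      "T": total_rna}))
        fl = np.clip(1.0 - pause_sum, 0.0, None)
        rows.append(pd.DataFrame({"band": "full_length", "replicate": rep,
                                  "time_s": timepoints,
                                  "P": noisy(fl) * total_rna, "T": total_rna}))
    return pd.concat(rows, ignore_index=True)
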