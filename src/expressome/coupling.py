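"""Ribosome-RNAP coupling statistics from equilibrium FRET data.

The 30S-RNAP FRET efficiency of an expressome ensemble separates into an
uncoupled population (E ~ 0), a loosely coupled population (E ~ 0.1) and a
coupled population (E ~ 0.3).  This module fits the pooled FRET histogram
with a Gaussian mixture, classifies states by configurable boundaries,
computes the coupled fraction with binomial error, summarises coupled
lifetimes under right-censoring (photobleach-limited dwells make the median
a lower bound) and estimates recoupling rates from uncoupled dwell times.
For dwell analysis every state with E > 0 (loose and coupled) pools into a
single coupled superclass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from .dwells import ExpFit, fit_exponential

__all__ = [
    "GmmFit",
    "CouplingSummary",
    "DEFAULT_BOUNDARIES",
    "fit_fret_histogram",
    "classify_states",
    "coupled_fraction",
    "coupled_lifetimes",
    "recoupling_rate",
    "end_of_transcription_coupling",
]

#: class boundaries midway between the anchor FRET levels 0, ~0.1 and ~0.3
DEFAULT_BOUNDARIES = (0.05, 0.2)
CLASS_NAMES = ("uncoupled", "loose", "coupled")


@dataclass
class GmmFit:
    K: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    bic: float

    def to_dict(self) -> dict:
        return {"K": self.K, "means": self.means.tolist(), "sds": self.sds.tolist(),
                "weights": self.weights.tolist(),
                "log_likelihood": self.log_likelihood, "bic": self.bic}


@dataclass
class CouplingSummary:
    fraction_coupled: float
    fraction_se: float
    n_molecules: int
    median_coupled_lifetime_s: float | None
    lifetime_is_lower_bound: bool
    recoupling: ExpFit | None
    occupancies: dict[str, float]
    boundaries: tuple[float, float]


def fit_fret_histogram(E_values, K: int, seed: int = 0, n_init: int = 20,
                       min_n: int = 200) -> GmmFit:
    """Maximum-likelihood Gaussian mixture of pooled FRET efficiencies
    (EM, k-means initialisation, ``n_init`` seeded restarts)."""
    E = np.asarray(E_values, dtype=float)
    E = E[np.isfinite(E)]
    if E.size < min_n:
        raise ValueError(f"need at least {min_n} FRET values, got {E.size}")
    if np.all(E == E[0]):
        raise ValueError("degenerate FRET data (zero variance)")
    gm = GaussianMixture(n_components=K, n_init=n_init, random_state=seed,
                         init_params="kmeans").fit(E.reshape(-1, 1))
    order = np.argsort(gm.means_.ravel())
    loglik = float(gm.score(E.reshape(-1, 1)) * E.size)
    return GmmFit(K=K, means=gm.means_.ravel()[order],
                  sds=np.sqrt(gm.covariances_.ravel()[order]),
                  weights=gm.weights_[order], log_likelihood=loglik,
                  bic=float(gm.bic(E.reshape(-1, 1))))


def classify_states(values, boundaries=DEFAULT_BOUNDARIES) -> np.ndarray:
    """Classify FRET values (or state means) as uncoupled / loose / coupled.

    Values below the first boundary are uncoupled (negatives clamp there);
    between the boundaries loosely coupled; above, coupled.  The clamp
    happens here only — stored FRET series are never modified.
    """
    b = np.asarray(boundaries, dtype=float)
    if b.size != 2 or b[0] >= b[1]:
        raise ValueError("boundaries must be two sorted values")
    values = np.asarray(values, dtype=float)
    idx = np.searchsorted(b, values, side="right")
    return np.asarray(CLASS_NAMES)[idx]


def is_coupled_superclass(classes) -> np.ndarray:
    """Loose + coupled pool into a single coupled superclass (E > 0)."""
    return np.isin(np.asarray(classes), ("loose", "coupled"))


def coupled_fraction(coupled_flags) -> tuple[float, float]:
    """fraction coupled = coupled molecules / total molecules, with binomial
    standard error sqrt(p(1-p)/n)."""
    flags = np.asarray(coupled_flags, dtype=bool)
    n = flags.size
    if n == 0:
        raise ValueError("no molecules")
    p = flags.mean()
    return float(p), float(np.sqrt(p * (1 - p) / n))


def coupled_lifetimes(durations, censored) -> tuple[float, bool]:
    """Median coupled-superclass lifetime under right-censoring.

    When more than half the coupled dwells are photobleach-limited the
    completed-dwell median is unidentifiable; the median of the observed
    (censored) durations is then reported, flagged as a lower bound.
    """
    durations = np.asarray(durations, dtype=float)
    censored = np.asarray(censored, dtype=bool)
    if durations.size == 0:
        raise ValueError("no coupled dwells")
    if censored.mean() > 0.5:
        return float(np.median(durations)), True
    completed = durations[~censored]
    return float(np.median(completed)), False


def recoupling_rate(durations, censored=None, n_boot: int = 200, seed: int = 0
                    ) -> ExpFit:
    """Recoupling kinetics: single-exponential ECDF fit of completed
    uncoupled (E = 0) dwell times."""
    durations = np.asarray(durations, dtype=float)
    if censored is not None:
        durations = durations[~np.asarray(censored, dtype=bool)]
    if durations.size < 20:
        raise ValueError("need at least 20 completed uncoupled dwells")
    return fit_exponential(durations, model="single", n_boot=n_boot, seed=seed)


def end_of_transcription_coupling(indicators, end_frames, frame_time: float,
                                  window_s: float = 10.0) -> tuple[float, float, int]:
    """Fraction of molecules coupled at the end of transcription.

    A molecule counts as coupled if its 30S-DNA FRET indicator is ON at some
    frame within ``window_s`` seconds *before* the DNA-signal loss; an
    indicator that only turns on after the loss is an artefact and does not
    count.  Returns (fraction, binomial SE, n).
    """
    end_frames = np.asarray(end_frames)
    if len(indicators) == 0 or end_frames.size == 0:
        raise ValueError("no transcription-end events")
    w = max(1, int(round(window_s / frame_time)))
    flags = []
    for ind, end in zip(indicators, end_frames):
        ind = np.asarray(ind, dtype=bool)
        lo = max(0, int(end) - w)
        flags.append(bool(ind[lo:int(end)].any()))
    p, se = coupled_fraction(flags)
    return p, se, len(flags)
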