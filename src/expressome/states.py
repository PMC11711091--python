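"""Per-frame FRET state assignment.

Two-colour data is assigned with a Gaussian-emission hidden Markov model
shared across all molecules (k-means-initialised maximum-likelihood
Baum-Welch, with the number of states chosen by BIC over K = 1..K_max).
Three-colour data, where spectral bleedthrough rules out HMMs, is assigned
with trace-specific thresholds.  Candidate transitions can additionally be
screened for anti-correlated donor/acceptor intensity changes — the
automated surrogate for the study-style manual curation of real FRET
transitions — and isolated intermediate-FRET runs flanked by high-FRET
dwells can be resolved toward the high-FRET state.

The ML Baum-Welch + BIC combination is a deterministic stand-in for the
variational-Bayes consensus modelling used interactively in this field; for
the well-separated emission regimes handled here the two select the same
model, and the interface leaves room for a VB backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM
from sklearn.cluster import KMeans

from .traceio import FretSeries, Trace

__all__ = [
    "HmmModel",
    "StatePath",
    "select_model",
    "fit_hmm",
    "decode",
    "threshold_assign",
    "correct_anticorrelated",
    "resolve_intermediate",
]


@dataclass
class HmmModel:
    """Fitted shared-emission HMM; states are sorted by ascending FRET mean."""

    K: int
    means: np.ndarray
    sds: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray
    log_likelihood: float
    bic: float
    converged: bool
    n_obs: int
    _hmm: GaussianHMM = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {"K": self.K, "means": self.means.tolist(), "sds": self.sds.tolist(),
                "transmat": self.transmat.tolist(),
                "startprob": self.startprob.tolist(),
                "log_likelihood": self.log_likelihood, "bic": self.bic,
                "converged": self.converged}


@dataclass
class StatePath:
    """Per-frame discrete state labels for one molecule.

    ``frames`` are the (windowed, valid) frame indices the labels refer to;
    ``state_means`` maps label -> FRET mean.  ``log`` records automated
    corrections applied after the initial assignment.
    """

    molecule_id: str
    frames: np.ndarray
    labels: np.ndarray
    state_means: np.ndarray
    method: str
    frame_time: float
    log: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# HMM fitting and model selection
# ---------------------------------------------------------------------------

def _pooled(series_set) -> tuple[np.ndarray, list[int]]:
    chunks = []
    for s in series_set:
        arr = s.windowed() if isinstance(s, FretSeries) else np.asarray(s, float)
        arr = arr[np.isfinite(arr)]
        if arr.size:
            chunks.append(arr)
    if not chunks:
        return np.empty((0, 1)), []
    X = np.concatenate(chunks).reshape(-1, 1)
    return X, [len(c) for c in chunks]


def fit_hmm(series_set, K: int, seed: int = 0, n_iter: int = 500,
            tol_rel: float = 1e-6) -> HmmModel:
    """K-state Gaussian-emission HMM fit jointly across all series.

    Emission means are initialised by k-means on the pooled FRET values;
    Baum-Welch runs until the relative log-likelihood change falls below
    ``tol_rel`` or ``n_iter`` iterations (non-convergence is flagged, the
    best iterate is returned).  Emissions are Gaussian on E, matching a
    workflow that assigns states on corrected FRET rather than raw counts.
    """
    X, lengths = _pooled(series_set)
    n = X.shape[0]
    if n < K:
        raise ValueError("fewer observations than states")
    km = KMeans(n_clusters=K, n_init=10, random_state=seed).fit(X)
    order = np.argsort(km.cluster_centers_.ravel())
    means0 = km.cluster_centers_.ravel()[order].reshape(-1, 1)
    var0 = np.empty(K)
    for i, lab in enumerate(order):
        pts = X[km.labels_ == lab, 0]
        var0[i] = max(np.var(pts), 1e-6) if pts.size else 1e-4

    hmm = GaussianHMM(n_components=K, covariance_type="diag",
                      init_params="", params="stmc",
                      n_iter=n_iter, tol=tol_rel * max(1.0, float(n)),
                      random_state=seed)
    hmm.startprob_ = np.full(K, 1.0 / K)
    hmm.transmat_ = np.full((K, K), 0.1 / max(K - 1, 1)) + np.eye(K) * (0.9 - 0.1 / max(K - 1, 1))
    hmm.transmat_ /= hmm.transmat_.sum(axis=1, keepdims=True)
    hmm.means_ = means0
    hmm.covars_ = var0.reshape(-1, 1)
    hmm.fit(X, lengths)

    # canonical state order: ascending emission mean
    perm = np.argsort(hmm.means_.ravel())
    hmm.means_ = hmm.means_[perm]
    hmm.covars_ = np.asarray([np.diag(c) for c in hmm.covars_])[perm].reshape(-1, 1)
    hmm.startprob_ = hmm.startprob_[perm]
    hmm.transmat_ = hmm.transmat_[np.ix_(perm, perm)]

    loglik = float(hmm.score(X, lengths))
    n_params = (K - 1) + K * (K - 1) + 2 * K
    bic = -2.0 * loglik + n_params * np.log(n)
    return HmmModel(K=K, means=hmm.means_.ravel().copy(),
                    sds=np.sqrt(np.asarray([np.diag(c) for c in hmm.covars_]).ravel()),
                    transmat=hmm.transmat_.copy(), startprob=hmm.startprob_.copy(),
                    log_likelihood=loglik, bic=bic,
                    converged=bool(hmm.monitor_.converged), n_obs=n, _hmm=hmm)


def select_model(series_set, K_max: int, seed: int = 0, n_iter: int = 200
                 ) -> tuple[int, dict[int, float]]:
    """Choose the number of FRET states by BIC over shared-emission HMMs
    with K = 1..K_max.  Returns (K, {K: BIC})."""
    X, _ = _pooled(series_set)
    if X.shape[0] < 50:
        raise ValueError("insufficient data for model selection (< 50 frames)")
    scores: dict[int, float] = {}
    for K in range(1, K_max + 1):
        try:
            scores[K] = fit_hmm(series_set, K, seed=seed, n_iter=n_iter).bic
        except (ValueError, np.linalg.LinAlgError):
            scores[K] = np.inf
    best = min(scores, key=lambda k: (scores[k], k))
    return best, scores


def decode(model: HmmModel, series, molecule_id: str = "",
           frame_time: float | None = None) -> StatePath:
    """Most-probable (Viterbi) state sequence for one FRET series.

    Invalid (non-finite) frames are skipped; an all-invalid series yields an
    empty path.  Ties break toward the lower state index.
    """
    if isinstance(series, FretSeries):
        s, e = series.window
        E = series.E[s:e]
        mask = series.valid[s:e] & np.isfinite(E)
        frames = np.arange(s, e)[mask]
        values = E[mask]
        molecule_id = molecule_id or series.molecule_id
        frame_time = frame_time if frame_time is not None else series.frame_time
    else:
        values = np.asarray(series, float)
        mask = np.isfinite(values)
        frames = np.flatnonzero(mask)
        values = values[mask]
        frame_time = frame_time if frame_time is not None else 1.0
    if values.size == 0:
        return StatePath(molecule_id, np.array([], int), np.array([], int),
                         model.means, "hmm", frame_time)
    labels = model._hmm.predict(values.reshape(-1, 1))
    return StatePath(molecule_id, frames, labels.astype(int),
                     model.means, "hmm", frame_time)


# ---------------------------------------------------------------------------
# thresholding (three-colour data)
# ---------------------------------------------------------------------------

def _runs(labels: np.ndarray) -> list[list[int]]:
    """[[label, length], ...] run-length encoding."""
    runs: list[list[int]] = []
    for lab in labels:
        if runs and runs[-1][0] == lab:
            runs[-1][1] += 1
        else:
            runs.append([int(lab), 1])
    return runs


def _merge_short_runs(runs: list[list[int]], min_len: int) -> list[list[int]]:
    """Absorb runs shorter than min_len into the neighbour with the longer
    adjacent run (tie -> earlier neighbour); repeats until stable."""
    runs = [list(r) for r in runs]
    while True:
        if len(runs) <= 1:
            break
        idx = next((i for i, r in enumerate(runs) if r[1] < min_len), None)
        if idx is None:
            break
        left = runs[idx - 1] if idx > 0 else None
        right = runs[idx + 1] if idx < len(runs) - 1 else None
        if left is not None and (right is None or left[1] >= right[1]):
            target = left
        else:
            target = right
        runs[idx][0] = target[0]
        # merge adjacent equal labels
        merged: list[list[int]] = []
        for r in runs:
            if merged and merged[-1][0] == r[0]:
                merged[-1][1] += r[1]
            else:
                merged.append(r)
        runs = merged
    return runs


def _expand(runs: list[list[int]]) -> np.ndarray:
    return np.concatenate([[lab] * ln for lab, ln in runs]) if runs else np.array([], int)


def threshold_assign(series, thresholds, min_dwell_frames: int = 1,
                     molecule_id: str = "", frame_time: float = 1.0,
                     state_means: np.ndarray | None = None) -> StatePath:
    """Trace-specific threshold assignment: a frame's label is the number of
    thresholds below its value; runs shorter than ``min_dwell_frames`` are
    merged into the neighbouring state with the longer adjacent run."""
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("need at least one threshold")
    if np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be sorted ascending")
    if min_dwell_frames < 1:
        raise ValueError("min_dwell_frames must be >= 1")
    if isinstance(series, FretSeries):
        s, e = series.window
        values = series.E[s:e]
        mask = series.valid[s:e] & np.isfinite(values)
        frames = np.arange(s, e)[mask]
        values = values[mask]
        molecule_id = molecule_id or series.molecule_id
        frame_time = series.frame_time
    else:
        values = np.asarray(series, float)
        mask = np.isfinite(values)
        frames = np.flatnonzero(mask)
        values = values[mask]
    labels = np.searchsorted(thresholds, values, side="left")
    if min_dwell_frames > 1 and labels.size:
        labels = _expand(_merge_short_runs(_runs(labels), min_dwell_frames))
    if state_means is None:
        # representative level per class: midpoint of threshold bins
        edges = np.concatenate([[thresholds[0] - (thresholds[-1] - thresholds[0] + 1)],
                                thresholds,
                                [thresholds[-1] + (thresholds[-1] - thresholds[0] + 1)]])
        state_means = (edges[:-1] + edges[1:]) / 2
    return StatePath(molecule_id, frames, labels.astype(int),
                     np.asarray(state_means, float), "threshold", frame_time)


# ---------------------------------------------------------------------------
# transition curation
# ---------------------------------------------------------------------------

def correct_anticorrelated(path: StatePath, trace: Trace, step_sigma: float = 2.0,
                           half_window: int = 3) -> StatePath:
    """Keep only candidate transitions with anti-correlated dye intensities.

    Real FRET transitions move donor and acceptor emission in opposite
    directions; blinks and drifts do not.  At every label change the mean
    intensity step of each dye across the boundary is compared against
    ``step_sigma`` times the local noise SD; transitions failing the test
    are removed and the flanking runs merged under the longer run's label.
    Every edit is recorded in ``path.log``.
    """
    if len(path) == 0:
        return path
    donor = trace.channels["donor_em"]
    acceptor = trace.channels["acceptor_em"]
    runs = _runs(path.labels)
    log = list(path.log)
    changed = True
    while changed:
        changed = False
        pos = 0
        for i in range(len(runs) - 1):
            pos_boundary = pos + runs[i][1]  # index into path.frames
            b = path.frames[min(pos_boundary, len(path.frames) - 1)]
            w = half_window
            lo, hi = max(0, b - w), min(len(donor), b + w)
            if b - lo < 1 or hi - b < 1:
                pos += runs[i][1]
                continue
            d_step = donor[b:hi].mean() - donor[lo:b].mean()
            a_step = acceptor[b:hi].mean() - acceptor[lo:b].mean()
            d_sd = max(np.std(np.diff(donor[lo:hi])) / np.sqrt(2), 1e-12)
            a_sd = max(np.std(np.diff(acceptor[lo:hi])) / np.sqrt(2), 1e-12)
            genuine = (d_step * a_step < 0 and abs(d_step) > step_sigma * d_sd
                       and abs(a_step) > step_sigma * a_sd)
            if not genuine:
                keep = runs[i][0] if runs[i][1] >= runs[i + 1][1] else runs[i + 1][0]
                log.append({"action": "remove_transition", "frame": int(b),
                            "labels": (runs[i][0], runs[i + 1][0]), "kept": int(keep)})
                runs[i] = [keep, runs[i][1] + runs[i + 1][1]]
                del runs[i + 1]
                # re-merge neighbours with equal labels
                j = 0
                while j < len(runs) - 1:
                    if runs[j][0] == runs[j + 1][0]:
                        runs[j][1] += runs[j + 1][1]
                        del runs[j + 1]
                    else:
                        j += 1
                changed = True
                break
            pos += runs[i][1]
    return StatePath(path.molecule_id, path.frames, _expand(runs),
                     path.state_means, path.method, path.frame_time, log)


def resolve_intermediate(path: StatePath, high_label: int, mid_label: int) -> StatePath:
    """Reassign intermediate-FRET runs flanked on both sides by high-FRET
    dwells to the high-FRET state (two-colour translation data)."""
    runs = _runs(path.labels)
    log = list(path.log)
    for i in range(1, len(runs) - 1):
        if (runs[i][0] == mid_label and runs[i - 1][0] == high_label
                and runs[i + 1][0] == high_label):
            log.append({"action": "resolve_intermediate", "run_index": i,
                        "length": runs[i][1]})
            runs[i][0] = high_label
    merged: list[list[int]] = []
    for r in runs:
        if merged and merged[-1][0] == r[0]:
            merged[-1][1] += r[1]
        else:
            merged.append(r)
    return StatePath(path.molecule_id, path.frames, _expand(merged),
                     path.state_means, path.method, path.frame_time, log)
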