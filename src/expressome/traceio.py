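"""Trace data model, file I/O, intensity corrections and FRET computation.

The analysis starts from per-molecule multi-channel fluorescence time series
(donor emission, acceptor emission, optionally a third dye and an
acceptor-direct-excitation channel for ALEX movies).  This module holds the
in-memory :class:`Trace` container, reads/writes the plain-text trace format
(long CSV plus a JSON sidecar), applies the standard smFRET intensity
corrections (baseline, donor bleedthrough, acceptor direct excitation,
detection-sensitivity gamma), computes apparent FRET efficiency, detects
single-step photobleaching and selects evaluation windows.

Conventions: frames are 0-based, windows are half-open ``[start, end)``,
time = frame_index x frame_time.  Corrections may produce negative
intensities (baseline-subtracted camera data can be negative); such frames
are flagged, never rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "CorrectionParams",
    "FretSeries",
    "TraceFormatError",
    "read_traces",
    "write_traces",
    "deinterleave_alex",
    "correct_trace",
    "compute_fret",
    "detect_photobleach",
    "select_evaluation_window",
    "smooth3",
]

#: channel roles understood by the pipeline
KNOWN_CHANNELS = ("donor_em", "acceptor_em", "third_em", "acceptor_direct")
REQUIRED_CHANNELS = ("donor_em", "acceptor_em")


class TraceFormatError(ValueError):
    """Raised when a trace file violates the expected format."""


@dataclass
class Trace:
    """Per-molecule multi-channel intensity time series.

    channels maps a role name (``donor_em``, ``acceptor_em``, optional
    ``third_em`` / ``acceptor_direct``) to a 1-D float array; all arrays
    share one length.  ``alex`` optionally tags each frame with one of two
    alternating excitation labels (e.g. ``"D"``/``"A"``).
    """

    molecule_id: str
    frame_time: float
    channels: dict[str, np.ndarray]
    alex: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_time <= 0:
            raise ValueError("frame_time must be > 0")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise TraceFormatError(
                f"inconsistent channel lengths in {self.molecule_id}: {sorted(lengths)}"
            )
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        if self.alex is not None:
            self.alex = np.asarray(self.alex)
            if len(self.alex) != self.n_frames:
                raise TraceFormatError("alex label length differs from channel length")

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_time

    def __eq__(self, other) -> bool:  # numeric equality, used in round-trip tests
        if not isinstance(other, Trace):
            return NotImplemented
        if (
            self.molecule_id != other.molecule_id
            or not np.isclose(self.frame_time, other.frame_time)
            or set(self.channels) != set(other.channels)
        ):
            return False
        if any(not np.allclose(self.channels[k], other.channels[k], rtol=1e-12)
               for k in self.channels):
            return False
        if (self.alex is None) != (other.alex is None):
            return False
        return self.alex is None or bool(np.all(self.alex == other.alex))


@dataclass
class CorrectionParams:
    """Standard smFRET intensity-correction parameters.

    l: donor -> acceptor emission bleedthrough fraction.
    d: acceptor direct-excitation fraction (applied only with ALEX data).
    gamma: detection-sensitivity ratio; applied in the FRET denominator,
        not to intensities.
    baseline: per-channel additive offset subtracted first.
    """

    l: float = 0.0
    d: float = 0.0
    gamma: float = 1.0
    baseline: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.l < 1.0 and 0.0 <= self.d < 1.0):
            raise ValueError("leakage and direct-excitation fractions must be in [0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


@dataclass
class FretSeries:
    """Per-frame apparent FRET efficiency with validity flags and window."""

    molecule_id: str
    E: np.ndarray
    window: tuple[int, int]
    valid: np.ndarray
    frame_time: float

    def windowed(self) -> np.ndarray:
        """E values inside the evaluation window, invalid frames dropped."""
        s, e = self.window
        E = self.E[s:e]
        return E[self.valid[s:e]]


# ---------------------------------------------------------------------------
# file I/O: long CSV + JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_traces(traces: list[Trace], path: str | Path) -> Path:
    """Write traces to a long-format CSV with a JSON metadata sidecar.

    Columns: ``molecule_id, frame, time_s, <channels...>[, alex]``.  The
    sidecar records frame_time and channel roles per molecule.
    """
    path = Path(path).with_suffix(".csv")
    frames = []
    molecules = {}
    for tr in traces:
        df = pd.DataFrame({"molecule_id": tr.molecule_id,
                           "frame": np.arange(tr.n_frames),
                           "time_s": tr.times})
        for name, series in tr.channels.items():
            df[name] = series
        if tr.alex is not None:
            df["alex"] = tr.alex
        frames.append(df)
        molecules[tr.molecule_id] = {
            "frame_time_s": tr.frame_time,
            "channels": sorted(tr.channels),
            "metadata": tr.metadata,
        }
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
    sidecar = {"format": "expressome-traces-v1", "molecules": molecules}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_traces(path: str | Path) -> list[Trace]:
    """Read traces written by :func:`write_traces` (or the single-molecule
    dialect whose sidecar has top-level ``molecule_id``/``frame_time_s``).

    Unknown CSV columns are preserved in ``Trace.metadata['extra_columns']``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = json.loads(_sidecar_path(path).read_text())

    if "molecule_id" not in df.columns:
        if "molecule_id" not in sidecar:
            raise TraceFormatError("missing column: molecule_id (and none in sidecar)")
        df = df.assign(molecule_id=sidecar["molecule_id"])
        molecules = {sidecar["molecule_id"]: sidecar}
    else:
        molecules = sidecar.get("molecules", {})

    if "frame" not in df.columns:
        raise TraceFormatError("missing column: frame")
    for ch in REQUIRED_CHANNELS:
        if ch not in df.columns:
            raise TraceFormatError(f"missing channel: {ch}")

    channel_cols = [c for c in KNOWN_CHANNELS if c in df.columns]
    core = {"molecule_id", "frame", "time_s", "alex", *channel_cols}
    extra_cols = [c for c in df.columns if c not in core]

    traces = []
    for mol, sub in df.groupby("molecule_id", sort=False):
        sub = sub.sort_values("frame")
        info = molecules.get(str(mol), {})
        frame_time = info.get("frame_time_s")
        if frame_time is None:
            if "time_s" in sub.columns and len(sub) > 1:
                frame_time = float(np.diff(sub["time_s"].to_numpy()[:2])[0])
            else:
                raise TraceFormatError(f"no frame_time for molecule {mol}")
        meta = dict(info.get("metadata", {}))
        if extra_cols:
            meta["extra_columns"] = {c: sub[c].tolist() for c in extra_cols}
        traces.append(Trace(
            molecule_id=str(mol),
            frame_time=float(frame_time),
            channels={c: sub[c].to_numpy(dtype=float) for c in channel_cols},
            alex=sub["alex"].to_numpy() if "alex" in sub.columns else None,
            metadata=meta,
        ))
    return traces


# ---------------------------------------------------------------------------
# ALEX deinterleaving
# ---------------------------------------------------------------------------

def deinterleave_alex(trace: Trace) -> tuple[Trace, Trace]:
    """Split an ALEX movie into donor-excitation and acceptor-excitation traces.

    Frames must alternate strictly between exactly two excitation tags; the
    two returned traces have doubled frame_time and keep original frame
    indices in ``metadata['source_frames']``.
    """
    if trace.alex is None:
        raise ValueError("trace carries no ALEX labels")
    labels = np.asarray(trace.alex)
    tags = list(dict.fromkeys(labels.tolist()))
    if len(tags) != 2:
        raise TraceFormatError(f"expected exactly two ALEX tags, got {tags}")
    expected = np.array(tags)[np.arange(len(labels)) % 2]
    if not np.all(labels == expected):
        raise TraceFormatError("ALEX labels do not alternate strictly")

    out = []
    for tag in tags:
        idx = np.flatnonzero(labels == tag)
        out.append(Trace(
            molecule_id=trace.molecule_id,
            frame_time=2 * trace.frame_time,
            channels={k: v[idx] for k, v in trace.channels.items()},
            metadata={**trace.metadata, "excitation": str(tag),
                      "source_frames": idx.tolist()},
        ))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# corrections and FRET
# ---------------------------------------------------------------------------

def correct_trace(trace: Trace, params: CorrectionParams) -> Trace:
    """Apply baseline, leakage and direct-excitation corrections.

    donor' = donor - baseline_D
    acceptor' = (acceptor - baseline_A) - l * donor' - d * acceptor_direct'

    The direct-excitation term is applied only when an ``acceptor_direct``
    channel is present.  gamma is *not* applied here; it enters the FRET
    denominator in :func:`compute_fret`.
    """
    ch = {k: v.copy() for k, v in trace.channels.items()}
    for name in ch:
        ch[name] -= params.baseline.get(name, 0.0)
    ch["acceptor_em"] = ch["acceptor_em"] - params.l * ch["donor_em"]
    if params.d and "acceptor_direct" in ch:
        ch["acceptor_em"] = ch["acceptor_em"] - params.d * ch["acceptor_direct"]
    return replace(trace, channels=ch,
                   metadata={**trace.metadata, "corrected": True})


def compute_fret(trace: Trace, params: CorrectionParams | None = None,
                 window: tuple[int, int] | None = None) -> FretSeries:
    """Apparent FRET efficiency E = Ia / (gamma*Id + Ia) on a corrected trace.

    Frames where the gamma-weighted total intensity is <= 0 are flagged
    invalid (E set to NaN there).  E is not clamped to [0, 1]: values
    slightly outside are genuine noise and clamping is a classification
    decision made downstream.
    """
    params = params or CorrectionParams()
    donor = trace.channels["donor_em"]
    acceptor = trace.channels["acceptor_em"]
    total = params.gamma * donor + acceptor
    valid = total > 0
    E = np.full_like(donor, np.nan)
    np.divide(acceptor, total, out=E, where=valid)
    if window is None:
        window = (0, trace.n_frames)
    return FretSeries(molecule_id=trace.molecule_id, E=E, window=window,
                      valid=valid, frame_time=trace.frame_time)


# ---------------------------------------------------------------------------
# photobleach detection and evaluation windows
# ---------------------------------------------------------------------------

def detect_photobleach(series: np.ndarray, accept_fraction: float = 0.25) -> int | None:
    """Locate a single photobleaching step in an intensity series.

    Two-segment change-point: the split that maximises the between-segment
    sum of squares is a candidate bleach; it is accepted only if the
    post-step mean is below ``accept_fraction`` of the pre-step mean (a
    sustained drop to baseline rather than partial quenching).  Returns the
    first frame of the dark segment, or None if no acceptable step exists.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("series too short for photobleach detection (need >= 10 frames)")
    csum = np.cumsum(y)
    total = csum[-1]
    k = np.arange(1, n)  # split: [0, k) vs [k, n)
    m1 = csum[:-1] / k
    m2 = (total - csum[:-1]) / (n - k)
    grand = total / n
    between = k * (m1 - grand) ** 2 + (n - k) * (m2 - grand) ** 2
    best = int(np.argmax(between))
    pre, post = m1[best], m2[best]
    if pre <= 0 or post >= pre or post >= accept_fraction * pre:
        return None
    return best + 1  # first post-step frame


def select_evaluation_window(
    trace: Trace,
    donor_bleach: int | None,
    acceptor_bleach: int | None,
    acceptor_direct_bleach: int | None = None,
    min_alive_s: float | None = None,
    end_frame: int | None = None,
) -> tuple[int, int] | None:
    """Evaluation window ``[0, end)`` from precomputed bleach frames.

    The window ends at the earliest of donor bleach, acceptor bleach, the
    user-supplied end and the trace end.  When ``min_alive_s`` is given
    (ALEX selection), the trace is rejected (None) if the acceptor-direct
    signal survives for less than that many seconds.
    """
    if min_alive_s is not None:
        survive = acceptor_direct_bleach if acceptor_direct_bleach is not None else trace.n_frames
        if survive * trace.frame_time < min_alive_s:
            return None
    candidates = [trace.n_frames]
    for b in (donor_bleach, acceptor_bleach, end_frame):
        if b is not None:
            candidates.append(int(b))
    end = max(0, min(candidates))
    return (0, end)


def smooth3(y: np.ndarray) -> np.ndarray:
    """3-point zero-phase moving average, for plotting only.

    Analysis always runs on unsmoothed data; this exists so example plots
    look like the raw traces practitioners are used to.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        return y.copy()
    padded = np.concatenate([y[:1], y, y[-1:]])
    return np.convolve(padded, np.ones(3) / 3.0, mode="valid")
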