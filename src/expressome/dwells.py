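"""Dwell-time extraction, the spontaneous-fluctuation correction and
exponential dwell-distribution fitting.

A dwell is a maximal run of one state in a state path; for translation data
the non-rotated (high-FRET) dwells are numbered by codon — each completed
non-rotated -> rotated cycle is one amino-acid incorporation.  The first
dwell of a path is left-censored and the last right-censored
(photobleaching- or movie-end-limited); censored dwells are kept in the
tables (they inform on stalling) but excluded from rate fits.

The fluctuation filter removes spontaneous intersubunit rotations that
masquerade as translation events: real non-rotated dwells under slow
translation (median ~12.8 s at 150 nM aa-tRNA) are far longer than
spontaneous fluctuations (0.3-2 s^-1).  Two consecutive non-rotated dwells
both below the 5th percentile of the elongating-condition reference
distribution occur with probability 0.05^2 = 0.25 % under genuine
translation, so at the first such pair the translation count stops (that
pair and all later non-rotated dwells are reassigned to the rotated state);
afterwards any remaining non-rotated dwell below the 1st-percentile
threshold is removed outright.  The printed reference thresholds are shipped
as presets: (2.18, 0.936) s and (0.936, 0.5834) s for the two dye datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .states import StatePath

__all__ = [
    "DWELL_COLUMNS",
    "THRESHOLD_PRESETS",
    "ExpFit",
    "extract_dwells",
    "percentile_threshold",
    "fluctuation_filter",
    "consecutive_subthreshold_prob",
    "fit_exponential",
    "codon_dwell_stats",
    "translation_state_names",
]

DWELL_COLUMNS = ["molecule_id", "state", "codon_index", "start_frame",
                 "start_s", "duration_s", "censored"]

#: published 5%-/1%-tile threshold pairs (s) for the two donor-dye datasets
THRESHOLD_PRESETS = {"cy3": (2.18, 0.936), "cy3b": (0.936, 0.5834)}


def translation_state_names(state_means: np.ndarray) -> dict[int, str]:
    """Label the higher-FRET state non_rotated, the lower rotated."""
    means = np.asarray(state_means, float)
    hi = int(np.argmax(means))
    return {i: ("non_rotated" if i == hi else "rotated") for i in range(len(means))}


def extract_dwells(path: StatePath, frame_time: float | None = None,
                   state_names: dict[int, str] | None = None) -> pd.DataFrame:
    """Turn maximal state runs into an ordered dwell table.

    Durations are frame counts x frame_time; the first dwell is flagged
    left-censored and the last right-censored; codon indices 1..m are
    assigned to successive non_rotated dwells (when such a state exists).
    """
    frame_time = frame_time if frame_time is not None else path.frame_time
    if len(path) == 0:
        return pd.DataFrame(columns=DWELL_COLUMNS)
    if state_names is None:
        state_names = {i: f"state_{i}" for i in range(len(path.state_means))}
    labels = path.labels
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(labels)]])
    rows = []
    codon = 0
    for i, (s, e) in enumerate(zip(starts, ends)):
        name = state_names[int(labels[s])]
        if name == "non_rotated":
            codon += 1
        censored = "none"
        if i == 0:
            censored = "left"
        if i == len(starts) - 1:
            censored = "right" if i > 0 else "left+right"
        rows.append({
            "molecule_id": path.molecule_id,
            "state": name,
            "codon_index": codon if name == "non_rotated" else np.nan,
            "start_frame": int(path.frames[s]),
            "start_s": float(path.frames[s]) * frame_time,
            "duration_s": (e - s) * frame_time,
            "censored": censored,
        })
    return pd.DataFrame(rows, columns=DWELL_COLUMNS)


def percentile_threshold(sample, q: float) -> float:
    """Empirical q-quantile with linear interpolation between order
    statistics (type-7 convention)."""
    sample = np.asarray(sample, dtype=float)
    if sample.size < 20:
        raise ValueError("need at least 20 dwells to set a percentile threshold")
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    return float(np.quantile(sample, q, method="linear"))


def consecutive_subthreshold_prob(q: float, k: int) -> float:
    """Probability of k consecutive dwells all below the q-quantile under
    independent sampling from the reference distribution: q**k.

    With q = 0.05 and k = 2 this is 0.0025 (0.25 %), the false-stop rate of
    the fluctuation filter under normal translation.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    return float(q) ** int(k)


# ---------------------------------------------------------------------------
# fluctuation filter
# ---------------------------------------------------------------------------

def _merge_sequence(dwells: list[dict]) -> list[dict]:
    """Merge adjacent same-state dwells, summing durations and combining
    censoring flags."""
    merged: list[dict] = []
    for d in dwells:
        if merged and merged[-1]["state"] == d["state"]:
            prev = merged[-1]
            prev["duration_s"] += d["duration_s"]
            flags = {prev["censored"], d["censored"]}
            flags.discard("none")
            prev["censored"] = "+".join(sorted(flags)) if flags else "none"
        else:
            merged.append(dict(d))
    return merged


def fluctuation_filter(table: pd.DataFrame, thresh5: float, thresh1: float
                       ) -> tuple[pd.DataFrame, list[dict]]:
    """Remove spontaneous-fluctuation artefacts from translation dwell tables.

    Per molecule, scanning non-rotated dwells in order: at the first pair of
    consecutive non-rotated dwells both shorter than ``thresh5`` (the
    5%-tile of the elongating-condition reference), that pair and every
    later non-rotated dwell are reassigned to the rotated state (translation
    count stops there).  Afterwards any surviving non-rotated dwell shorter
    than ``thresh1`` (1%-tile) is removed, its time merged into the flanking
    rotated dwells.  Codon indices are renumbered; all edits are logged.

    Thresholds must come from an elongating-condition reference dataset,
    never from the data being filtered.
    """
    if not (thresh5 >= thresh1 > 0):
        raise ValueError("need thresh5 >= thresh1 > 0")
    log: list[dict] = []
    out_frames = []
    for mol, sub in table.groupby("molecule_id", sort=False):
        dwells = sub.sort_values("start_s").to_dict("records")
        nr_idx = [i for i, d in enumerate(dwells) if d["state"] == "non_rotated"]
        # step 1: stop translation count at the first consecutive sub-5%-tile pair
        cut = None
        for j in range(len(nr_idx) - 1):
            a, b = dwells[nr_idx[j]], dwells[nr_idx[j + 1]]
            if a["duration_s"] < thresh5 and b["duration_s"] < thresh5:
                cut = j
                break
        def _codon(d):
            c = d.get("codon_index")
            return int(c) if c is not None and np.isfinite(c) else None

        if cut is not None:
            for i in nr_idx[cut:]:
                dwells[i]["state"] = "rotated"
            log.append({"molecule_id": mol, "action": "stop_translation_count",
                        "from_codon": _codon(dwells[nr_idx[cut]]),
                        "n_reassigned": len(nr_idx) - cut})
            nr_idx = nr_idx[:cut]
        # step 2: drop surviving sub-1%-tile non-rotated dwells
        for i in nr_idx:
            if dwells[i]["duration_s"] < thresh1:
                log.append({"molecule_id": mol, "action": "remove_short_dwell",
                            "codon_index": _codon(dwells[i]),
                            "duration_s": dwells[i]["duration_s"]})
                dwells[i]["state"] = "rotated"
        dwells = _merge_sequence(dwells)
        codon = 0
        for d in dwells:
            if d["state"] == "non_rotated":
                codon += 1
                d["codon_index"] = codon
            else:
                d["codon_index"] = np.nan
        out_frames.append(pd.DataFrame(dwells))
    result = (pd.concat(out_frames, ignore_index=True)[table.columns.tolist()]
              if out_frames else table.iloc[0:0].copy())
    return result, log


# ---------------------------------------------------------------------------
# exponential dwell fits
# ---------------------------------------------------------------------------

@dataclass
class ExpFit:
    """Single- or double-exponential ECDF fit of completed dwell times."""

    model: str                      # "single" | "double"
    taus: tuple[float, ...]         # time constants, ascending (s)
    amplitudes: tuple[float, ...]   # sum to 1
    minor_amplitude: float | None   # from the initial double fit
    ci95: dict
    n: int
    classified_single_by_rule: bool = False

    @property
    def rates(self) -> tuple[float, ...]:
        return tuple(1.0 / t for t in self.taus)

    @property
    def mean(self) -> float:
        return float(sum(a * t for a, t in zip(self.amplitudes, self.taus)))


def _ecdf(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ts = np.sort(t)
    return ts, np.arange(1, len(ts) + 1) / len(ts)


def _fit_single(ts, F):
    popt, _ = optimize.curve_fit(lambda t, tau: 1.0 - np.exp(-t / tau),
                                 ts, F, p0=[max(ts.mean(), 1e-9)],
                                 bounds=(1e-12, np.inf), maxfev=10000)
    return float(popt[0])

def _em_exp_mixture(x, n_iter=200, tol=1e-10):
    """Maximum-likelihood EM for a two-component exponential mixture; the
    fitted weight estimates the population fraction the classification rule
    speaks about.  Returns (a, t1, t2, log_likelihood)."""
    lo, hi = x[x <= np.median(x)], x[x > np.median(x)]
    a, t1, t2 = 0.5, max(lo.mean(), 1e-12), max(hi.mean(), 1e-12)
    ll = prev = -np.inf
    for _ in range(n_iter):
        f1 = a * np.exp(-x / t1) / t1
        f2 = (1 - a) * np.exp(-x / t2) / t2
        tot = f1 + f2
        ll = float(np.log(tot).sum())
        r = f1 / tot
        a = float(r.mean())
        if a in (0.0, 1.0):
            break
        t1 = float((r * x).sum() / r.sum())
        t2 = float(((1 - r) * x).sum() / (1 - r).sum())
        if abs(ll - prev) < tol * abs(ll):
            break
        prev = ll
    if t1 > t2:
        a, t1, t2 = 1 - a, t2, t1
    return a, t1, t2, ll


def _fit_double(ts, F):
    def f(t, a, t1, t2):
        return a * (1.0 - np.exp(-t / t1)) + (1 - a) * (1.0 - np.exp(-t / t2))
    # EM locates the population-fraction basin; least squares on the ECDF
    # then polishes within it (unweighted ECDF SSE alone over-weights the
    # bulk and can prefer spurious splits of a single component)
    a0, t10, t20, _ = _em_exp_mixture(ts)
    try:
        popt, _ = optimize.curve_fit(
            f, ts, F, p0=[min(max(a0, 1e-3), 1 - 1e-3), t10, t20],
            bounds=([0.0, 1e-12, 1e-12], [1.0, np.inf, np.inf]),
            maxfev=20000)
        a, t1, t2 = popt
    except RuntimeError:
        a, t1, t2 = a0, t10, t20
    if t1 > t2:
        a, t1, t2 = 1 - a, t2, t1
    return float(a), float(t1), float(t2)


def fit_exponential(durations, censored=None, model: str = "auto",
                    n_boot: int = 200, seed: int = 0, min_n: int = 20) -> ExpFit:
    """Fit completed dwell times to exponential kinetics via their ECDF.

    The empirical CDF of uncensored dwells is fitted by non-linear least
    squares to 1 - exp(-t/tau) and, when ``model='auto'`` or ``'double'``,
    to a two-component mixture.  If the initial double fit yields a minor
    population below 10 %, the data are classified as single-exponential and
    the single-fit parameters reported.  95 % CIs come from a parametric
    bootstrap (seeded, ``n_boot`` resamples).
    """
    durations = np.asarray(durations, dtype=float)
    if censored is not None:
        keep = ~np.asarray(censored, dtype=bool)
        durations = durations[keep]
    if durations.size < min_n:
        raise ValueError(f"need at least {min_n} completed dwells, got {durations.size}")
    ts, F = _ecdf(durations)

    tau_s = _fit_single(ts, F)
    minor = None
    chosen = "single"
    params: tuple = (tau_s,)
    amps: tuple = (1.0,)
    rule = False
    if model in ("auto", "double"):
        try:
            a_em, t1_em, t2_em, ll_mix = _em_exp_mixture(np.sort(durations))
            # the classification amplitude is the maximum-likelihood
            # population fraction, not the ECDF-ridge amplitude
            minor = float(min(a_em, 1.0 - a_em))
            n = durations.size
            tau_ml = durations.mean()
            ll_single = float(-n * np.log(tau_ml) - n)
            # a second component is resolvable only when it improves the
            # likelihood beyond its two extra parameters and the two time
            # constants actually differ
            resolvable = (2 * (ll_mix - ll_single) > 2 * np.log(n)
                          and t2_em / t1_em >= 1.2)
            if model == "double" or (resolvable and minor >= 0.10):
                a, t1, t2 = _fit_double(ts, F)
                chosen, params, amps = "double", (t1, t2), (a, 1 - a)
            else:
                rule = resolvable and minor < 0.10  # <10 % population rule
        except (RuntimeError, FloatingPointError):
            minor = None

    rng = np.random.default_rng(seed)
    boot: dict[str, list] = {f"tau{i+1}": [] for i in range(len(params))}
    n = durations.size
    for _ in range(n_boot):
        if chosen == "single":
            sample = rng.exponential(params[0], n)
        else:
            comp = rng.random(n) < amps[0]
            sample = np.where(comp, rng.exponential(params[0], n),
                              rng.exponential(params[1], n))
        bts, bF = _ecdf(sample)
        try:
            if chosen == "single":
                boot["tau1"].append(_fit_single(bts, bF))
            else:
                _, b1, b2 = _fit_double(bts, bF)
                boot["tau1"].append(b1)
                boot["tau2"].append(b2)
        except RuntimeError:
            continue
    ci = {k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
          for k, v in boot.items() if v}
    return ExpFit(model=chosen, taus=params, amplitudes=amps,
                  minor_amplitude=minor, ci95=ci, n=int(n),
                  classified_single_by_rule=rule)


# ---------------------------------------------------------------------------
# per-codon statistics
# ---------------------------------------------------------------------------

def codon_dwell_stats(tables: dict[str, pd.DataFrame],
                      max_codon: int | None = None) -> pd.DataFrame:
    """Box-plot statistics of dwell times per codon, state and condition,
    with two-sided Wilcoxon-Mann-Whitney comparisons between conditions.

    Returns one row per (condition, state, codon): n, median, quartiles and
    1.5xIQR whisker bounds; when exactly two conditions are given a
    ``p_value`` column holds the rank-sum p for that (state, codon) cell.
    """
    rows = []
    for cond, tab in tables.items():
        sub = tab[tab["state"].isin(["non_rotated", "rotated"])].copy()
        # rotated dwells inherit the codon of the preceding incorporation
        sub["codon_index"] = (sub.groupby("molecule_id")["codon_index"]
                              .ffill())
        sub = sub.dropna(subset=["codon_index"])
        for (state, codon), grp in sub.groupby(["state", "codon_index"]):
            if max_codon is not None and codon > max_codon:
                continue
            d = grp["duration_s"].to_numpy()
            q1, med, q3 = np.percentile(d, [25, 50, 75])
            iqr = q3 - q1
            rows.append({"condition": cond, "state": state,
                         "codon_index": int(codon), "n": len(d),
                         "median": med, "q1": q1, "q3": q3,
                         "whisker_low": max(d.min(), q1 - 1.5 * iqr),
                         "whisker_high": min(d.max(), q3 + 1.5 * iqr)})
    out = pd.DataFrame(rows)
    conds = list(tables)
    if len(conds) == 2 and not out.empty:
        pvals = []
        for _, row in out.iterrows():
            samples = []
            for cond in conds:
                tab = tables[cond]
                sub = tab[tab["state"].isin(["non_rotated", "rotated"])].copy()
                sub["codon_index"] = (sub.groupby("molecule_id")["codon_index"].ffill())
                sel = sub[(sub["state"] == row["state"])
                          & (sub["codon_index"] == row["codon_index"])]
                samples.append(sel["duration_s"].to_numpy())
            a, b = samples
            if len(a) == 0 or len(b) == 0:
                pvals.append(np.nan)
            elif np.unique(np.concatenate([a, b])).size == 1:
                pvals.append(1.0)  # degenerate: identical constant samples
            else:
                pvals.append(float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue))
        out["p_value"] = pvals
    return out
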