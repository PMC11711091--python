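"""End-to-end pipeline orchestration.

Runs simulate -> correct -> assign -> dwell/coupling/transcription/gel
analyses from a single config dict (YAML-loadable), writes every
intermediate table, a machine-readable ``results.json`` and a run log that
records every parameter and every automated correction, and is byte-for-byte
deterministic given the same config and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import coupling as cp
from . import dwells as dw
from . import gelkinetics as gel
from . import states as st
from . import synthgen as sg
from . import traceio as tio
from . import txnkinetics as txn

__all__ = [
    "ConfigError",
    "EmptyDataError",
    "run_pipeline",
    "run_translation_analysis",
    "run_coupling_analysis",
    "simulate_to_dir",
    "write_results",
]

RESULTS_SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class EmptyDataError(ValueError):
    """Empty or unusable input data (CLI exit code 3)."""


def _round_floats(obj, ndigits=10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return round(v, ndigits) if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_results(results: dict, path: Path) -> None:
    """Deterministic JSON: sorted keys, rounded floats, fixed separators."""
    payload = {"schema_version": RESULTS_SCHEMA_VERSION, **_round_floats(results)}
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def _sim_config(block: dict, seed: int) -> sg.SimConfig:
    known = sg.SimConfig.__dataclass_fields__
    unknown = set(block) - set(known)
    if unknown:
        raise ConfigError(f"unknown simulate parameters: {sorted(unknown)}")
    block = dict(block)
    if "rate_matrix" in block and block["rate_matrix"] is not None:
        block["rate_matrix"] = np.asarray(block["rate_matrix"], dtype=float)
    for key in ("state_fret_means", "dwell_means", "codon_schedule",
                "fluct_rates", "initial_probs"):
        if key in block and block[key] is not None:
            block[key] = tuple(block[key])
    try:
        return sg.SimConfig(seed=seed, **block)
    except ValueError as err:
        raise ConfigError(str(err)) from err


def simulate_to_dir(config: dict, outdir: Path, seed: int):
    """Simulate a dataset, write the trace CSV + sidecar and ground truth."""
    cfg = _sim_config(config.get("simulate", {}), seed)
    traces, truths = sg.simulate_dataset(cfg)
    outdir.mkdir(parents=True, exist_ok=True)
    tio.write_traces(traces, outdir / "traces.csv")
    gt = {tr.molecule_id: {
        "bleach_frames": truth.bleach_frames,
        "dwells": _round_floats(truth.dwells.to_dict("list")),
        "transcription_end_frame": truth.transcription_end_frame,
        "initial_state": truth.initial_state,
    } for tr, truth in zip(traces, truths)}
    (outdir / "ground_truth.json").write_text(json.dumps(gt, indent=1, sort_keys=True))
    return traces, truths


# ---------------------------------------------------------------------------
# translation pipeline
# ---------------------------------------------------------------------------

def run_translation_analysis(traces, params: dict | None = None, seed: int = 0):
    """Two-colour translation analysis: correct -> FRET -> 2-state HMM ->
    decode -> dwells -> fluctuation filter -> exponential fits -> per-codon
    stats.  Returns (results dict, dwell table, log)."""
    params = params or {}
    corr = tio.CorrectionParams(l=params.get("leakage_l", 0.0),
                                d=params.get("direct_d", 0.0),
                                gamma=params.get("gamma", 1.0))
    log: list[dict] = [{"stage": "correct", "params": {"l": corr.l, "d": corr.d,
                                                       "gamma": corr.gamma}}]
    fret_list = []
    for tr in traces:
        ctr = tio.correct_trace(tr, corr)
        total = ctr.channels["donor_em"] + ctr.channels["acceptor_em"]
        try:
            donor_bleach = tio.detect_photobleach(total)
            acceptor_bleach = tio.detect_photobleach(ctr.channels["acceptor_em"])
        except ValueError:
            continue
        window = tio.select_evaluation_window(ctr, donor_bleach, acceptor_bleach)
        fret_list.append(tio.compute_fret(ctr, corr, window=window))
    fret_list = [f for f in fret_list if f.windowed().size >= params.get("min_frames", 20)]
    if not fret_list:
        raise EmptyDataError("no usable traces after window selection")

    K = params.get("n_states", 2)
    model = st.fit_hmm(fret_list, K, seed=seed)
    log.append({"stage": "hmm", "model": model.to_dict()})
    names = dw.translation_state_names(model.means)

    tables = []
    for f in fret_list:
        path = st.decode(model, f)
        if len(path) == 0:
            continue
        tables.append(dw.extract_dwells(path, state_names=names))
    if not tables:
        raise EmptyDataError("no state paths decoded")
    table = pd.concat(tables, ignore_index=True)

    thresholds = params.get("fluct_thresholds")
    if thresholds == "auto":
        # elongating reference data: thresholds are its own 5%/1% tiles
        ref = table[(table["state"] == "non_rotated")
                    & (table["censored"] == "none")]["duration_s"].to_numpy()
        thresholds = (dw.percentile_threshold(ref, 0.05),
                      dw.percentile_threshold(ref, 0.01))
    if thresholds is not None:
        table, edits = dw.fluctuation_filter(table, *thresholds)
        log.append({"stage": "fluctuation_filter", "thresholds": list(thresholds),
                    "n_edits": len(edits), "edits": edits})

    results: dict = {"n_traces": len(fret_list),
                     "hmm": model.to_dict(),
                     "state_names": {str(k): v for k, v in names.items()}}
    if thresholds is not None:
        results["fluct_thresholds_s"] = list(thresholds)
    for state in ("non_rotated", "rotated"):
        sub = table[(table["state"] == state) & (table["censored"] == "none")]
        if len(sub) >= 20:
            fit = dw.fit_exponential(sub["duration_s"].to_numpy(),
                                     n_boot=params.get("n_boot", 50), seed=seed)
            results[f"{state}_dwell_fit"] = {
                "model": fit.model, "taus_s": list(fit.taus),
                "amplitudes": list(fit.amplitudes), "n": fit.n,
                "minor_amplitude": fit.minor_amplitude, "ci95": fit.ci95}
    stats_df = dw.codon_dwell_stats({"dataset": table},
                                    max_codon=params.get("max_codon"))
    results["per_codon"] = _round_floats(stats_df.to_dict("records"))
    return results, table, log


# ---------------------------------------------------------------------------
# coupling pipeline
# ---------------------------------------------------------------------------

def run_coupling_analysis(traces, params: dict | None = None, seed: int = 0):
    """ALEX coupling analysis: deinterleave -> window on acceptor-direct
    survival -> correct -> FRET -> HMM (K states) -> classify -> coupled
    fraction, lifetimes and recoupling rate."""
    params = params or {}
    corr = tio.CorrectionParams(l=params.get("leakage_l", 0.0),
                                d=params.get("direct_d", 0.0),
                                gamma=params.get("gamma", 1.0))
    min_alive_s = params.get("min_alive_s", 100.0)
    log: list[dict] = [{"stage": "correct", "params": {"l": corr.l, "d": corr.d,
                                                       "gamma": corr.gamma,
                                                       "min_alive_s": min_alive_s}}]
    fret_list = []
    for tr in traces:
        if tr.alex is not None:
            donor_exc, acceptor_exc = tio.deinterleave_alex(tr)
        else:
            donor_exc, acceptor_exc = tr, None
        ctr = tio.correct_trace(donor_exc, corr)
        acc_direct_bleach = None
        if acceptor_exc is not None:
            try:
                acc_direct_bleach = tio.detect_photobleach(
                    acceptor_exc.channels["acceptor_direct"])
            except ValueError:
                pass
        total = ctr.channels["donor_em"] + ctr.channels["acceptor_em"]
        try:
            donor_bleach = tio.detect_photobleach(total)
        except ValueError:
            donor_bleach = None
        window = tio.select_evaluation_window(
            ctr, donor_bleach, acc_direct_bleach,
            acceptor_direct_bleach=acc_direct_bleach,
            min_alive_s=min_alive_s if acceptor_exc is not None else None)
        if window is None:
            continue
        fret_list.append(tio.compute_fret(ctr, corr, window=window))
    fret_list = [f for f in fret_list if f.windowed().size >= params.get("min_frames", 20)]
    if not fret_list:
        raise EmptyDataError("no usable traces after ALEX window selection")

    K = params.get("n_states")
    if K is None:
        K, scores = st.select_model(fret_list, params.get("k_max", 4), seed=seed)
        log.append({"stage": "model_selection", "K": K, "bic": scores})
    model = st.fit_hmm(fret_list, K, seed=seed)
    log.append({"stage": "hmm", "model": model.to_dict()})

    pooled = np.concatenate([f.windowed() for f in fret_list])
    gmm = cp.fit_fret_histogram(pooled, K, seed=seed)
    boundaries = tuple(params.get("boundaries", cp.DEFAULT_BOUNDARIES))
    state_classes = cp.classify_states(model.means, boundaries)

    coupled_flags, coupled_durs, coupled_cens, unc_durs, unc_cens = [], [], [], [], []
    occupancy_frames = {c: 0 for c in cp.CLASS_NAMES}
    for f in fret_list:
        path = st.decode(model, f)
        if len(path) == 0:
            continue
        classes = state_classes[path.labels]
        for c in cp.CLASS_NAMES:
            occupancy_frames[c] += int(np.sum(classes == c))
        coupled_flags.append(bool(cp.is_coupled_superclass([classes[0]])[0]))
        table = dw.extract_dwells(path)
        super_lab = cp.is_coupled_superclass(
            state_classes[[int(s.split("_")[1]) for s in table["state"]]])
        # merge adjacent superclass dwells
        durs, cens, labs = [], [], []
        for is_c, dur, c_flag in zip(super_lab, table["duration_s"],
                                     table["censored"]):
            if labs and labs[-1] == is_c:
                durs[-1] += dur
                cens[-1] = cens[-1] or c_flag != "none"
            else:
                labs.append(bool(is_c))
                durs.append(float(dur))
                cens.append(c_flag != "none")
        for is_c, dur, c_flag in zip(labs, durs, cens):
            if is_c:
                coupled_durs.append(dur)
                coupled_cens.append(c_flag)
            else:
                unc_durs.append(dur)
                unc_cens.append(c_flag)

    frac, se = cp.coupled_fraction(coupled_flags)
    total_frames = sum(occupancy_frames.values())
    occupancies = {c: occupancy_frames[c] / total_frames for c in cp.CLASS_NAMES}
    median_lt, lower_bound = (cp.coupled_lifetimes(coupled_durs, coupled_cens)
                              if coupled_durs else (None, False))
    recoup = None
    n_completed_unc = int(np.sum(~np.asarray(unc_cens, bool))) if unc_durs else 0
    if n_completed_unc >= 20:
        recoup = cp.recoupling_rate(np.asarray(unc_durs), np.asarray(unc_cens),
                                    n_boot=params.get("n_boot", 50), seed=seed)

    results = {
        "n_traces": len(coupled_flags),
        "hmm": model.to_dict(),
        "gmm": gmm.to_dict(),
        "boundaries": list(boundaries),
        "state_classes": state_classes.tolist(),
        "fraction_coupled": frac,
        "fraction_coupled_se": se,
        "occupancies": occupancies,
        "median_coupled_lifetime_s": median_lt,
        "lifetime_is_lower_bound": lower_bound,
        "recoupling": ({"tau_s": recoup.taus[0], "n": recoup.n,
                        "ci95": recoup.ci95} if recoup else None),
    }
    return results, log


# ---------------------------------------------------------------------------
# top-level runner
# ---------------------------------------------------------------------------

def run_pipeline(config: dict, outdir: str | Path, seed: int | None = None) -> dict:
    """Run the configured scheme end to end and write a report bundle.

    Emits ``traces.csv(+json)``, ``ground_truth.json``, ``dwells.tsv`` (when
    applicable), ``results.json`` and ``run_log.json`` under ``outdir``.
    Deterministic given config + seed.
    """
    if not isinstance(config, dict) or "scheme" not in config:
        raise ConfigError("config must be a mapping with a 'scheme' key")
    scheme = config["scheme"]
    seed = int(seed if seed is not None else config.get("seed", 0))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = [{"stage": "config", "scheme": scheme, "seed": seed,
                        "config": _round_floats(config)}]
    results: dict = {"scheme": scheme, "seed": seed}

    if scheme in ("translation_2state", "coupling_multistate"):
        sim_block = dict(config.get("simulate", {}))
        sim_block.setdefault("kinetic_scheme", scheme)
        if scheme == "coupling_multistate":
            sim_block.setdefault("alex", True)
        traces, _ = simulate_to_dir({"simulate": sim_block}, outdir, seed)
        if not traces:
            raise EmptyDataError("simulation produced no traces")
        analysis = config.get("analysis", {})
        if scheme == "translation_2state":
            res, table, alog = run_translation_analysis(traces, analysis, seed=seed)
            table.to_csv(outdir / "dwells.tsv", sep="\t", index=False,
                         float_format="%.6g")
        else:
            res, alog = run_coupling_analysis(traces, analysis, seed=seed)
        results.update(res)
        log.extend(alog)
    elif scheme == "transcription_times":
        block = config.get("transcription", {})
        times = sg.simulate_transcription_times(
            n=int(block.get("n", 500)), mu=float(block.get("mu", 60.0)),
            sigma=float(block.get("sigma", 8.0)), tau=float(block.get("tau", 15.0)),
            seed=seed)
        pd.DataFrame({"molecule_id": [f"m{i:05d}" for i in range(len(times))],
                      "time_s": times, "censored": False}).to_csv(
            outdir / "transcription_times.tsv", sep="\t", index=False,
            float_format="%.6g")
        fit = txn.fit_emg(times, n_boot=int(block.get("n_boot", 50)), seed=seed)
        results.update({"emg": {"mu_s": fit.mu, "sigma_s": fit.sigma,
                                "tau_s": fit.tau, "mean_s": fit.mean,
                                "n": fit.n, "ci95": fit.ci95},
                        "median_s": float(np.median(times))})
        if "template_nt" in block:
            results["rate_nt_per_s"] = txn.transcription_rate(
                int(block["template_nt"]), fit.mu)
        log.append({"stage": "fit_emg", "n": fit.n})
    elif scheme == "gel":
        block = config.get("gel", {})
        if "input" in block:
            table = pd.read_csv(block["input"])
        else:
            table = sg.simulate_gel_timecourse(
                pause_lifetimes=block.get("pause_lifetimes", [182.0]),
                amplitudes=block.get("amplitudes", [0.5]),
                timepoints=block.get("timepoints",
                                     [0, 10, 20, 30, 40, 60, 90, 120, 180, 240, 360, 600]),
                noise_cv=float(block.get("noise_cv", 0.05)),
                seed=seed, n_replicates=int(block.get("n_replicates", 2)))
            table.to_csv(outdir / "gel_timecourse.csv", index=False,
                         float_format="%.6g")
        if table.empty:
            raise EmptyDataError("empty gel table")
        fit_range = tuple(block.get("fit_range", (20.0, 600.0)))
        bands = block.get("bands") or sorted(
            b for b in table["band"].unique() if b != "full_length")
        results["pause_escape"] = {}
        for band in bands:
            summary = gel.fit_pause_escape_replicates(table, band, fit_range)
            results["pause_escape"][band] = {
                "lifetime_s": summary["lifetime_s"],
                "half_range_s": summary["half_range_s"],
                "fit_range": list(fit_range),
                "replicates": {str(r): {"slope": f.slope, "r_squared": f.r_squared,
                                        "lifetime_s": f.lifetime_s,
                                        "n_points": f.n_points}
                               for r, f in summary["replicates"].items()}}
        log.append({"stage": "gel_fit", "bands": list(bands),
                    "fit_range": list(fit_range)})
    else:
        raise ConfigError(f"unknown scheme {scheme!r}")

    write_results(results, outdir / "results.json")
    (outdir / "run_log.json").write_text(
        json.dumps(_round_floats(log), indent=1, sort_keys=True) + "\n")
    return results
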