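"""Bulk single-round transcription time courses: pause-escape kinetics.

Gel band intensities P are normalised by the total RNA per lane T (which
compensates pipetting differences); the pause band then decays as
P/T(t) = A exp(-t/lifetime), so an ordinary least-squares line through
ln(P/T) versus time inside the user-chosen pause-escape range has slope
m = -1/lifetime.  Replicates are fitted independently and summarised as
mean +/- half-range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PauseEscapeFit",
    "normalize_bands",
    "fit_pause_escape",
    "fit_pause_escape_replicates",
    "compare_escape",
]


@dataclass
class PauseEscapeFit:
    slope: float                 # s^-1 (the pause-escape rate is -slope)
    intercept: float
    slope_se: float
    r_squared: float
    fit_range: tuple[float, float]
    n_points: int
    lifetime_s: float | None     # -1/slope, only when slope < 0
    excluded_points: list = field(default_factory=list)

    @property
    def lifetime_defined(self) -> bool:
        return self.lifetime_s is not None


def normalize_bands(P, T) -> np.ndarray:
    """Elementwise P/T; every lane total must be positive."""
    P = np.asarray(P, dtype=float)
    T = np.asarray(T, dtype=float)
    if P.shape != T.shape:
        raise ValueError("P and T must have equal length")
    bad = np.flatnonzero(T <= 0)
    if bad.size:
        raise ValueError(f"non-positive total RNA in lane(s) {bad.tolist()}")
    return P / T


def fit_pause_escape(timepoints, p_over_t, fit_range: tuple[float, float]
                     ) -> PauseEscapeFit:
    """OLS of ln(P/T) against time within the pause-escape range.

    Zero or negative P/T points inside the range are excluded (recorded in
    ``excluded_points``); at least 3 usable points are required.  The fit
    range is an explicit input: pause-escape windows are dataset-specific
    and must be chosen by the analyst.
    """
    t = np.asarray(timepoints, dtype=float)
    r = np.asarray(p_over_t, dtype=float)
    lo, hi = fit_range
    inside = (t >= lo) & (t <= hi)
    usable = inside & (r > 0)
    excluded = [(float(ti), float(ri)) for ti, ri in zip(t[inside & ~usable],
                                                         r[inside & ~usable])]
    if usable.sum() < 3:
        raise ValueError("need at least 3 usable points inside the fit range")
    res = stats.linregress(t[usable], np.log(r[usable]))
    lifetime = float(-1.0 / res.slope) if res.slope < 0 else None
    return PauseEscapeFit(slope=float(res.slope), intercept=float(res.intercept),
                          slope_se=float(res.stderr),
                          r_squared=float(res.rvalue ** 2),
                          fit_range=(float(lo), float(hi)),
                          n_points=int(usable.sum()), lifetime_s=lifetime,
                          excluded_points=excluded)


def fit_pause_escape_replicates(gel_table: pd.DataFrame, band: str,
                                fit_range: tuple[float, float]) -> dict:
    """Fit each biological replicate independently and summarise the
    lifetime as mean +/- half-range across replicates."""
    sub = gel_table[gel_table["band"] == band]
    if sub.empty:
        raise ValueError(f"no rows for band {band!r}")
    fits = {}
    lifetimes = []
    for rep, grp in sub.groupby("replicate"):
        ratio = normalize_bands(grp["P"].to_numpy(), grp["T"].to_numpy())
        fit = fit_pause_escape(grp["time_s"].to_numpy(), ratio, fit_range)
        fits[rep] = fit
        if fit.lifetime_defined:
            lifetimes.append(fit.lifetime_s)
    if not lifetimes:
        raise ValueError("no replicate yielded a defined lifetime")
    mean = float(np.mean(lifetimes))
    half_range = float((max(lifetimes) - min(lifetimes)) / 2)
    return {"band": band, "lifetime_s": mean, "half_range_s": half_range,
            "replicates": fits}


def compare_escape(fit_a: PauseEscapeFit, fit_b: PauseEscapeFit) -> dict:
    """Lifetime ratio A/B with the error propagated from the slope SEs."""
    if not (fit_a.lifetime_defined and fit_b.lifetime_defined):
        raise ValueError("both fits must have a defined lifetime (negative slope)")
    ratio = fit_a.lifetime_s / fit_b.lifetime_s
    rel = np.sqrt((fit_a.slope_se / fit_a.slope) ** 2
                  + (fit_b.slope_se / fit_b.slope) ** 2)
    return {"ratio": float(ratio), "ratio_se": float(abs(ratio) * rel),
            "lifetime_a_s": fit_a.lifetime_s, "lifetime_b_s": fit_b.lifetime_s}
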