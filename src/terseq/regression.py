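"""Operon-level TER and delay from CI-weighted regression of bin delays.

The polymerase wave makes a bin's onset delay affine in its transcript
position: ``T_d(p) = delay + p / TER``.  Weighted least squares of the
fitted bin delays on the mean bin positions (weights = inverse squared
95%-CI half-width) therefore yields the operon's average elongation
rate as the inverse slope and its initiation delay as the intercept.
Negative intercepts are reported as-is; clipping to zero happens only in
cohort summaries and histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .kinetics import BinDelayEstimate

__all__ = ["OperonTER", "InsufficientBinsError", "fit_ter", "summarize_ters",
           "ters_to_frame"]

# CI half-widths below this floor (s) are raised to it: onset times are
# not resolvable below a fraction of the sampling resolution, so exact
# (zero-width) intervals from noise-free data get finite, equal weights
# instead of infinite ones.
HALFWIDTH_FLOOR_S = 0.5


class InsufficientBinsError(ValueError):
    """Fewer than the minimum number of usable bins for a regression."""


@dataclass
class OperonTER:
    """Regression result for one operon."""

    operon: str
    ter: float  # nt/s; nan when the wave is not detected
    delay: float  # s, may be negative
    slope: float  # s/nt
    intercept: float  # s
    n_bins_used: int
    r_squared: float
    direction: str = "increase"
    flags: tuple[str, ...] = ()


# Bins whose bootstrap delay distribution piles onto the search
# boundary beyond this fraction carry no usable onset information.
BOUNDARY_FRAC_MAX = 0.5
# Cap on inverse-variance weights, as a multiple of the median weight:
# a single spuriously narrow CI must not dominate the regression.
WEIGHT_CAP = 50.0
# Robust-z cutoff for the trimming prepass; tight because an operon
# contributes at most ~15 bins and the bin-delay error is heavy-tailed.
TRIM_Z = 2.0
# Slope t-statistic below which a positive slope is considered a weak,
# low-confidence wave.
WEAK_WAVE_T = 2.0


def fit_ter(estimates: Sequence[BinDelayEstimate],
            operon: str = "",
            min_bins: int = 3,
            halfwidth_floor: float = HALFWIDTH_FLOOR_S,
            trim: float | None = TRIM_Z,
            boundary_frac_max: float = BOUNDARY_FRAC_MAX,
            weight_cap: float = WEIGHT_CAP) -> OperonTER:
    """Weighted regression of bin delays on bin midpoints.

    Weight per bin is 1 / (95% CI half-width)^2 (inverse variance, with
    a floor, capped at ``weight_cap`` times the median weight).  Bins
    whose bootstrap delays sat on the search boundary more than
    ``boundary_frac_max`` of the time are excluded as non-identifiable.
    With ``trim`` set, a Huber regression prepass drops bins whose
    residual exceeds ``trim`` robust standard deviations before the
    final WLS — the bin-delay error distribution is heavy-tailed and a
    single gross outlier otherwise corrupts the slope.  ``trim=None``
    fits all usable bins (the plain WLS contract).

    TER = 1/slope when the slope is positive; a non-positive slope
    means no 5'->3' wave was detected and is flagged ``no_wave`` instead
    of inverted; a positive slope whose t-statistic is below 2 is
    flagged ``weak_wave``.
    """
    usable = [e for e in estimates
              if np.isfinite(e.T_d_hat) and np.isfinite(e.ci_halfwidth)
              and e.boundary_frac <= boundary_frac_max]
    if len(usable) < min_bins:
        raise InsufficientBinsError(
            f"{operon or 'operon'}: {len(usable)} usable bins < {min_bins}")
    x = np.array([e.bin_midpoint for e in usable])
    y = np.array([e.T_d_hat for e in usable])
    hw = np.array([max(e.ci_halfwidth, halfwidth_floor) for e in usable])
    w = 1.0 / hw**2
    w = np.minimum(w, weight_cap * np.median(w))

    keep = np.ones(x.size, dtype=bool)
    flags: list[str] = []
    if trim is not None and x.size > min_bins:
        rlm = sm.RLM(y, sm.add_constant(x), M=sm.robust.norms.HuberT()).fit()
        r = y - rlm.fittedvalues
        scale = 1.4826 * np.median(np.abs(r - np.median(r)))
        if scale <= 0:
            # most bins sit exactly on the line: anything off it is an outlier
            keep = np.abs(r) <= 1e-9 * max(1.0, float(np.max(np.abs(y))))
        else:
            keep = np.abs(r) <= trim * scale
        if keep.sum() < min_bins:
            keep = np.ones(x.size, dtype=bool)
        elif not keep.all():
            flags.append("trimmed")

    res = sm.WLS(y[keep], sm.add_constant(x[keep]), weights=w[keep]).fit()
    intercept, slope = float(res.params[0]), float(res.params[1])
    slope_se = float(res.bse[1])
    if slope > 0:
        ter = 1.0 / slope
        if slope_se > 0 and slope / slope_se < WEAK_WAVE_T:
            flags.append("weak_wave")
    else:
        ter = float("nan")
        flags.append("no_wave")
    directions = {e.params.direction for e in usable}
    direction = usable[0].params.direction if len(directions) == 1 else "mixed"
    return OperonTER(operon=operon or "operon", ter=ter, delay=intercept,
                     slope=slope, intercept=intercept,
                     n_bins_used=int(keep.sum()), r_squared=float(res.rsquared),
                     direction=direction, flags=tuple(flags))


def summarize_ters(results: Sequence[OperonTER]) -> dict:
    """Cohort summary of TERs and delays.

    Quantiles use linear interpolation.  Delay statistics follow the
    histogram convention: negative operon delays (regression intercepts
    slightly below zero) are clipped to 0, i.e. immediate initiation.
    """
    if len(results) == 0:
        raise ValueError("no results to summarize")
    ters = np.array([r.ter for r in results if np.isfinite(r.ter)])
    delays = np.array([r.delay for r in results if np.isfinite(r.ter)])
    delays_clipped = np.clip(delays, 0.0, None)

    def stats(v: np.ndarray) -> dict:
        return {
            "mean": float(np.mean(v)),
            "median": float(np.median(v)),
            "q10": float(np.quantile(v, 0.10, method="linear")),
            "q90": float(np.quantile(v, 0.90, method="linear")),
        }

    return {
        "n_operons": int(ters.size),
        "ter": stats(ters),
        "delay": stats(delays_clipped),
        "n_negative_delays": int(np.sum(delays < 0)),
    }


def ters_to_frame(results: Sequence[OperonTER]) -> pd.DataFrame:
    """Per-operon results table (TSV-ready)."""
    return pd.DataFrame([{
        "operon": r.operon, "ter_nt_s": r.ter, "delay_s": r.delay,
        "slope_s_nt": r.slope, "n_bins": r.n_bins_used,
        "r_squared": r.r_squared, "direction": r.direction,
        "flags": ";".join(r.flags),
    } for r in results])
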