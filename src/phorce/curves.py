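"""Growth-curve analysis: growth-rate fits and collapse detection.

Operates on per-well time series of a bacterial population proxy
(bioluminescence or optical density, arbitrary units).  The growth rate is
the slope of a log-linear fit restricted to the steady-state exponential
window (t > 0.5 h, signal < 1e6 AU by default); the collapse is the first
prominent local maximum of the signal; its uncertainty comes from case
bootstrap of the time series.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import linregress

__all__ = [
    "GrowthCurve",
    "GrowthFit",
    "CollapseEstimate",
    "BootstrapResult",
    "InsufficientDataError",
    "fit_growth_rate",
    "estimate_b0_proxy",
    "B0Proxy",
    "detect_collapse",
    "bootstrap_collapse_se",
]

logger = logging.getLogger("phorce")

MIN_SAMPLES = 8  # curves shorter than this are not analyzable


class InsufficientDataError(ValueError):
    """Too few usable samples for the requested fit."""


@dataclass
class GrowthCurve:
    """One well's time series of a population signal.

    ``condition`` is free-form metadata (typically the plate-layout row or
    the synthetic generator's ground-truth record).
    """

    times: np.ndarray
    signal: np.ndarray
    readout: str = "bioluminescence"
    well_id: str = ""
    condition: Optional[dict] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape:
            raise ValueError("times and signal must have the same length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"times must be strictly increasing (well {self.well_id!r})")
        if np.any(self.signal < 0):
            raise ValueError(f"signal must be non-negative (well {self.well_id!r})")
        if self.readout not in ("bioluminescence", "optical_density"):
            raise ValueError(f"unknown readout {self.readout!r}")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class GrowthFit:
    """Result of the log-linear growth fit."""

    r_bac: float            #: slope of ln(signal) vs t, h^-1
    log_intercept: float    #: ln(signal) extrapolated to t = 0
    fit_window: tuple       #: (t_min, signal_max) actually applied
    se_r_bac: float         #: standard error of the slope, h^-1
    n_points: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.r_bac):
            raise ValueError("fitted growth rate is not finite")


@dataclass
class CollapseEstimate:
    """A detected (or censored) population collapse."""

    t_col: float                    #: peak time, h (nan when censored)
    signal_at_collapse: float       #: signal at the peak, AU
    se_t_col: float = float("nan")  #: bootstrap standard error, h
    censored: bool = False          #: no qualifying peak found
    excluded: bool = False          #: peak outside the steady-state regime
    wide_uncertainty: bool = False  #: >50% of bootstrap replicates censored

    @property
    def usable(self) -> bool:
        return not (self.censored or self.excluded)


class B0Proxy(float):
    """Initial-concentration proxy; ``semi_quantitative`` marks AU-only values."""

    semi_quantitative: bool

    def __new__(cls, value: float, semi_quantitative: bool):
        obj = super().__new__(cls, value)
        obj.semi_quantitative = semi_quantitative
        return obj


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap uncertainty of a collapse time."""

    se_t_col: float
    censored_fraction: float
    wide_uncertainty: bool
    n_boot: int


def fit_growth_rate(
    curve: GrowthCurve,
    t_min: float = 0.5,
    signal_max: float = 1e6,
) -> GrowthFit:
    """Least-squares line on (t, ln signal) inside the exponential window.

    Points with ``t <= t_min`` or ``signal >= signal_max`` are excluded;
    non-positive signals are dropped (with a logged count) rather than
    floored.  The slope is the bacterial growth rate; the intercept
    estimates the initial-concentration proxy.
    """
    if len(curve) < MIN_SAMPLES:
        raise InsufficientDataError(
            f"well {curve.well_id!r}: need >= {MIN_SAMPLES} samples, got {len(curve)}"
        )
    positive = curve.signal > 0
    n_dropped = int((~positive).sum())
    if n_dropped:
        logger.info("well %r: dropped %d non-positive signal values", curve.well_id, n_dropped)
    mask = positive & (curve.times > t_min) & (curve.signal < signal_max)
    if mask.sum() < 4:
        raise InsufficientDataError(
            f"well {curve.well_id!r}: only {int(mask.sum())} usable points in the fit window"
        )
    res = linregress(curve.times[mask], np.log(curve.signal[mask]))
    return GrowthFit(
        r_bac=float(res.slope),
        log_intercept=float(res.intercept),
        fit_window=(t_min, signal_max),
        se_r_bac=float(res.stderr),
        n_points=int(mask.sum()),
    )


def estimate_b0_proxy(fit: GrowthFit, scale: Optional[float] = None) -> B0Proxy:
    """Initial-concentration estimate from the fit intercept.

    Returns ``exp(log_intercept)`` in AU, multiplied by ``scale``
    (cells mL^-1 per AU) when a calibration factor is supplied.  Without a
    calibration the value is flagged semi-quantitative: only ratios between
    wells sharing the readout are meaningful.
    """
    value = math.exp(fit.log_intercept)
    if scale is None:
        return B0Proxy(value, semi_quantitative=True)
    return B0Proxy(value * scale, semi_quantitative=False)


def detect_collapse(
    curve: GrowthCurve,
    smooth_width: int = 4,
    steady_state_max: float = 3e5,
    prominence_frac: float = 0.1,
) -> CollapseEstimate:
    """Locate the phage-induced collapse as the first prominent signal peak.

    A peak qualifies when its width is at least ``smooth_width`` samples and
    its prominence exceeds ``prominence_frac`` of the curve's dynamic range.
    ``censored`` is set when no peak qualifies (e.g., a monotone no-phage
    curve); ``excluded`` when the peak signal exceeds ``steady_state_max``
    (outside the steady-state exponential regime), with ``t_col`` still
    reported.  No sub-sample refinement is applied: ``t_col`` lives on the
    sampling grid.
    """
    if len(curve) < MIN_SAMPLES:
        raise InsufficientDataError(
            f"well {curve.well_id!r}: need >= {MIN_SAMPLES} samples, got {len(curve)}"
        )
    dynamic_range = float(curve.signal.max() - curve.signal.min())
    if dynamic_range <= 0:
        return CollapseEstimate(float("nan"), float("nan"), censored=True)
    peaks, _props = find_peaks(
        curve.signal,
        width=smooth_width,
        prominence=prominence_frac * dynamic_range,
    )
    if len(peaks) == 0:
        return CollapseEstimate(float("nan"), float("nan"), censored=True)
    first = int(peaks[0])
    signal_at = float(curve.signal[first])
    return CollapseEstimate(
        t_col=float(curve.times[first]),
        signal_at_collapse=signal_at,
        excluded=signal_at > steady_state_max,
    )


def bootstrap_collapse_se(
    curve: GrowthCurve,
    n_boot: int = 1000,
    seed: int = 0,
    smooth_width: int = 4,
    steady_state_max: float = 3e5,
) -> BootstrapResult:
    """Case-bootstrap standard error of the collapse time.

    Resamples (t, signal) pairs with replacement, sorts each replicate by
    time (duplicated times jittered by 1e-9 h to keep the grid strictly
    increasing), re-runs collapse detection and returns the standard
    deviation of the replicate collapse times.  Replicates without a
    detected collapse are skipped; if they exceed half of ``n_boot`` the
    result carries a wide-uncertainty flag.  Deterministic under ``seed``.
    """
    original = detect_collapse(curve, smooth_width=smooth_width, steady_state_max=steady_state_max)
    if original.censored:
        raise ValueError(
            f"well {curve.well_id!r}: no collapse on the original curve; nothing to bootstrap"
        )
    rng = np.random.default_rng(seed)
    n = len(curve)
    t_cols = []
    n_censored = 0
    for _ in range(n_boot):
        idx = np.sort(rng.integers(0, n, size=n))
        t_rep = curve.times[idx].copy()
        # jitter duplicated sample times so the replicate grid stays increasing
        dup = np.zeros(n)
        run = 0
        for j in range(1, n):
            run = run + 1 if t_rep[j] == t_rep[j - 1] else 0
            dup[j] = run
        t_rep = t_rep + dup * 1e-9
        rep = GrowthCurve(
            times=t_rep,
            signal=curve.signal[idx],
            readout=curve.readout,
            well_id=curve.well_id,
        )
        est = detect_collapse(rep, smooth_width=smooth_width, steady_state_max=steady_state_max)
        if est.censored:
            n_censored += 1
        else:
            t_cols.append(est.t_col)
    censored_fraction = n_censored / n_boot
    wide = censored_fraction > 0.5
    if wide:
        logger.warning(
            "well %r: %.0f%% of bootstrap replicates lost the collapse",
            curve.well_id,
            100 * censored_fraction,
        )
    se = float(np.std(t_cols, ddof=1)) if len(t_cols) > 1 else 0.0
    return BootstrapResult(
        se_t_col=se,
        censored_fraction=censored_fraction,
        wide_uncertainty=wide,
        n_boot=n_boot,
    )
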