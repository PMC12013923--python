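"""Phage amplification rates from collapse events.

The adsorption-limited collapse time

    t_col = (1/r_bac) * ln(1 + r_bac * ln(p_inf/p0) / (r_pha * b0))

is inverted (single curve) or fitted jointly across initial-condition
gradients with the amplification rate ``r_pha`` as the sole free parameter.
Also provided: the calibration-curve route to the phage fold-increase
``p_inf/p0``, a diagnostic separating the adsorption- from the
latency-limited regime, and an adsorption-constant estimator used to
reconstruct full trajectories for overlay comparisons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress, pearsonr

from .curves import CollapseEstimate, InsufficientDataError
from .model import (
    InitialState,
    PredationParams,
    Trajectory,
    phage_growth_closed_form,
    simulate_adsorption_limited,
)

__all__ = [
    "RateEstimate",
    "JointRateFit",
    "CalibrationCurve",
    "YieldEstimate",
    "RegimeReport",
    "KAdsorbEstimate",
    "NotIdentifiableError",
    "DETECTION_LIMIT",
    "rate_from_single_curve",
    "joint_fit_rate",
    "fit_calibration",
    "phage_ratio_from_collapse",
    "approximate_ratio",
    "regime_diagnostic",
    "estimate_kadsorb",
    "reconstruct_trajectory",
]

#: default minimum resolvable amplification rate, mL h^-1 (set by the culture
#: reaching stationary phase before a phage-driven collapse)
DETECTION_LIMIT = 3e-10


class NotIdentifiableError(ValueError):
    """The requested parameter is not identifiable from the supplied data."""


@dataclass
class YieldEstimate:
    """Fold increase of the phage population, ``p_inf / p0``.

    ``d`` is the purification dilution factor applied before reinoculation;
    ``approximated`` marks values obtained by assuming the fold increase
    equals the stock dilution of the original experiment.
    """

    p_ratio: float
    d: float = 1.0
    approximated: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.p_ratio):
            raise ValueError("p_ratio must be finite")
        if self.d < 1.0:
            raise ValueError(f"purification dilution d must be >= 1, got {self.d}")


@dataclass
class RateEstimate:
    """An inferred phage amplification rate, mL h^-1."""

    r_pha: float
    se_r_pha: float = 0.0
    below_detection: bool = False
    detection_limit: float = DETECTION_LIMIT
    method: str = "single_curve"
    n_curves: int = 1
    approximated_ratio: bool = False

    def __post_init__(self) -> None:
        if not self.below_detection and not self.r_pha > 0:
            raise ValueError("r_pha must be positive unless below detection")
        if self.se_r_pha < 0:
            raise ValueError("se_r_pha must be >= 0")


@dataclass
class JointRateFit(RateEstimate):
    """A joint fit across conditions, with per-condition predictions."""

    t_observed: np.ndarray = field(default_factory=lambda: np.array([]))
    t_predicted: np.ndarray = field(default_factory=lambda: np.array([]))
    r2: float = float("nan")            #: squared Pearson corr(observed, predicted)
    r2_identity: float = float("nan")   #: 1 - SS_res/SS_tot about the identity line


@dataclass
class CalibrationCurve:
    """Collapse time vs log relative phage concentration.

    ``t_col = a * ln(p0/p_stock) + b``, fitted over a stock-dilution series.
    ``a`` is expected negative (more phage collapses earlier) but is not
    enforced; ``b`` is the collapse time of the undiluted stock.
    """

    a: float
    b_intercept: float
    dilution_range: Tuple[float, float]     #: (min, max) stock-dilution factors
    fit_residual_sd: float
    n_points: int = 0

    def predict_t_col(self, dilution: float) -> float:
        """Collapse time expected at a given stock-dilution factor."""
        return self.a * (-math.log(dilution)) + self.b_intercept


@dataclass
class RegimeReport:
    """Outcome of the adsorption- vs latency-limited diagnostic."""

    slope: float                #: d t_col / d ln(b0), h per natural-log unit
    se_slope: float
    pearson_rho: float
    p_value: float
    call: str                   #: 'adsorption-limited' | 'latency-limited' | 'indeterminate'
    reason: str = ""
    n_points: int = 0


@dataclass
class KAdsorbEstimate:
    """Adsorption constant recovered from collapse-density variation."""

    k_adsorb: float
    se_k_adsorb: float
    r_pha: float        #: amplification rate implied by the same regression


def _t_col_or_censored(collapse: "CollapseEstimate | float") -> Tuple[float, float, bool]:
    """Normalize a collapse argument to (t_col, se, censored)."""
    if isinstance(collapse, CollapseEstimate):
        se = collapse.se_t_col if math.isfinite(collapse.se_t_col) else 0.0
        return collapse.t_col, se, collapse.censored
    return float(collapse), 0.0, False


def rate_from_single_curve(
    t_col: "CollapseEstimate | float",
    r_bac: float,
    b0: float,
    yield_: YieldEstimate,
    detection_limit: float = DETECTION_LIMIT,
) -> RateEstimate:
    """Invert the collapse-time formula for one curve.

        r_pha = r_bac * ln(p_inf/p0) / (b0 * (e^{r_bac t_col} - 1))

    The standard error of ``t_col`` (when given as a
    :class:`~phorce.curves.CollapseEstimate`) is propagated by the delta
    method.  A censored collapse yields a below-detection result carrying
    ``detection_limit`` instead of raising.
    """
    t, se_t, censored = _t_col_or_censored(t_col)
    if censored:
        return RateEstimate(
            r_pha=detection_limit,
            below_detection=True,
            detection_limit=detection_limit,
            approximated_ratio=yield_.approximated,
        )
    if not t > 0:
        raise ValueError(f"t_col must be positive, got {t}")
    if not b0 > 0:
        raise ValueError(f"b0 must be positive, got {b0}")
    if not yield_.p_ratio > 1:
        raise ValueError(f"p_ratio must exceed 1, got {yield_.p_ratio}")
    growth = math.expm1(r_bac * t)
    r_pha = r_bac * math.log(yield_.p_ratio) / (b0 * growth)
    # d r_pha / d t_col = -r_pha * r_bac * e^{rt} / (e^{rt} - 1)
    sensitivity = r_pha * r_bac * math.exp(r_bac * t) / growth
    return RateEstimate(
        r_pha=r_pha,
        se_r_pha=sensitivity * se_t,
        detection_limit=detection_limit,
        approximated_ratio=yield_.approximated,
    )


def joint_fit_rate(
    collapses: Sequence[Tuple[CollapseEstimate, InitialState, YieldEstimate]],
    r_bac: float,
    detection_limit: float = DETECTION_LIMIT,
) -> JointRateFit:
    """Fit all collapse times simultaneously with a single ``r_pha``.

    Nonlinear least squares of the collapse-time formula over every usable
    (non-censored, non-excluded) condition, log-parameterized to keep the
    rate positive.  The initializer is the single-curve estimate of the
    median-collapse-time condition.  Goodness of fit is reported both as
    the squared Pearson correlation between observed and predicted collapse
    times and as the coefficient of determination about the identity line.
    """
    usable = [
        (ce, ini, ye)
        for ce, ini, ye in collapses
        if ce.usable and math.isfinite(ce.t_col)
    ]
    if len(usable) < 2:
        raise InsufficientDataError(
            f"joint fit needs >= 2 usable collapses, got {len(usable)}"
        )
    t_obs = np.array([ce.t_col for ce, _, _ in usable])
    b0s = np.array([ini.b0 for _, ini, _ in usable])
    log_ratio = np.array([math.log(ye.p_ratio) for _, _, ye in usable])
    if np.any(log_ratio <= 0):
        raise ValueError("all p_ratio values must exceed 1")

    def predict(log_rpha: float) -> np.ndarray:
        rpha = math.exp(log_rpha)
        return np.log1p(r_bac * log_ratio / (rpha * b0s)) / r_bac

    median_idx = int(np.argsort(t_obs)[len(t_obs) // 2])
    ce0, ini0, ye0 = usable[median_idx]
    start = rate_from_single_curve(ce0.t_col, r_bac, ini0.b0, ye0).r_pha

    result = least_squares(
        lambda x: predict(x[0]) - t_obs,
        x0=[math.log(start)],
        method="lm",
    )
    if not result.success:
        raise RuntimeError(
            f"joint fit did not converge from r_pha = {start:.3g} "
            f"(residual norm {np.linalg.norm(result.fun):.3g})"
        )
    log_rpha = float(result.x[0])
    r_pha = math.exp(log_rpha)
    t_pred = predict(log_rpha)

    dof = max(len(t_obs) - 1, 1)
    s2 = float(np.sum(result.fun**2)) / dof
    jtj = float(np.sum(result.jac**2))
    se_log = math.sqrt(s2 / jtj) if jtj > 0 else float("inf")

    if np.std(t_obs) > 0 and np.std(t_pred) > 0:
        r2 = float(pearsonr(t_obs, t_pred)[0] ** 2)
        ss_tot = float(np.sum((t_obs - t_obs.mean()) ** 2))
        r2_identity = 1.0 - float(np.sum((t_obs - t_pred) ** 2)) / ss_tot
    else:
        r2 = r2_identity = float("nan")

    approx = any(ye.approximated for _, _, ye in usable)
    return JointRateFit(
        r_pha=r_pha,
        se_r_pha=r_pha * se_log,
        below_detection=False,
        detection_limit=detection_limit,
        method="joint_fit",
        n_curves=len(usable),
        approximated_ratio=approx,
        t_observed=t_obs,
        t_predicted=t_pred,
        r2=r2,
        r2_identity=r2_identity,
    )


def fit_calibration(
    dilutions: Sequence[float], t_cols: Sequence[float]
) -> CalibrationCurve:
    """Fit the calibration line ``t_col = a * ln(p0/p_stock) + b``.

    ``dilutions`` are stock-dilution factors (p_stock/p0 >= 1) of the
    calibration series; the regressor is the log relative concentration
    ``ln(p0/p_stock) = -ln(dilution)``, so ``a`` comes out negative for the
    physical direction (more phage collapses earlier).
    """
    dil = np.asarray(dilutions, dtype=float)
    t = np.asarray(t_cols, dtype=float)
    if len(dil) != len(t):
        raise ValueError("dilutions and t_cols must have the same length")
    if len(dil) < 3:
        raise InsufficientDataError("calibration needs >= 3 points")
    if np.any(dil <= 0):
        raise ValueError("dilutions must be positive")
    x = -np.log(dil)
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError("all calibration dilutions are equal (rank-deficient)")
    res = linregress(x, t)
    resid = t - (res.slope * x + res.intercept)
    sd = float(np.std(resid, ddof=2)) if len(t) > 2 else 0.0
    return CalibrationCurve(
        a=float(res.slope),
        b_intercept=float(res.intercept),
        dilution_range=(float(dil.min()), float(dil.max())),
        fit_residual_sd=sd,
        n_points=len(t),
    )


def phage_ratio_from_collapse(
    cal: CalibrationCurve,
    t_col: float,
    d: float,
    stock_dilution: float = 1.0,
) -> YieldEstimate:
    """Phage fold increase from a reinoculation collapse time.

    Inverting the calibration line gives the assay-well concentration of
    the purified sample relative to the stock,
    ``exp((t_col - b)/a)``; multiplying by the reinoculation dilution ``d``
    undoes the dilution applied before the assay, yielding
    ``p_inf/p_stock``; multiplying by the stock dilution ``p_stock/p0`` of
    the original experiment yields ``p_inf/p0``.  Both dilution factors are
    carried explicitly because they enter at different stages.
    """
    if cal.a == 0:
        raise ValueError("invalid calibration: zero slope")
    lo = cal.predict_t_col(cal.dilution_range[0])
    hi = cal.predict_t_col(cal.dilution_range[1])
    if not (min(lo, hi) <= t_col <= max(lo, hi)):
        warnings.warn(
            f"collapse time {t_col:.3g} h outside the calibrated range "
            f"[{min(lo, hi):.3g}, {max(lo, hi):.3g}] h; extrapolating",
            stacklevel=2,
        )
    p_inf_over_stock = math.exp((t_col - cal.b_intercept) / cal.a) * d
    return YieldEstimate(
        p_ratio=p_inf_over_stock * stock_dilution,
        d=d,
        approximated=False,
    )


def approximate_ratio(stock_dilution: float) -> YieldEstimate:
    """Approximate the phage fold increase by the stock dilution.

    Assumes the phage population grew back to its stock concentration,
    ``p_inf/p0 = p_stock/p0``.  Downstream rate estimates inherit the
    ``approximated`` flag; the amplification rate depends only
    logarithmically on this ratio.
    """
    if not stock_dilution > 1:
        raise ValueError(f"stock_dilution must exceed 1, got {stock_dilution}")
    return YieldEstimate(p_ratio=stock_dilution, approximated=True)


def regime_diagnostic(
    collapses: Sequence[Tuple[CollapseEstimate, InitialState]],
    slope_tol: float = 0.02,
    alpha: float = 0.05,
    min_span_decades: float = 1.5,
) -> RegimeReport:
    """Classify the rate-limiting step from a fixed-MOI b0 sweep.

    Fits ``t_col`` against ``ln b0``.  A significant negative slope marks
    the adsorption-limited regime (collapse time falls logarithmically with
    bacterial density); a slope within ``slope_tol`` (h per natural-log
    unit) of zero marks the latency-limited regime (collapse time depends
    on the MOI only); anything else is indeterminate.
    """
    usable = [(ce, ini) for ce, ini in collapses if ce.usable and math.isfinite(ce.t_col)]
    if len(usable) < 4:
        return RegimeReport(
            float("nan"), float("nan"), float("nan"), float("nan"),
            call="indeterminate", reason=f"only {len(usable)} usable conditions",
            n_points=len(usable),
        )
    t = np.array([ce.t_col for ce, _ in usable])
    ln_b0 = np.array([math.log(ini.b0) for _, ini in usable])
    span = float(np.ptp(ln_b0)) / math.log(10.0)
    if span < min_span_decades:
        return RegimeReport(
            float("nan"), float("nan"), float("nan"), float("nan"),
            call="indeterminate",
            reason=f"b0 span {span:.2f} decades < {min_span_decades}",
            n_points=len(usable),
        )
    res = linregress(ln_b0, t)
    if np.ptp(t) == 0:
        rho, p = 0.0, 1.0
        slope, se = 0.0, 0.0
    else:
        rho, p = float(res.rvalue), float(res.pvalue)
        slope, se = float(res.slope), float(res.stderr)
    if abs(slope) <= slope_tol:
        call, reason = "latency-limited", "collapse time independent of b0"
    elif slope < 0 and p < alpha:
        call, reason = "adsorption-limited", "collapse time falls with ln b0"
    else:
        call, reason = "indeterminate", "slope neither flat nor significantly negative"
    return RegimeReport(
        slope=slope, se_slope=se, pearson_rho=rho, p_value=p,
        call=call, reason=reason, n_points=len(usable),
    )


def estimate_kadsorb(
    collapses: Sequence[Tuple[CollapseEstimate, InitialState]],
    r_bac: float,
    min_span_decades: float = 2.0,
) -> KAdsorbEstimate:
    """Adsorption constant from the p0 dependence of the collapse density.

    At collapse the phage density equals ``r_bac / k_adsorb``, so the fold
    growth of the bacteria up to collapse obeys

        b0 * (b_col/b0 - 1) = (r_bac/r_pha) * [ln(r_bac/k_adsorb) - ln p0]

    with ``b_col/b0 = e^{r_bac t_col}``.  A linear regression of the
    left-hand side on ``ln p0`` yields ``r_pha = -r_bac/slope`` and
    ``k_adsorb = r_bac * exp(intercept/slope)``.  Wide p0 variation
    (>= ``min_span_decades`` decades) is required; a flat dependence (e.g.,
    the infinite-burst limit, where the collapse density no longer depends
    on p0) raises :class:`NotIdentifiableError`.  Intended for
    reconstructing full trajectories, not as a precision estimator.
    """
    usable = [
        (ce, ini)
        for ce, ini in collapses
        if ce.usable and math.isfinite(ce.t_col) and ini.p0 > 0
    ]
    if len(usable) < 4:
        raise InsufficientDataError(f"need >= 4 usable collapses, got {len(usable)}")
    ln_p0 = np.array([math.log(ini.p0) for _, ini in usable])
    span = float(np.ptp(ln_p0)) / math.log(10.0)
    if span < min_span_decades:
        raise NotIdentifiableError(
            f"p0 span {span:.2f} decades < {min_span_decades}; "
            "k_adsorb not identifiable"
        )
    z = np.array(
        [ini.b0 * math.expm1(r_bac * ce.t_col) for ce, ini in usable]
    )
    coef, cov = np.polyfit(ln_p0, z, 1, cov=True)
    slope, intercept = float(coef[0]), float(coef[1])
    se_slope = math.sqrt(cov[0, 0])
    if slope >= 0 or abs(slope) < 2 * se_slope:
        raise NotIdentifiableError(
            "collapse density does not decrease with p0 "
            f"(slope {slope:.3g} +- {se_slope:.3g}); k_adsorb not identifiable"
        )
    k_adsorb = r_bac * math.exp(intercept / slope)
    r_pha = -r_bac / slope
    # delta method on k(intercept, slope)
    dk_dc = k_adsorb / slope
    dk_ds = -k_adsorb * intercept / slope**2
    var_k = (
        dk_dc**2 * cov[1, 1]
        + dk_ds**2 * cov[0, 0]
        + 2 * dk_dc * dk_ds * cov[0, 1]
    )
    return KAdsorbEstimate(
        k_adsorb=k_adsorb,
        se_k_adsorb=math.sqrt(max(var_k, 0.0)),
        r_pha=r_pha,
    )


def reconstruct_trajectory(
    r_bac: float,
    r_pha: float,
    k_adsorb: float,
    init: InitialState,
    times: np.ndarray,
    start_index: int = 10,
    b_start: Optional[float] = None,
) -> Trajectory:
    """Model trajectory for overlaying on a measured curve.

    Integrates the adsorption-limited model from the ``start_index``-th
    sample (skipping the noisy start of a measured curve).  The bacterial
    state there defaults to pure exponential growth from ``init.b0``; the
    phage state comes from the super-exponential closed form.  Returns the
    trajectory on ``times[start_index:]``.
    """
    times = np.asarray(times, dtype=float)
    if not 0 <= start_index < len(times) - 1:
        raise ValueError("start_index out of range")
    t0 = times[start_index]
    b_at = b_start if b_start is not None else init.b0 * math.exp(r_bac * t0)
    params = PredationParams(
        r_bac=r_bac, k_adsorb=k_adsorb, n_burst=r_pha / k_adsorb
    )
    p_at = phage_growth_closed_form(params, init, t0)
    window = times[start_index:] - t0
    dt = float(np.min(np.diff(window)))
    traj = simulate_adsorption_limited(
        params,
        InitialState(b0=b_at, p0=p_at),
        t_end=float(window[-1]),
        dt=dt,
    )
    # re-sample onto the curve's own grid
    b = np.interp(window, traj.times, traj.b)
    p = np.interp(window, traj.times, traj.p)
    return Trajectory(times=times[start_index:], b=b, p=p)
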