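"""Kinetic models of lytic-phage predation on growing bacteria.

Two limiting regimes of the phage infection cycle are implemented:

* **adsorption-limited** — the cycle rate is set by phage-host encounter
  kinetics (mass-action adsorption), giving::

      db/dt = r_bac * b - k_adsorb * p * b
      dp/dt = n_burst * k_adsorb * p * b

* **latency-limited** — the cycle rate is set by the intracellular latent
  period ``tau_latency``, giving::

      db/dt = r_bac * b - p / tau_latency
      dp/dt = n_burst * p / tau_latency

An extended variant of the adsorption-limited model tracks phage-resistant
and lysogenized subpopulations in addition to the sensitive one.

The product ``r_pha = n_burst * k_adsorb`` acts as a concentration-independent
*phage amplification rate*: ``r_pha * b`` is the specific growth rate of the
phage population in a bacterial population of concentration ``b``.  In the
adsorption-limited regime the bacterial population peaks ("collapses") when
the phage density reaches ``r_bac / k_adsorb``, which yields a closed-form
collapse time that this module exposes alongside the numerical simulators.

Units throughout: concentrations in mL^-1, times in hours, ``k_adsorb`` and
``r_pha`` in mL h^-1.  All logarithms are natural; ``r_bac`` is the continuous
specific growth rate (doubling time ``ln 2 / r_bac``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "PredationParams",
    "InitialState",
    "Trajectory",
    "IntegrationFailure",
    "UndefinedDensityError",
    "ResonantParameterError",
    "simulate_adsorption_limited",
    "simulate_latency_limited",
    "simulate_extended",
    "phage_growth_closed_form",
    "latency_closed_form",
    "collapse_time_adsorption",
    "collapse_phage_density",
    "collapse_moi_latency",
    "collapse_time_latency",
]

#: default relative tolerance of the adaptive integrator
RTOL = 1e-8
#: default absolute tolerance, mL^-1 (sub-single-particle resolution)
ATOL = 1e-3


class IntegrationFailure(RuntimeError):
    """The ODE solver produced a non-finite state or failed to converge."""


class UndefinedDensityError(ValueError):
    """Collapse phage density is undefined (zero adsorption constant)."""


class ResonantParameterError(ValueError):
    """Closed form degenerate at n_burst/tau_latency == r_bac; integrate numerically."""


@dataclass(frozen=True)
class PredationParams:
    """Kinetic constants of the predation model.

    Parameters
    ----------
    r_bac : float
        Bacterial specific growth rate, h^-1.  Must be positive.
    k_adsorb : float
        Adsorption rate constant, mL h^-1 (mass-action constant per
        phage-bacterium pair).
    n_burst : float
        Burst size: replication-competent progeny phage released per lysed
        cell.  Treated as a composite parameter (it absorbs the efficiency
        of plating).
    tau_latency : float, optional
        Latent period, h.  Required only by the latency-limited model.
    r_res : float
        Per-capita rate at which sensitive bacteria acquire phage
        resistance, h^-1 (extended model; default 0).
    phi_lys : float
        Fraction of infections that lysogenize rather than lyse,
        dimensionless in [0, 1] (extended model; default 0).
    """

    r_bac: float
    k_adsorb: float
    n_burst: float
    tau_latency: Optional[float] = None
    r_res: float = 0.0
    phi_lys: float = 0.0

    def __post_init__(self) -> None:
        if not self.r_bac > 0:
            raise ValueError(f"r_bac must be positive, got {self.r_bac}")
        if self.k_adsorb < 0:
            raise ValueError(f"k_adsorb must be >= 0, got {self.k_adsorb}")
        if self.n_burst < 0:
            raise ValueError(f"n_burst must be >= 0, got {self.n_burst}")
        if self.tau_latency is not None and not self.tau_latency > 0:
            raise ValueError(f"tau_latency must be positive, got {self.tau_latency}")
        if self.r_res < 0:
            raise ValueError(f"r_res must be >= 0, got {self.r_res}")
        if not 0.0 <= self.phi_lys <= 1.0:
            raise ValueError(f"phi_lys must lie in [0, 1], got {self.phi_lys}")

    @property
    def r_pha(self) -> float:
        """Phage amplification rate ``n_burst * k_adsorb``, mL h^-1."""
        return self.n_burst * self.k_adsorb

    def _require_latency(self) -> float:
        if self.tau_latency is None:
            raise ValueError("tau_latency must be set for the latency-limited model")
        return self.tau_latency


@dataclass(frozen=True)
class InitialState:
    """Initial bacterial and phage concentrations, mL^-1."""

    b0: float
    p0: float

    def __post_init__(self) -> None:
        if not self.b0 > 0:
            raise ValueError(f"b0 must be positive, got {self.b0}")
        if self.p0 < 0:
            raise ValueError(f"p0 must be >= 0, got {self.p0}")

    @property
    def moi(self) -> float:
        """Multiplicity of infection, ``p0 / b0``."""
        return self.p0 / self.b0


@dataclass
class Trajectory:
    """Simulated concentrations on a sample grid.

    ``lysed`` is the integrator's running total of lysed bacteria (per mL),
    used to assert phage-number conservation.  The subpopulation series are
    populated by the extended model only, in which case ``b`` is their sum.
    """

    times: np.ndarray
    b: np.ndarray
    p: np.ndarray
    b_sens: Optional[np.ndarray] = None
    b_res: Optional[np.ndarray] = None
    b_lys: Optional[np.ndarray] = None
    lysed: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def collapse_index(self) -> int:
        """Index of the bacterial maximum on the sampled grid."""
        return int(np.argmax(self.b))

    @property
    def collapse_time(self) -> float:
        """Time of the bacterial maximum (operational collapse time), h."""
        return float(self.times[self.collapse_index])

    @property
    def collapsed(self) -> bool:
        """True when the bacterial maximum is interior to the window."""
        i = self.collapse_index
        return 0 < i < len(self.times) - 1

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns ``time_h``, ``species``, ``value``."""
        frames = {"b": self.b, "p": self.p}
        for name in ("b_sens", "b_res", "b_lys"):
            series = getattr(self, name)
            if series is not None:
                frames[name] = series
        rows = [
            pd.DataFrame({"time_h": self.times, "species": name, "value": values})
            for name, values in frames.items()
        ]
        return pd.concat(rows, ignore_index=True)


def _integrate(rhs, y0, t_end, dt, n_state, rtol=RTOL, atol=ATOL):
    """Run the adaptive solver on a fixed output grid and sanity-check it."""
    t_eval = np.arange(0.0, t_end + dt * 1e-9, dt)
    if t_eval[-1] < t_end - dt * 1e-6:
        t_eval = np.append(t_eval, t_end)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationFailure(
            f"integration failed near t = {sol.t[-1]:.6g} h: {sol.message}"
        )
    bad = ~np.all(np.isfinite(sol.y), axis=0)
    if np.any(bad):
        t_bad = sol.t[np.argmax(bad)]
        raise IntegrationFailure(f"non-finite state at t = {t_bad:.6g} h")
    y = np.clip(sol.y, 0.0, None)  # floor negative round-off
    assert y.shape[0] == n_state
    return sol.t, y


def simulate_adsorption_limited(
    params: PredationParams,
    init: InitialState,
    t_end: float,
    dt: float = 5.0 / 60.0,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Integrate the adsorption-limited predation model.

    Solves ``db/dt = r_bac*b - k_adsorb*p*b``,
    ``dp/dt = n_burst*k_adsorb*p*b`` with LSODA at rtol 1e-8 / atol 1e-3,
    sampling every ``dt`` hours.  Negative round-off is floored at zero.
    A third state variable accumulates lysed bacteria so that phage-number
    conservation ``p(t) - p0 = n_burst * lysed(t)`` can be asserted.
    """
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    if not dt > 0:
        raise ValueError("dt must be positive")
    r, k, n = params.r_bac, params.k_adsorb, params.n_burst

    def rhs(_t, y):
        b, p, _ = y
        infection = k * p * b
        return [r * b - infection, n * infection, infection]

    t, y = _integrate(rhs, [init.b0, init.p0, 0.0], t_end, dt, 3, rtol, atol)
    return Trajectory(times=t, b=y[0], p=y[1], lysed=y[2])


def simulate_latency_limited(
    params: PredationParams,
    init: InitialState,
    t_end: float,
    dt: float = 5.0 / 60.0,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Integrate the latency-limited predation model (linear system)."""
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    tau = params._require_latency()
    r, n = params.r_bac, params.n_burst

    def rhs(_t, y):
        b, p = y
        return [r * b - p / tau, n * p / tau]

    t, y = _integrate(rhs, [init.b0, init.p0], t_end, dt, 2, rtol, atol)
    return Trajectory(times=t, b=y[0], p=y[1])


def simulate_extended(
    params: PredationParams,
    init: InitialState,
    t_end: float,
    dt: float = 5.0 / 60.0,
    b0_res: float = 0.0,
    b0_lys: float = 0.0,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Integrate the predation model extended with resistance and lysogeny.

    Sensitive bacteria convert to resistant at per-capita rate ``r_res``;
    a fraction ``phi_lys`` of infections lysogenize instead of bursting.
    The initial population is fully sensitive unless ``b0_res``/``b0_lys``
    override it.  The reported ``b`` is the total of the three classes.
    """
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    r, k, n = params.r_bac, params.k_adsorb, params.n_burst
    rr, phi = params.r_res, params.phi_lys

    def rhs(_t, y):
        bs, br, bl, p = y
        infection = k * p * bs
        return [
            bs * (r - rr) - infection,
            r * br + rr * bs,
            r * bl + phi * infection,
            n * infection * (1.0 - phi),
        ]

    y0 = [init.b0 - b0_res - b0_lys, b0_res, b0_lys, init.p0]
    t, y = _integrate(rhs, y0, t_end, dt, 4, rtol, atol)
    total = y[0] + y[1] + y[2]
    return Trajectory(
        times=t, b=total, p=y[3], b_sens=y[0], b_res=y[1], b_lys=y[2]
    )


def phage_growth_closed_form(
    params: PredationParams, init: InitialState, t
) -> np.ndarray | float:
    """Super-exponential phage growth while bacteria grow unchecked.

    Neglecting predation losses on the bacteria (``b(t) = b0 e^{r_bac t}``),
    the phage population is

        ``p(t) = p0 * exp[(r_pha * b0 / r_bac) * (e^{r_bac t} - 1)]``.
    """
    r = params.r_bac
    exponent = (params.r_pha * init.b0 / r) * np.expm1(r * np.asarray(t, dtype=float))
    out = init.p0 * np.exp(exponent)
    return float(out) if np.isscalar(t) else out


def collapse_time_adsorption(
    params: PredationParams, init: InitialState, p_ratio: float
) -> float:
    """Closed-form collapse time of the adsorption-limited model, h.

        ``t_col = (1/r_bac) * ln(1 + (r_bac / (r_pha * b0)) * ln(p_ratio))``

    ``p_ratio`` is the fold increase of the phage population up to the
    collapse (``p_inf / p0``).  A zero amplification rate yields an infinite
    (censored) collapse time rather than an exception.
    """
    if p_ratio < 1.0:
        raise ValueError(f"p_ratio must be >= 1, got {p_ratio}")
    if params.r_pha == 0.0:
        return math.inf
    r = params.r_bac
    return math.log1p(r * math.log(p_ratio) / (params.r_pha * init.b0)) / r


def collapse_phage_density(params: PredationParams) -> float:
    """Phage density at which the bacterial population peaks, mL^-1.

    The population peaks when phage-driven lysis balances growth, i.e.,
    at ``p = r_bac / k_adsorb``.
    """
    if params.k_adsorb == 0.0:
        raise UndefinedDensityError(
            "collapse phage density undefined for k_adsorb = 0"
        )
    return params.r_bac / params.k_adsorb


def latency_closed_form(params: PredationParams, init: InitialState, t):
    """Analytic solution of the latency-limited model.

    With ``alpha = n_burst / tau_latency``:

        ``p(t) = p0 * e^{alpha t}``
        ``b(t) = b0 * e^{r t}
                 - p0 * (e^{alpha t} - e^{r t}) / (n_burst - r * tau_latency)``

    The denominator ``n_burst - r_bac*tau_latency`` (= ``tau*(alpha - r)``)
    is fixed by substituting the solution back into the model equations.
    Returns the pair ``(b, p)`` evaluated at ``t`` (scalar or array).
    """
    tau = params._require_latency()
    r = params.r_bac
    alpha = params.n_burst / tau
    if math.isclose(alpha, r, rel_tol=1e-12, abs_tol=0.0):
        raise ResonantParameterError(
            "n_burst/tau_latency equals r_bac; the closed form is degenerate -- "
            "use simulate_latency_limited instead"
        )
    t = np.asarray(t, dtype=float)
    e_r = np.exp(r * t)
    e_a = np.exp(alpha * t)
    p = init.p0 * e_a
    b = init.b0 * e_r - init.p0 * (e_a - e_r) / (tau * (alpha - r))
    if t.ndim == 0:
        return float(b), float(p)
    return b, p


def collapse_moi_latency(params: PredationParams) -> float:
    """MOI at which the latency-limited population peaks: ``r_bac * tau_latency``."""
    return params.r_bac * params._require_latency()


def collapse_time_latency(params: PredationParams, moi0: float) -> float:
    """Collapse time of the latency-limited model, h.

    Depends only on the initial MOI.  Derived by imposing ``db/dt = 0``
    (equivalently, the fixed collapse MOI ``m* = r_bac * tau_latency``) on
    the analytic solution.  With ``alpha = n_burst / tau_latency``:

        ``t_col = ln[ m* (n_burst - m* + moi0) / (moi0 * n_burst) ]
                  / (alpha - r_bac)``

    For ``moi0 >= m*`` the population is already past its peak and the
    collapse time is 0.
    """
    if not moi0 > 0:
        raise ValueError(f"moi0 must be positive, got {moi0}")
    tau = params._require_latency()
    r = params.r_bac
    alpha = params.n_burst / tau
    moi_col = r * tau
    if moi0 >= moi_col:
        return 0.0
    if math.isclose(alpha, r, rel_tol=1e-12, abs_tol=0.0):
        raise ResonantParameterError(
            "n_burst/tau_latency equals r_bac; integrate numerically"
        )
    x = moi_col * (params.n_burst - moi_col + moi0) / (moi0 * params.n_burst)
    return math.log(x) / (alpha - r)
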