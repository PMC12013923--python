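"""Synthetic plate-reader datasets with known ground truth.

Renders trajectories of any predation-model variant as noisy
bioluminescence-like signals on configurable plate layouts, so that every
analysis stage (growth fit, collapse detection, rate inference, interaction
calls) can be scored against the generating parameters without external
data.

The generator adds one ingredient the predation model lacks: a logistic
stationary-phase ceiling (growth term ``r_bac * b * (1 - b/K)``), because
real plate curves plateau and the collapse analysis must be able to exclude
collapses that fall outside the steady-state exponential regime.  Ground
truth (collapse time, final phage count) is always defined on the noiseless
trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .curves import GrowthCurve
from .model import InitialState, IntegrationFailure, PredationParams

__all__ = [
    "SignalModel",
    "PlateSpec",
    "WellSpec",
    "PlateDataset",
    "PHAGE_STOCK_CONCENTRATION",
    "serial_levels",
    "generate_curve",
    "generate_gradient_plate",
    "generate_drug_gradient_dataset",
]

#: virtual phage-stock concentration used for dilution bookkeeping, pfu/mL
PHAGE_STOCK_CONCENTRATION = 2.6e8


@dataclass(frozen=True)
class SignalModel:
    """How a bacterial concentration becomes a measured signal.

    ``scale`` converts cells/mL to AU; ``noise_cv`` is the coefficient of
    variation of multiplicative lognormal measurement noise;
    ``carrying_capacity`` is the stationary-phase ceiling of the logistic
    growth term.  With the defaults the plateau sits at 1e7 AU, the growth
    fit ceiling of 1e6 AU maps to 0.1 K (still near-exponential) and the
    collapse-exclusion threshold of 3e5 AU maps to 3e8 cells/mL.
    """

    scale: float = 1e-3             #: AU per cell/mL
    noise_cv: float = 0.05          #: multiplicative lognormal CV
    floor: float = 1.0              #: detection floor, AU
    carrying_capacity: float = 1e10  #: mL^-1
    cadence_min: float = 5.0        #: minutes between samples
    duration_h: float = 16.0        #: h
    mean_preserving: bool = False   #: subtract sigma^2/2 so E[signal] = truth

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not self.carrying_capacity > 0:
            raise ValueError("carrying_capacity must be positive")

    @property
    def sigma(self) -> float:
        """Lognormal sigma corresponding to ``noise_cv``."""
        return math.sqrt(math.log(1.0 + self.noise_cv**2))

    def grid(self) -> np.ndarray:
        """Sample times in hours."""
        step = self.cadence_min / 60.0
        return np.arange(0.0, self.duration_h + step * 1e-9, step)


@dataclass(frozen=True)
class WellSpec:
    """One well of a synthetic plate."""

    well_id: str
    init: InitialState
    params: PredationParams
    drug: str = ""                  #: antibiotic label ('' = no drug axis)
    drug_conc: float = 0.0
    phage: Optional[str] = None     #: None marks a no-phage control
    model: str = "adsorption"


@dataclass(frozen=True)
class PlateSpec:
    """A full plate: wells plus the master seed (fixed seed => identical data)."""

    wells: Tuple[WellSpec, ...]
    seed: int

    def __post_init__(self) -> None:
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            raise ValueError("well_ids must be unique")


@dataclass
class PlateDataset:
    """Generated curves plus machine-readable ground truth and layout."""

    curves: List[GrowthCurve]
    manifest: pd.DataFrame      #: one row per well, all parameters and truth
    layout: pd.DataFrame        #: what an experimenter would know
    signal_model: SignalModel
    spec: PlateSpec


def serial_levels(top: float, n: int, step: float = 2.0) -> np.ndarray:
    """Serial-dilution series ``top, top/step, ...`` (exact factors), length n."""
    if not top > 0 or n < 1 or not step > 1:
        raise ValueError("need top > 0, n >= 1, step > 1")
    return top / step ** np.arange(n)


def _rhs(model: str, params: PredationParams, K: float):
    r, k, n = params.r_bac, params.k_adsorb, params.n_burst

    if model == "adsorption":
        def rhs(_t, y):
            b, p = y
            infection = k * p * b
            return [r * b * (1.0 - b / K) - infection, n * infection]
        return rhs, 2
    if model == "latency":
        tau = params.tau_latency
        if tau is None:
            raise ValueError("latency model requires tau_latency")
        def rhs(_t, y):
            b, p = y
            return [r * b * (1.0 - b / K) - p / tau, n * p / tau]
        return rhs, 2
    if model == "extended":
        rr, phi = params.r_res, params.phi_lys
        def rhs(_t, y):
            bs, br, bl, p = y
            logistic = 1.0 - (bs + br + bl) / K
            infection = k * p * bs
            return [
                bs * (r * logistic - rr) - infection,
                r * br * logistic + rr * bs,
                r * bl * logistic + phi * infection,
                n * infection * (1.0 - phi),
            ]
        return rhs, 4
    raise ValueError(f"unknown model {model!r}")


def _simulate_noiseless(
    params: PredationParams, init: InitialState, signal_model: SignalModel, model: str
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    rhs, n_state = _rhs(model, params, signal_model.carrying_capacity)
    times = signal_model.grid()
    if n_state == 2:
        y0 = [init.b0, init.p0]
    else:
        y0 = [init.b0, 0.0, 0.0, init.p0]
    sol = solve_ivp(
        rhs, (times[0], times[-1]), y0, method="LSODA",
        t_eval=times, rtol=1e-8, atol=1e-3,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise IntegrationFailure(f"generator integration failed: {sol.message}")
    y = np.clip(sol.y, 0.0, None)
    if n_state == 2:
        b, p = y[0], y[1]
    else:
        b, p = y[0] + y[1] + y[2], y[3]
    return times, b, p


def generate_curve(
    params: PredationParams,
    init: InitialState,
    signal_model: SignalModel = SignalModel(),
    seed: int = 0,
    model: str = "adsorption",
    well_id: str = "",
    metadata: Optional[dict] = None,
) -> GrowthCurve:
    """Generate one noisy growth curve with ground truth in its metadata.

    Integrates the chosen model variant with a logistic stationary-phase
    ceiling, maps bacterial concentration to signal, then applies
    multiplicative lognormal noise and a detection floor.  The metadata
    records the generating parameters, the noiseless collapse time (argmax
    of b; None if the noiseless curve never turns over), and the phage
    concentration at collapse and at the end of the run.
    """
    times, b, p = _simulate_noiseless(params, init, signal_model, model)
    i_max = int(np.argmax(b))
    collapsed = 0 < i_max < len(times) - 1
    truth = {
        "well": well_id,
        "model": model,
        "b0": init.b0,
        "p0": init.p0,
        "r_bac": params.r_bac,
        "k_adsorb": params.k_adsorb,
        "n_burst": params.n_burst,
        "r_pha": params.r_pha,
        "tau_latency": params.tau_latency,
        "r_res": params.r_res,
        "phi_lys": params.phi_lys,
        "t_col_true": float(times[i_max]) if collapsed else None,
        "b_at_collapse_true": float(b[i_max]) if collapsed else None,
        "p_at_collapse_true": float(p[i_max]) if collapsed else None,
        "p_final_true": float(p[-1]),
        "collapsed": collapsed,
        "seed": seed,
    }
    if metadata:
        truth.update(metadata)
    signal = signal_model.scale * b
    if signal_model.noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = signal_model.sigma
        eps = rng.normal(0.0, sigma, size=len(times))
        if signal_model.mean_preserving:
            eps -= 0.5 * sigma**2
        signal = signal * np.exp(eps)
    signal = np.maximum(signal, signal_model.floor)
    return GrowthCurve(
        times=times, signal=signal, readout="bioluminescence",
        well_id=well_id, condition=truth,
    )


def _well_seeds(seed: int, n: int) -> List[int]:
    """Stable per-well seeds below 2**31 derived from the master seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def _build_dataset(spec: PlateSpec, signal_model: SignalModel) -> PlateDataset:
    seeds = _well_seeds(spec.seed, len(spec.wells))
    curves, manifest_rows, layout_rows = [], [], []
    for well, well_seed in zip(spec.wells, seeds):
        meta = {"phage": well.phage, "drug": well.drug, "drug_conc": well.drug_conc}
        curve = generate_curve(
            well.params, well.init, signal_model,
            seed=well_seed, model=well.model, well_id=well.well_id,
            metadata=meta,
        )
        curves.append(curve)
        manifest_rows.append(curve.condition)
        stock_dilution = (
            PHAGE_STOCK_CONCENTRATION / well.init.p0 if well.init.p0 > 0 else np.nan
        )
        layout_rows.append(
            {
                "well": well.well_id,
                "b0": well.init.b0,
                "phage": well.phage if well.phage is not None else "",
                "stock_dilution": stock_dilution,
                "drug": well.drug,
                "drug_conc": well.drug_conc,
                "role": "phage_well" if well.phage is not None else "no_phage_control",
            }
        )
    return PlateDataset(
        curves=curves,
        manifest=pd.DataFrame(manifest_rows),
        layout=pd.DataFrame(layout_rows),
        signal_model=signal_model,
        spec=spec,
    )


def generate_gradient_plate(
    base_params: PredationParams,
    b0_levels: Optional[Sequence[float]] = None,
    p0_levels: Optional[Sequence[float]] = None,
    signal_model: SignalModel = SignalModel(),
    seed: int = 0,
    phage: str = "phage",
    include_controls: bool = True,
) -> PlateDataset:
    """Full-factorial plate over initial bacterial and phage concentrations.

    Defaults reproduce the reference 2D-gradient design: eight bacterial
    levels (1.4e6 mL^-1 down in 2x steps) crossed with ten phage levels
    (1.3e6 mL^-1 down in 2x steps), plus one no-phage control per
    bacterial level for growth-rate fitting.  Rows index b0, columns p0.
    """
    if b0_levels is None:
        b0_levels = serial_levels(1.4e6, 8, 2.0)
    if p0_levels is None:
        p0_levels = serial_levels(1.3e6, 10, 2.0)
    b0_levels = np.asarray(b0_levels, dtype=float)
    p0_levels = np.asarray(p0_levels, dtype=float)
    if len(b0_levels) < 2 or len(p0_levels) < 2:
        raise ValueError("need at least 2 levels per axis")
    wells = []
    for i, b0 in enumerate(b0_levels):
        row = chr(ord("A") + i) if i < 26 else f"R{i}"
        for j, p0 in enumerate(p0_levels):
            wells.append(
                WellSpec(
                    well_id=f"{row}{j + 1}",
                    init=InitialState(b0=b0, p0=p0),
                    params=base_params,
                    phage=phage,
                )
            )
        if include_controls:
            wells.append(
                WellSpec(
                    well_id=f"{row}{len(p0_levels) + 1}",
                    init=InitialState(b0=b0, p0=0.0),
                    params=base_params,
                    phage=None,
                )
            )
    return _build_dataset(PlateSpec(wells=tuple(wells), seed=seed), signal_model)


def generate_drug_gradient_dataset(
    base_params: PredationParams,
    r_bac_effect: Callable[[float], float],
    r_pha_effect: Callable[[float], float],
    concentrations: Optional[Sequence[float]] = None,
    signal_model: SignalModel = SignalModel(),
    seed: int = 0,
    phage: str = "phage",
    drug: str = "drug",
    b0: float = 4e5,
    p0: float = 1e5,
    n_replicates: int = 5,
) -> PlateDataset:
    """Antibiotic-gradient dataset: per dose, one phage-free control well and
    ``n_replicates`` phage wells (five, matching replicated bench practice
    for dose-response characterization).

    ``r_bac_effect`` and ``r_pha_effect`` are multiplicative dose-response
    factors (both 1 at concentration 0).  The drug acts on the amplification
    rate through the adsorption constant.  The manifest records the sign of
    the true concentration dependence of r_pha (`tau_sign_true`: +1
    monotone increasing, -1 decreasing, 0 flat/non-monotone), which is the
    ground truth for interaction calls.  Default doses: a zero-drug control
    plus seven levels evenly spaced up to 3 ug/mL.
    """
    if concentrations is None:
        concentrations = np.concatenate([[0.0], np.linspace(3.0 / 7, 3.0, 7)])
    concentrations = np.asarray(concentrations, dtype=float)
    effects = np.array([r_pha_effect(c) for c in concentrations])
    diffs = np.diff(effects)
    if np.all(diffs > 0):
        tau_sign = 1
    elif np.all(diffs < 0):
        tau_sign = -1
    else:
        tau_sign = 0
    wells = []
    for i, c in enumerate(concentrations):
        params_c = replace(
            base_params,
            r_bac=base_params.r_bac * r_bac_effect(c),
            k_adsorb=base_params.k_adsorb * r_pha_effect(c),
        )
        wells.append(
            WellSpec(
                well_id=f"C{i + 1}",
                init=InitialState(b0=b0, p0=0.0),
                params=params_c,
                drug=drug,
                drug_conc=float(c),
                phage=None,
            )
        )
        for j in range(n_replicates):
            wells.append(
                WellSpec(
                    well_id=f"P{i + 1}r{j + 1}",
                    init=InitialState(b0=b0, p0=p0),
                    params=params_c,
                    drug=drug,
                    drug_conc=float(c),
                    phage=phage,
                )
            )
    dataset = _build_dataset(PlateSpec(wells=tuple(wells), seed=seed), signal_model)
    dataset.manifest["tau_sign_true"] = tau_sign
    return dataset
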