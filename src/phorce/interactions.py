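"""Phage-antibiotic interaction scoring.

An interaction is scored as Kendall's tau between antibiotic concentration
and the phage amplification rate measured at that concentration (each rate
computed with the drug-matched bacterial growth rate).  tau > 0 with
p < alpha is called synergy, tau < 0 with p < alpha antagonism, anything
else neutral.  Because tau is rank-based, the call is invariant under
normalizing the rates to the zero-drug control and under any strictly
monotone transformation of either axis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, wilcoxon

from .curves import InsufficientDataError
from .inference import RateEstimate

__all__ = [
    "DrugGradient",
    "InteractionResult",
    "DrugComparison",
    "PairingError",
    "interaction_score",
    "normalize_rates",
    "compare_drug_profiles",
    "bonferroni",
]

logger = logging.getLogger("phorce")


class PairingError(ValueError):
    """Phage panels of two drug profiles do not match."""


@dataclass
class DrugGradient:
    """Amplification rates of one phage along one antibiotic gradient.

    ``concentrations`` (ug/mL) must be sorted ascending and include a
    zero-drug control; ``r_bac_per_conc`` are the phage-free growth rates
    measured at the matching concentrations.
    """

    drug: str
    phage: str
    concentrations: np.ndarray
    rates: List[RateEstimate]
    r_bac_per_conc: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")
        if np.any(np.diff(self.concentrations) < 0):
            raise ValueError("concentrations must be sorted ascending")
        if self.concentrations[0] != 0:
            raise ValueError("gradient must include a zero-drug control")
        if len(self.rates) != len(self.concentrations):
            raise ValueError("one rate per concentration required")
        if self.r_bac_per_conc is not None:
            self.r_bac_per_conc = np.asarray(self.r_bac_per_conc, dtype=float)
            if len(self.r_bac_per_conc) != len(self.concentrations):
                raise ValueError("one r_bac per concentration required")


@dataclass
class InteractionResult:
    """Kendall-tau interaction score of one phage-drug pair."""

    phage: str
    drug: str
    tau: float
    p_value: float
    call: str           #: 'synergy' | 'antagonism' | 'neutral'
    n_points: int


@dataclass
class DrugComparison:
    """Paired comparison of two drugs' interaction profiles."""

    signed_rank_statistic: float
    signed_rank_p: float
    cross_drug_tau: float
    cross_drug_p: float
    calls: pd.DataFrame     #: per-phage tau and call for both drugs


def _classify(tau: float, p: float, alpha: float) -> str:
    if math.isnan(tau) or math.isnan(p) or p >= alpha:
        return "neutral"
    return "synergy" if tau > 0 else "antagonism"


def interaction_score(
    gradient: DrugGradient,
    alpha: float = 0.05,
    impute_censored: bool = False,
) -> InteractionResult:
    """Score one phage-drug pair.

    Tie-corrected Kendall tau-b between concentration and amplification
    rate.  The p-value uses the exact null distribution whenever the panel
    is small (n <= 33) and tie-free — essential for calibrated calls on
    8-point gradients, where the normal approximation is anticonservative —
    and the tie-corrected normal approximation otherwise.  Below-detection
    rates are excluded (with a logged count) unless ``impute_censored``
    substitutes the detection limit — a sensitivity option, not the default.
    """
    conc, values = [], []
    n_censored = 0
    for c, rate in zip(gradient.concentrations, gradient.rates):
        if rate.below_detection and not impute_censored:
            n_censored += 1
            continue
        conc.append(c)
        values.append(rate.detection_limit if rate.below_detection else rate.r_pha)
    if n_censored:
        logger.info(
            "%s/%s: excluded %d below-detection rates",
            gradient.phage, gradient.drug, n_censored,
        )
    if len(conc) < 4:
        raise InsufficientDataError(
            f"{gradient.phage}/{gradient.drug}: only {len(conc)} usable rates (need >= 4)"
        )
    conc = np.asarray(conc)
    values = np.asarray(values)
    has_ties = len(np.unique(values)) < len(values) or len(np.unique(conc)) < len(conc)
    method = "exact" if (len(conc) <= 33 and not has_ties) else "asymptotic"
    if np.ptp(values) == 0:
        tau, p = float("nan"), 1.0
    else:
        tau, p = kendalltau(conc, values, method=method)
        tau, p = float(tau), float(p)
    return InteractionResult(
        phage=gradient.phage,
        drug=gradient.drug,
        tau=tau,
        p_value=p,
        call=_classify(tau, p, alpha),
        n_points=len(conc),
    )


def normalize_rates(gradient: DrugGradient) -> DrugGradient:
    """Express each rate relative to the zero-drug control.

    Rank-preserving (shared positive divisor), so the interaction score is
    unchanged; useful for plotting gradients of different phages together.
    """
    reference = gradient.rates[0]
    if reference.below_detection:
        raise ValueError(
            f"{gradient.phage}/{gradient.drug}: zero-drug control is below detection; "
            "cannot normalize"
        )
    r0 = reference.r_pha
    scaled = [
        replace(
            rate,
            r_pha=rate.r_pha / r0,
            se_r_pha=rate.se_r_pha / r0,
            detection_limit=rate.detection_limit / r0,
        )
        for rate in gradient.rates
    ]
    return DrugGradient(
        drug=gradient.drug,
        phage=gradient.phage,
        concentrations=gradient.concentrations.copy(),
        rates=scaled,
        r_bac_per_conc=None if gradient.r_bac_per_conc is None else gradient.r_bac_per_conc.copy(),
    )


def compare_drug_profiles(
    results_a: Sequence[InteractionResult],
    results_b: Sequence[InteractionResult],
) -> DrugComparison:
    """Paired comparison of interaction scores across a shared phage panel.

    Wilcoxon signed-rank test on the per-phage tau values of the two drugs
    plus the cross-drug Kendall correlation of those tau values, and a
    per-phage table of scores and calls.
    """
    by_phage_a = {r.phage: r for r in results_a}
    by_phage_b = {r.phage: r for r in results_b}
    if set(by_phage_a) != set(by_phage_b):
        missing = set(by_phage_a) ^ set(by_phage_b)
        raise PairingError(f"phage panels differ: {sorted(missing)}")
    phages = sorted(by_phage_a)
    tau_a = np.array([by_phage_a[p].tau for p in phages])
    tau_b = np.array([by_phage_b[p].tau for p in phages])
    diff = tau_a - tau_b
    if np.all(diff == 0):
        stat, p = 0.0, 1.0
    else:
        stat, p = wilcoxon(tau_a, tau_b)
        stat, p = float(stat), float(p)
    if np.ptp(tau_a) == 0 or np.ptp(tau_b) == 0:
        cross_tau, cross_p = float("nan"), float("nan")
    else:
        cross_tau, cross_p = kendalltau(tau_a, tau_b)
        cross_tau, cross_p = float(cross_tau), float(cross_p)
    calls = pd.DataFrame(
        {
            "phage": phages,
            "tau_a": tau_a,
            "call_a": [by_phage_a[p].call for p in phages],
            "tau_b": tau_b,
            "call_b": [by_phage_b[p].call for p in phages],
        }
    )
    return DrugComparison(
        signed_rank_statistic=stat,
        signed_rank_p=p,
        cross_drug_tau=cross_tau,
        cross_drug_p=cross_p,
        calls=calls,
    )


def bonferroni(
    results: Sequence[InteractionResult], alpha: float = 0.05
) -> List[InteractionResult]:
    """Re-call a family of interactions with Bonferroni-adjusted p-values."""
    n = len(results)
    adjusted = []
    for r in results:
        p_adj = min(r.p_value * n, 1.0)
        adjusted.append(
            replace(r, p_value=p_adj, call=_classify(r.tau, p_adj, alpha))
        )
    return adjusted
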