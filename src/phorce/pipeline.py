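"""End-to-end analysis pipeline: growth fits -> collapses -> rates -> interactions.

Stages mirror the bench protocol: bacterial growth rates come from phage-free
control wells matched on (drug, concentration); collapse times (with bootstrap
uncertainty) come from the phage wells; amplification rates invert the
collapse-time formula using the drug-matched growth rate; interaction scores
correlate rates with antibiotic concentration per phage-drug pair.
All thresholds default to the analysis conventions (fit window t > 0.5 h and
signal < 1e6 AU, collapse exclusion above 3e5 AU, 1000 bootstrap replicates,
alpha 0.05, detection limit 3e-10 mL/h) and every run writes them to a JSON
manifest; runs are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curves import (
    GrowthCurve,
    InsufficientDataError,
    bootstrap_collapse_se,
    detect_collapse,
    fit_growth_rate,
)
from .inference import (
    DETECTION_LIMIT,
    RateEstimate,
    approximate_ratio,
    rate_from_single_curve,
)
from .interactions import DrugGradient, interaction_score
from .io import read_plate_timeseries
from .synth import PlateDataset

__all__ = ["DEFAULT_THRESHOLDS", "PipelineResult", "run_pipeline", "analyze_drug_dataset"]

logger = logging.getLogger("phorce")

DEFAULT_THRESHOLDS: Dict[str, float] = {
    "t_min": 0.5,             # h, start of the growth-fit window
    "signal_max": 1e6,        # AU, ceiling of the growth-fit window
    "steady_state_max": 3e5,  # AU, collapse-exclusion threshold
    "smooth_width": 4,        # samples, peak width for collapse detection
    "n_boot": 1000,           # bootstrap replicates per collapse
    "alpha": 0.05,            # significance level for interaction calls
    "detection_limit": DETECTION_LIMIT,  # mL/h
}


@dataclass
class PipelineResult:
    per_curve: pd.DataFrame
    per_phage: pd.DataFrame
    interactions: pd.DataFrame
    manifest: dict


def _load_config(config: Union[dict, str, Path]) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _drug_label(value) -> str:
    """Normalize a drug label (empty/NaN -> no drug)."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return str(value)


def _control_growth_rates(curves: Sequence[GrowthCurve], thresholds: dict) -> Dict[tuple, float]:
    """Mean fitted growth rate per (drug, drug_conc) group of control wells."""
    rates: Dict[tuple, List[float]] = {}
    for curve in curves:
        cond = curve.condition or {}
        if cond.get("role") != "no_phage_control":
            continue
        key = (_drug_label(cond.get("drug")), float(cond.get("drug_conc") or 0.0))
        try:
            fit = fit_growth_rate(
                curve, t_min=thresholds["t_min"], signal_max=thresholds["signal_max"]
            )
        except InsufficientDataError as exc:
            logger.error("control well %r skipped: %s", curve.well_id, exc)
            continue
        rates.setdefault(key, []).append(fit.r_bac)
    return {key: float(np.mean(vals)) for key, vals in rates.items()}


def run_pipeline(config: Union[dict, str, Path]) -> PipelineResult:
    """Run the full analysis described by a declarative configuration.

    Configuration keys: ``seed`` (int), ``input`` (``timeseries``,
    ``layout``, optional ``time_unit``), optional ``thresholds`` overrides,
    optional ``output_dir``.  Stage failures are logged with their well
    context and the run continues where wells are independent.
    """
    cfg = _load_config(config)
    thresholds = {**DEFAULT_THRESHOLDS, **(cfg.get("thresholds") or {})}
    seed = int(cfg.get("seed", 0))
    inp = cfg.get("input") or {}
    curves = read_plate_timeseries(
        inp["timeseries"], layout=inp.get("layout"), time_unit=inp.get("time_unit", "h")
    )
    result = analyze_curves(curves, thresholds, seed)
    result.manifest.update(
        {
            "config_input": {k: str(v) for k, v in inp.items()},
        }
    )
    out_dir = cfg.get("output_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.per_curve.to_csv(out / "per_curve.csv", index=False)
        result.per_phage.to_csv(out / "per_phage.csv", index=False)
        result.interactions.to_csv(out / "interactions.csv", index=False)
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(result.manifest, fh, indent=2, default=str)
    return result


def analyze_curves(
    curves: Sequence[GrowthCurve], thresholds: Optional[dict] = None, seed: int = 0
) -> PipelineResult:
    """Analyze already-loaded curves (the core of :func:`run_pipeline`)."""
    thresholds = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    manifest = {
        "phorce_version": __version__,
        "seed": seed,
        "thresholds": thresholds,
        "n_curves": len(curves),
    }
    if not curves:
        warnings.warn("empty plate: no curves to analyze", stacklevel=2)
        empty = pd.DataFrame()
        return PipelineResult(empty, empty, empty, manifest)

    r_bac_by_group = _control_growth_rates(curves, thresholds)
    seeds = np.random.SeedSequence(seed).spawn(len(curves))

    rows = []
    for curve, child in zip(curves, seeds):
        cond = curve.condition or {}
        if cond.get("role") != "phage_well":
            continue
        drug = _drug_label(cond.get("drug"))
        drug_conc = float(cond.get("drug_conc") or 0.0)
        key = (drug, drug_conc)
        row = {
            "well": curve.well_id,
            "phage": cond.get("phage", ""),
            "drug": drug,
            "drug_conc": drug_conc,
            "b0": cond.get("b0", np.nan),
            "stock_dilution": cond.get("stock_dilution", np.nan),
            "r_bac": r_bac_by_group.get(key, np.nan),
        }
        try:
            est = detect_collapse(
                curve,
                smooth_width=int(thresholds["smooth_width"]),
                steady_state_max=thresholds["steady_state_max"],
            )
            if not est.censored:
                boot = bootstrap_collapse_se(
                    curve,
                    n_boot=int(thresholds["n_boot"]),
                    seed=int(child.generate_state(1)[0] % (2**31)),
                    smooth_width=int(thresholds["smooth_width"]),
                    steady_state_max=thresholds["steady_state_max"],
                )
                est.se_t_col = boot.se_t_col
                est.wide_uncertainty = boot.wide_uncertainty
            row.update(
                t_col=est.t_col,
                se_t_col=est.se_t_col,
                signal_at_collapse=est.signal_at_collapse,
                censored=est.censored,
                excluded=est.excluded,
                wide_uncertainty=est.wide_uncertainty,
            )
            b0 = row["b0"]
            dilution = row["stock_dilution"]
            if (
                math.isfinite(row["r_bac"])
                and isinstance(b0, (int, float))
                and math.isfinite(float(b0))
                and isinstance(dilution, (int, float))
                and math.isfinite(float(dilution))
                and float(dilution) > 1
            ):
                rate = rate_from_single_curve(
                    est,
                    r_bac=row["r_bac"],
                    b0=float(b0),
                    yield_=approximate_ratio(float(dilution)),
                    detection_limit=thresholds["detection_limit"],
                )
                row.update(
                    r_pha=rate.r_pha,
                    se_r_pha=rate.se_r_pha,
                    below_detection=rate.below_detection,
                    approximated_ratio=rate.approximated_ratio,
                )
        except (InsufficientDataError, ValueError) as exc:
            logger.error("well %r failed: %s", curve.well_id, exc)
            row["error"] = str(exc)
        rows.append(row)
    per_curve = pd.DataFrame(rows)

    per_phage_rows = []
    interaction_rows = []
    if not per_curve.empty and "t_col" in per_curve.columns:
        usable = per_curve[
            per_curve["censored"].fillna(True).astype(bool).eq(False)
            & per_curve["excluded"].fillna(True).astype(bool).eq(False)
        ]
        for (phage, drug, conc), grp in usable.groupby(["phage", "drug", "drug_conc"]):
            entry = {
                "phage": phage,
                "drug": drug,
                "drug_conc": conc,
                "n_wells": len(grp),
                "median_t_col": float(grp["t_col"].median()),
            }
            if "r_pha" in grp.columns and grp["r_pha"].notna().any():
                entry["median_r_pha"] = float(grp["r_pha"].median())
            per_phage_rows.append(entry)

        if "r_pha" in per_curve.columns:
            for (phage, drug), grp in per_curve.groupby(["phage", "drug"]):
                grp = grp.dropna(subset=["r_pha"]).sort_values("drug_conc")
                if drug == "" and (grp["drug_conc"] == 0).all():
                    continue
                if 0.0 not in grp["drug_conc"].values or len(grp) < 4:
                    continue
                rates = [
                    RateEstimate(
                        r_pha=r.r_pha,
                        se_r_pha=r.se_r_pha if math.isfinite(r.se_r_pha) else 0.0,
                        below_detection=bool(r.below_detection),
                        detection_limit=thresholds["detection_limit"],
                    )
                    for r in grp.itertuples()
                ]
                gradient = DrugGradient(
                    drug=drug or "drug",
                    phage=phage,
                    concentrations=grp["drug_conc"].to_numpy(),
                    rates=rates,
                    r_bac_per_conc=grp["r_bac"].to_numpy(),
                )
                try:
                    score = interaction_score(gradient, alpha=thresholds["alpha"])
                except InsufficientDataError as exc:
                    logger.error("interaction %s/%s skipped: %s", phage, drug, exc)
                    continue
                interaction_rows.append(
                    {
                        "phage": score.phage,
                        "drug": score.drug,
                        "tau": score.tau,
                        "p_value": score.p_value,
                        "call": score.call,
                        "n_points": score.n_points,
                    }
                )
    per_phage = pd.DataFrame(per_phage_rows)
    interactions = pd.DataFrame(interaction_rows)
    return PipelineResult(per_curve, per_phage, interactions, manifest)


def analyze_drug_dataset(
    dataset: PlateDataset,
    thresholds: Optional[dict] = None,
    use_true_ratio: bool = False,
):
    """Score a synthetic antibiotic-gradient dataset end to end.

    Fits the drug-matched growth rate from each phage-free well, detects the
    collapse in the matching phage well, converts it to an amplification
    rate (stock-dilution approximation of the phage fold increase by
    default; the generator's true fold increase when ``use_true_ratio``)
    and returns the interaction score.
    """
    thresholds = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    by_conc: Dict[float, dict] = {}
    for curve in dataset.curves:
        cond = curve.condition or {}
        conc = float(cond.get("drug_conc") or 0.0)
        slot = by_conc.setdefault(conc, {"phage": []})
        if cond.get("phage"):
            slot["phage"].append(curve)
        else:
            slot["control"] = curve
    concs = sorted(by_conc)
    rates = []
    r_bacs = []
    phage_name = ""
    for conc in concs:
        slot = by_conc[conc]
        fit = fit_growth_rate(
            slot["control"], t_min=thresholds["t_min"], signal_max=thresholds["signal_max"]
        )
        r_bacs.append(fit.r_bac)
        replicate_rates = []
        for curve in slot["phage"]:
            cond = curve.condition
            phage_name = cond.get("phage") or phage_name
            est = detect_collapse(
                curve,
                smooth_width=int(thresholds["smooth_width"]),
                steady_state_max=thresholds["steady_state_max"],
            )
            if use_true_ratio:
                p_col = cond.get("p_at_collapse_true") or cond.get("p_final_true")
                yield_ = approximate_ratio(max(p_col / cond["p0"], 1.0 + 1e-9))
            else:
                from .synth import PHAGE_STOCK_CONCENTRATION

                yield_ = approximate_ratio(PHAGE_STOCK_CONCENTRATION / cond["p0"])
            replicate_rates.append(
                rate_from_single_curve(
                    est,
                    r_bac=fit.r_bac,
                    b0=cond["b0"],
                    yield_=yield_,
                    detection_limit=thresholds["detection_limit"],
                )
            )
        usable = [r for r in replicate_rates if not r.below_detection]
        if not usable:
            rates.append(replicate_rates[0])  # keep the censored point
            continue
        values = np.array([r.r_pha for r in usable])
        se = (
            float(np.std(values, ddof=1) / math.sqrt(len(values)))
            if len(values) > 1
            else usable[0].se_r_pha
        )
        rates.append(
            RateEstimate(
                r_pha=float(np.median(values)),
                se_r_pha=se,
                detection_limit=thresholds["detection_limit"],
                n_curves=len(usable),
                approximated_ratio=usable[0].approximated_ratio,
            )
        )
    gradient = DrugGradient(
        drug="drug",
        phage=phage_name,
        concentrations=np.array(concs),
        rates=rates,
        r_bac_per_conc=np.array(r_bacs),
    )
    return interaction_score(gradient, alpha=thresholds["alpha"])
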