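# phorce

**P**hage-**H**ost **O**bservation for **R**ate estimation from **C**ollapse
**E**vents: a Python toolkit for quantifying the amplification rate of lytic
bacteriophages from bacterial growth curves alone — no time-resolved phage
titers required.

## The problem

Bacterial fitness is routinely summarized by a growth rate; phages have had
no comparable high-throughput metric, because phage concentrations cannot be
read out continuously the way optical density or bioluminescence can.  Yet a
lytic phage added to an exponentially growing culture leaves a sharp
signature in the *bacterial* signal: growth proceeds unperturbed until the
phage population is large enough to lyse cells faster than they divide, at
which point the culture suddenly collapses.  The timing of that collapse
encodes the phage's kinetics.

## The model

Adsorption-limited predation couples bacteria `b(t)` and phage `p(t)`:

    db/dt = r_bac b − k_adsorb p b
    dp/dt = n_burst k_adsorb p b

with bacterial growth rate `r_bac` (h⁻¹), adsorption constant `k_adsorb`
(mL h⁻¹) and burst size `n_burst`.  Only the product

    r_pha = n_burst · k_adsorb      [mL h⁻¹]

matters for the collapse: `r_pha · b` is the specific growth rate of the
phage population, so `r_pha` plays the role of a *phage amplification rate*
that is independent of the starting concentrations.  While bacteria grow
unchecked, the phage amplifies super-exponentially and the culture peaks when
`p` reaches `r_bac / k_adsorb`, giving a closed-form collapse time

    t_col = (1/r_bac) · ln[ 1 + r_bac ln(p∞/p0) / (r_pha b0) ]

where `b0`, `p0` are the initial concentrations and `p∞/p0` is the fold
increase of the phage up to the collapse.  Inverting this formula — per curve
or jointly over a whole plate of initial conditions with `r_pha` the single
free parameter — is the core of the method.  In the opposite, latency-limited
regime the collapse instead happens at a fixed phage-to-bacteria ratio
`MOI* = r_bac·τ_latency` and its time depends only on the initial MOI; the
package implements both regimes plus a diagnostic that tells them apart from
a fixed-MOI dilution sweep (collapse time falling linearly in `ln b0` is the
fingerprint of adsorption limitation).

On top of rate estimation the package scores **phage–antibiotic
interactions**: the amplification rate is measured along an antibiotic
concentration gradient (with the growth rate re-measured at each dose in
phage-free controls) and Kendall's τ between dose and rate is the interaction
score — τ > 0 with p < 0.05 is synergy, τ < 0 antagonism.

## What's in the box

| module | contents |
| --- | --- |
| `phorce.model` | ODE simulators (adsorption-, latency-limited, resistance/lysogeny-extended) and all closed forms |
| `phorce.curves` | log-linear growth fits, collapse detection (`find_peaks`), bootstrap uncertainties |
| `phorce.inference` | single-curve and joint rate estimation, calibration-based phage quantification, regime diagnostic |
| `phorce.interactions` | Kendall-τ interaction calls, drug-profile comparisons |
| `phorce.synth` | synthetic plate-reader datasets with full ground truth |
| `phorce.io` / `phorce.pipeline` / `phorce.cli` | tabular readers/writers, the end-to-end pipeline, and a `phorce` command-line tool |

## Worked example

Generate a synthetic 8×10 plate (eight bacterial × ten phage starting
concentrations, 2× serial dilutions, 5-min bioluminescence-like sampling with
5 % multiplicative noise) from a phage with true `r_pha = 1e-7` mL/h, then
run the full analysis:

```python
import numpy as np
from phorce import (PredationParams, InitialState,
                    generate_gradient_plate, detect_collapse, fit_growth_rate,
                    joint_fit_rate, YieldEstimate)

params = PredationParams(r_bac=1.0, k_adsorb=1e-9, n_burst=100)
plate = generate_gradient_plate(params, seed=1)

r_bac = np.mean([fit_growth_rate(c).r_bac
                 for c in plate.curves if c.condition["p0"] == 0])

collapses = []
for curve in plate.curves:
    cond = curve.condition
    if cond["p0"] == 0 or cond["t_col_true"] is None:
        continue
    est = detect_collapse(curve)
    if est.usable:
        collapses.append((est,
                          InitialState(cond["b0"], cond["p0"]),
                          YieldEstimate(p_ratio=cond["p_at_collapse_true"] / cond["p0"])))

fit = joint_fit_rate(collapses, r_bac=r_bac)
print(f"fitted growth rate : {r_bac:.3f} 1/h")
print(f"amplification rate : {fit.r_pha:.3e} mL/h  (true 1.000e-07)")
print(f"collapse-time fit  : r2 = {fit.r2:.3f} over {fit.n_curves} wells")
```

prints

```
fitted growth rate : 0.993 1/h
amplification rate : 1.040e-07 mL/h  (true 1.000e-07)
collapse-time fit  : r2 = 0.998 over 80 wells
```

i.e., the growth rate is recovered from the no-phage controls, all 80
collapse times are fitted simultaneously by the single free parameter
`r_pha`, and the recovered rate lands within a few percent of the generating
truth with the observed/predicted collapse times agreeing at `r² ≈ 1`.

The same analysis is available from the shell
(`phorce generate`, `phorce fit-growth`, `phorce detect-collapse`,
`phorce joint-fit`, `phorce interactions`, `phorce run --config cfg.yaml` …).

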