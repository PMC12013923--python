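# Methods

## Predation models

The base model couples bacteria `b` and free phage `p` through mass-action
adsorption: `db/dt = r_bac·b − k_adsorb·p·b`, `dp/dt = n_burst·k_adsorb·p·b`.
It deliberately omits an explicit eclipse phase, spatial structure,
multi-phage competition and stochasticity; those are outside the package's
scope.  `n_burst` is treated as a composite parameter — the number of
*replication-competent* progeny per lysis, so an efficiency of plating below
one is absorbed into it rather than modelled separately.

Units: concentrations mL⁻¹, times h, `k_adsorb` and `r_pha = n_burst·k_adsorb`
mL·h⁻¹.  All logarithms are natural and `r_bac` is the continuous specific
growth rate (doubling time `ln 2 / r_bac`).

**Collapse time.**  Neglecting predation losses on the bacteria
(`b ≈ b0·e^{r_bac t}`), the phage grows super-exponentially,
`p(t) = p0·exp[(r_pha b0/r_bac)(e^{r_bac t} − 1)]`, and the bacterial
population peaks when lysis balances growth, i.e., at phage density
`r_bac/k_adsorb`.  Substituting gives
`t_col = (1/r_bac)·ln[1 + r_bac·ln(p∞/p0)/(r_pha b0)]`, with `p∞`
approximated by the collapse density.  The rate estimator is the exact
algebraic inverse of this expression.

The approximation is accurate when the phage must amplify substantially
before the collapse: the neglected predation term contributes a relative
bias of roughly `−e^{1/ln(p∞/p0)}`-ish magnitude — measured against the exact
ODE it is −35 % at `ln(p∞/p0) = 3`, −10 % at 5, −4 % at 7 and <1 % at 12.
Practical designs should therefore keep the phage inoculum at least ~10³
below the collapse density; this is also what bounds the method's detection
limit (below).

**Latency-limited regime.**  When the latent period `τ_latency` rather than
adsorption limits the cycle, `db/dt = r_bac·b − p/τ`, `dp/dt = n_burst·p/τ`.
The linear system solves to `p = p0·e^{αt}` (`α = n_burst/τ`) and
`b = b0·e^{r t} − p0(e^{αt} − e^{rt})/(n_burst − r_bac τ)`; the denominator
`n_burst − r_bac·τ` is the one fixed by substituting the solution back into
the equations (tests verify the balance to 1e-9).  Setting `db/dt = 0` gives
a collapse at the fixed ratio `MOI* = r_bac·τ` and a collapse time

    t_col = ln[ MOI*·(n_burst − MOI* + MOI0) / (MOI0·n_burst) ] / (α − r_bac)

which depends on the initial MOI only.  This degeneracy is the basis of the
regime diagnostic: at fixed MOI, collapse times falling linearly in `ln b0`
(slope ≈ −1/r_bac) indicate adsorption limitation; a flat profile indicates
latency limitation.  With realistic parameters (`n_burst/τ ≈ 200 h⁻¹`) the
latency-limited collapse completes within minutes — far below plate-reader
cadence — so the diagnostic's latency branch is exercised on model collapse
times rather than on 5-min-sampled curves.

**Resistance and lysogeny extension.**  Sensitive cells convert to a
phage-immune resistant class at per-capita rate `r_res`; a fraction
`phi_lys` of infections lysogenize (immune, non-producing) instead of
bursting.  With literature-scale rates (`r_res = 1e-8 h⁻¹`,
`phi_lys = 1e-6`) the total-population trajectory through the initial
collapse deviates from the base model by <0.01 % — these processes shape
post-collapse regrowth, which the package intentionally does not model.

## Numerics

Simulators use `scipy.integrate.solve_ivp` with LSODA (the double-exponential
phage growth makes the system stiff near collapse), rtol 1e-8 and atol 1e-3
mL⁻¹ (sub-single-particle), overridable per call; negative round-off is
floored at zero after solving.  The adsorption simulator carries a third
state accumulating lysed bacteria so that phage-number conservation
(`p − p0 = n_burst × lysed`) is assertable to solver tolerance.  The model
collapse time is the argmax of `b` on the sampled grid — the same operational
definition the curve analysis uses — with no sub-sample refinement.
Test oracles are independent fixed-step integrators (forward Euler at
dt = 1e-4 h for the adsorption model; Heun at dt = 1e-7 h for the fast
latency dynamics, where first-order bias would exceed the step size).

## Curve analysis

Growth rates come from a least-squares line on `(t, ln signal)` restricted
to the steady-state window `t > 0.5 h` and `signal < 1e6 AU`; non-positive
signals are dropped, not floored, to avoid floor-induced bias.  The collapse
is the first local maximum found by `scipy.signal.find_peaks` with a minimum
width of 4 samples (20 min at the default cadence) and a prominence of 10 %
of the curve's dynamic range — the prominence rule is this package's
declared choice for disambiguating multiple qualifying peaks.  Collapses
with peak signal above `3e5 AU` are flagged `excluded` (outside the
steady-state exponential regime); monotone curves are `censored`.
Uncertainty comes from case bootstrap: `(t, signal)` pairs are resampled
with replacement, duplicated times jittered by 1e-9 h, collapse re-detected
per replicate (1000 by default), and the replicate SD reported; a
wide-uncertainty flag is raised when more than half the replicates lose the
collapse.

## Rate inference

Joint fits minimize squared collapse-time residuals with `ln r_pha` the only
free parameter (positivity by construction), initialized from the
single-curve estimate of the median condition.  Goodness of fit is reported
both as the squared Pearson correlation between observed and predicted
collapse times and as the coefficient of determination about the identity
line; the two differ when the fit is biased, so both are exposed.

The phage fold increase `p∞/p0` enters only logarithmically.  It can be
(a) measured by reinoculation against a calibration line
`t_col = a·ln(p0/p_stock) + b` — note the regressor is the log *relative
concentration*, so `a < 0`, and recovering `p∞` from a sample assayed after a
`d`-fold dilution multiplies by `d` — or (b) approximated by the stock
dilution of the original experiment (`approximated=True` is propagated to
downstream estimates).  Both dilution factors (reinoculation and original
stock) are carried explicitly because they enter at different stages.

**Detection limit.**  A collapse is observable only if it occurs before the
culture leaves the steady-state regime.  Since the collapse density is
`b_col ≈ b0 + r_bac·ln(p∞/p0)/r_pha`, slow phages collapse at densities
beyond the exclusion threshold and every well of a plate comes back
censored/excluded; such plates yield a below-detection result carrying the
conventional limit value 3e-10 mL·h⁻¹ rather than an estimate.  Under the
default synthetic conditions (16 h window, thresholds above) this puts
`r_pha ≤ 1e-8` below the plate's limit while `1e-7`–`1e-6` are recovered
within a few percent.

`estimate_kadsorb` disentangles `k_adsorb` from `r_pha` by regressing
`b0·(e^{r_bac t_col} − 1)` on `ln p0` (slope `−r_bac/r_pha`, intercept
`(r_bac/r_pha)·ln(r_bac/k_adsorb)`), which needs ≥2 decades of `p0`
variation; a flat dependence (the infinite-burst limit) is reported as
non-identifiable.  The estimate is intended for reconstructing full
trajectories to overlay on measured curves (integration started from the
10th data point to skip start-up noise), not as a precision estimator.

## Interaction scoring

Kendall's τ-b between antibiotic concentration and amplification rate, each
rate computed with the growth rate measured at the matching concentration in
phage-free controls — this is what disentangles host inhibition from a
genuine effect on the phage.  p-values use the exact null distribution for
tie-free panels up to n = 33 and the tie-corrected normal approximation
otherwise; on 8-point gradients the normal approximation is anticonservative
(nominal 5 % becomes ~7–12 % false positives), so the exact test is what
keeps flat gradients at the advertised α.  Below-detection rates are
excluded from the score (with imputation at the limit available as a
sensitivity flag), boundary `p = α` is called neutral, and no
multiple-testing correction is applied across phage–drug pairs by default
(a Bonferroni helper exists).  Drug profiles over a shared phage panel are
compared with the Wilcoxon signed-rank test on τ plus the cross-drug Kendall
correlation.

## Synthetic data

The generator renders any model variant as plate-reader-like signals:
logistic saturation `r_bac·b·(1 − b/K)` is added to the growth term (the
pure model lacks a stationary phase, but the analysis must be able to
exclude collapses beyond the steady-state regime), bacterial concentration
maps to signal through a scale factor, and multiplicative lognormal noise
(`σ = √ln(1+cv²)`) plus a detection floor are applied.  Ground truth —
noiseless collapse time, phage at collapse and at the end — is recorded per
well; truth is always defined on the noiseless trajectory.

Default study conditions: 5-min cadence, 16 h duration, noise CV 5 %,
scale 1e-3 AU per cell/mL and carrying capacity 1e10 mL⁻¹.  The last two
were chosen once for internal consistency of the analysis thresholds in
generator units: the growth-fit ceiling (1e6 AU) maps to 0.1 K, where growth
is still near-exponential (the induced slope bias is ≈0.6 %), and the
collapse-exclusion threshold (3e5 AU) maps to 3e8 mL⁻¹, safely inside the
exponential regime.  The gradient plate reproduces the reference 2-D design
(eight bacterial levels from 1.4e6 mL⁻¹ and ten phage levels from
1.3e6 mL⁻¹, 2× serial dilutions) plus one no-phage control per bacterial
level.  The antibiotic-gradient dataset uses a zero-drug control plus seven
doses to 3 µg/mL (linearly spaced — τ is invariant to dose spacing, and a
linear grid spreads the effect evenly across ranks) with one phage-free
control well and five phage replicate wells per dose, matching replicated
bench practice for dose–response work; replicate rates are combined by the
median per dose before scoring.  Single wells on a 5-min grid leave
borderline (~90 %) power for a 50 % monotone effect under the exact test;
replication restores it without touching the noise model.

What the generator does *not* emulate: signal nonlinearity near stationary
phase beyond the logistic ceiling, plate edge effects, condensation
artifacts, pipetting error in the dilution series, and post-collapse
resistant regrowth dynamics (the extended model produces regrowth but the
analysis does not use it).  Passing tests therefore demonstrate correctness
of the inference chain under the stated noise model, not robustness to every
artifact of real plates.

## Known limitations

- The collapse-time formula is biased low for `ln(p∞/p0) ≲ 5`
  (high-MOI inoculation); the package reports, it does not de-bias.
- Latent period and burst size are not separately identifiable from collapse
  times in the adsorption-limited regime; only `r_pha` is estimated.
- Collapse times live on the sampling grid (no sub-sample interpolation), so
  the grid spacing is a hard noise floor for every downstream quantity.
- The regime diagnostic assumes the sweep holds MOI fixed; it does not model
  intermediate regimes where `k_adsorb·b ~ 1/τ_latency`.
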