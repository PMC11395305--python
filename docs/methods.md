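# Methods

## The model

`kflux` analyzes whole-body potassium kinetics measured with stable
isotopes. A conscious animal at dietary steady state receives a constant
intravenous infusion of ⁴¹K-enriched potassium; serial plasma samples
track Δ⁴¹K/³⁹K, the change of the delta-notation isotope ratio from the
animal's own pre-infusion baseline, in per mil (‰) of the standard ratio
R₀ ≈ 0.0722.

Body K⁺ is described by three well-mixed pools: the extracellular fluid
(ECF, pool size K_ECF) and two intracellular pools that exchange K⁺ with
the ECF rapidly (ICF2, the "fast" pool — heart, kidney, stomach and other
high-perfusion tissues) or slowly (ICF3, the "slow" pool — chiefly
resting skeletal muscle). Renal excretion removes K⁺ from the ECF with
rate constant k01. Writing y_i(t) for Δ⁴¹K/³⁹K in pool i:

    dy1/dt = −(k01 + k21 + k31)·y1 + k12·y2·K_ICF2/K_ECF
             + k13·y3·K_ICF3/K_ECF + Inf(t)/K_ECF
    dy2/dt = −k12·y2 + k21·y1·K_ECF/K_ICF2
    dy3/dt = −k13·y3 + k31·y1·K_ECF/K_ICF3

with y(0) = 0 (Δ is change from baseline; basal samples carry t < 0 and
Δ = 0; t = 0 is infusion start). Because every pool is assumed at K⁺
steady state, the efflux constants are tied to the influx constants by
flux balance: k12 = K_ECF·k21/K_ICF2 and k13 = K_ECF·k31/K_ICF3. A
two-pool variant (single homogeneous ICF) is provided for model
comparison.

### Units

Pool sizes are mEq per 300 g body weight; rate constants are min⁻¹ (a
rate constant k_ij is the fraction of pool j's K⁺ transferred toward
pool i per minute); time is minutes; deltas are ‰. For monovalent K⁺,
mEq and mmol coincide.

### The forcing term

The pump setting (mg of elemental K per hour at ⁴¹K atom fraction e) is
converted to a delta-displacement rate by linearizing the measured-delta
dynamics Δ = (R − R_baseline)/R₀ about natural abundance:

    Inf_eff = 1000 · r_mol · max(e − f₄₁, 0) / (R₀ · f₃₉²)   [‰·mEq/min]

with r_mol the molar delivery rate and f₃₉, f₄₁ the natural atom
fractions. Infusing natural-abundance K (e = f₄₁) yields zero forcing,
as it must. Inf(t) equals Inf_eff during the infusion and zero after.

The *absolute* scale of the forcing depends on infusate composition
details (actual enrichment, what mass the pump setting refers to) that
are rarely reported, and in estimation it trades off only against pool
sizes, never against rate constants. `InfusionProtocol.rate_scale`
exposes this scale. The bundled protocol library sets
`rate_scale = 0.075`, calibrated once so that the forward simulation at
control-group mean parameters reproduces the experimentally observed
~1.83‰ plasma plateau at the end of a 60-min, 0.5 mg/h infusion; this
pins the synthetic data's signal-to-noise ratio (plateau vs the ~0.15‰
instrument reproducibility) to the regime the protocol-design
conclusions were drawn in. With `rate_scale = 1.0` the same pump setting
predicts a ~24‰ plateau; no claim of absolute agreement with any
particular experiment is made at either setting.

### Solvers

The system is linear and time-invariant with piecewise-constant forcing,
so the default solver is exact: eigendecomposition of the rate matrix
(always diagonalizable with real eigenvalues under flux-balance closure,
since the matrix is similar to a symmetric one), with the propagation
restarted at the infusion-off discontinuity. This is both exact and
~100× faster than adaptive integration, which matters for the Monte
Carlo study (thousands of refits). A stiff LSODA integrator
(`method="ivp"`, rtol 1e−8, atol 1e−10, integration split at the
switch-off) is retained as an independent cross-check; the two agree to
integrator tolerance in the test suite. If the eigenbasis is
ill-conditioned (possible for contrived degenerate parameter sets) the
exact solver refuses and points to the integrator.

### The exact dual-isotope oracle

`simulate_exact_isotopes` never linearizes: it tracks absolute ³⁹K and
⁴¹K amounts per compartment under isotope-blind first-order transport,
and computes Δ from the ratio definition. By default a constant
natural-abundance intake into the ECF balances the baseline renal loss
k01·K_ECF — the intake/output equilibrium the compartmental model
presumes. Two facts worth recording:

- With a pure ⁴¹K infusate the ³⁹K amounts are stationary and the exact
  delta dynamics are *identical* to the linear model at any infusion
  rate; the linearization is not an approximation in that case. The
  oracle then independently validates the forcing conversion and the
  solver (different state variables, different integrator).
- Genuine nonlinearity appears when the infusate carries ³⁹K
  (enrichment < 1), which drifts the ratio denominator; the
  linearization error then grows in proportion to dose (tested at
  enrichment 0.9: max relative gap ~2·10⁻⁴ at 0.5 mg/h vs ~2·10⁻² at
  50 mg/h).

Without the balancing intake the oracle instead represents a fasted
animal whose body K⁺ drains through the kidney (~3% over 5 h at control
excretion rates); that mode is available (`steady_state_intake=False`)
but is a different physiological assumption, not a sharper test of the
linearization.

## Parameter identification

Five parameters (K_ECF, K_ICF2, K_ICF3, k21, k31) are estimated per
animal by unweighted nonlinear least squares on the plasma Δ samples
(t > 0), using Levenberg–Marquardt in log-parameter space — positivity
is enforced by the transform, so no active bounds distort the LM steps.
The renal constant is never free: at every iterate
k01 = U/K_ECF, where U is that animal's measured urinary K⁺ excretion
(mEq/min). Holding the measured renal *flux* fixed — rather than a
pre-computed k01 value — is the only self-consistent resolution of the
circularity that k01 depends on the K_ECF being estimated. On return,
k12 and k13 are filled in by flux balance, so every reported parameter
set closes exactly. The fitter reports k01·K_ECF = U exactly, by
construction.

Default initial guess: K_ECF from plasma [K⁺] × 0.15 L/kg × body weight
(ECF volume physiology), K_ICF2 = 4, K_ICF3 = 17 mEq, k21 = 0.3,
k31 = 0.2 min⁻¹ — order-of-magnitude rat physiology. Multistart
(default 5 starts) jitters the guess log-uniformly by up to 3-fold with
a fixed substream seed; the best sum of squares wins and the start used
is recorded. On noise-free synthetic data the fitter recovers all eight
parameters to machine precision from starts several-fold off; the test
suite asserts 0.1%.

The two intracellular pools are exchangeable in the likelihood
(swapping the fast and slow pool parameter triples leaves the plasma
prediction unchanged), so every returned fit is canonicalized with
compartment 2 as the fast pool, k12 ≥ k13. Without this convention a
perfectly good optimum found with swapped labels would masquerade as
gross mis-estimation.

Non-convergent fits are returned with `converged=False` (and excluded
from group summaries), not raised. A time course that is identically
zero cannot constrain anything and raises `IdentifiabilityError`.

Residual screens report, per sampling time across animals, the mean
residual as % of the observed value, a two-tailed one-sample t test
against zero, and Bonferroni-adjusted p values (multiplied by the number
of timepoints, capped at 1). Between-animal precision is summarized as
the fractional SD, 100·SD/mean with the n−1 sample SD.

## Synthetic cohorts

The generator emulates the experiments the estimator was built for: a
60-min, 0.5 mg/h ⁴¹K infusion observed for 5 h with 20 samples
(schedule {2, 5, 10, 20, 30, 40, 50, 60, 62, 65, 70, 80, 90, 105, 120,
150, 180, 210, 240, 300} min), per-animal parameters drawn log-normally
around group means with the groups' published fractional SDs, additive
Gaussian measurement noise of 0.15‰ (the ~0.015% external
reproducibility of the isotope-ratio measurement; a proportional-noise
mode exists, since whether measurement error is absolute or scales with
the signal is rarely characterized), and a urinary
excretion measurement equal to k01·K_ECF with 10% multiplicative
log-normal error (cage urine collection is not precise). Plasma [K⁺] is
3.9 ± 0.3 mEq/L for control and 3.2 ± 0.5 for the restricted group;
body weight 290 ± 7 g. Defaults: n = 6 control, n = 7 restricted.

Log-normal between-animal dispersion is a design choice (only mean ± SD
are published; positivity is required). Random streams: one master seed
with per-animal substreams, so animal i is identical whether the cohort
has 2 or 50 members, and a cohort spec reproduces byte-identical CSVs.

What the generator does *not* emulate: circadian or meal-driven
variation, correlated parameter draws across animals, drift or
heteroscedasticity in the mass spectrometry beyond the optional
proportional mode, tissue-level deltas beyond the three model
compartments, and any misspecification of the compartmental structure
itself. Passing recovery tests therefore demonstrate that the estimator
inverts its own generative model under realistic noise — not that the
three-pool description is correct for real animals.

## Protocol identifiability study

For each candidate infusion duration (10, 30, 60, 120 min; protocols
#1, #2, #4, #6, all at 0.5 mg/h with 18–20 samples over 5 h and at
least four samples inside the infusion window) the study simulates the
noiseless plasma course at the true parameters, adds fresh noise per
replicate (grid {0, 0.0375, 0.075, 0.15, 0.3, 0.6} ‰, anchored at the
instrument reproducibility), refits with k01 fixed at its true value,
and scores each parameter as *unidentifiable* when the estimate is more
than 3-fold off (strictly: ratio > 3 or < 1/3; an exactly 3-fold
deviation counts as identified). Results are per-(protocol, noise,
parameter) probabilities with Monte Carlo standard errors
√(p(1−p)/n); 200 replicates by default (CLI `--full` gives 1000).
Optimizer failures count as unidentifiable — a design must not look
better because its pathological fits crashed — and are tallied
separately. MC fits use a single start from a generic physiological
guess; the zero-noise rows verify that this start recovers the truth
exactly, so any unidentifiability at positive noise is attributable to
the noise, not the start.

Since only the production 60-min schedule is fully specified in the
source material, the other schedules are reconstructions; the study's
conclusions are therefore asserted as directions (identifiability
degrades with noise; intermediate infusion durations identify the
efflux constants k12/k13 at least as well as the 10/120-min extremes,
compared group-wise within 2 MC SEs), never as specific curves.

## Group comparison

Per-parameter group summaries use mean ± SD, FSD, and the signed percent
change of the restricted-group mean relative to control, rounded to the
nearest integer with ties away from zero. Significance uses classic
pooled-variance Student t tests — one-tailed (restricted < control) for
the three pool sizes, where dietary restriction has a directional
hypothesis, and two-tailed for rate constants — with no multiplicity
correction in the replication-style report (the `corrected` flag records
this; Bonferroni is available). Welch's t is an option.

Tissue uptake at end of infusion is expressed as % of the plasma delta
and classified fast (≥ 50%), slow (≤ 14%) or intermediate; 14% is the
published boundary for resting skeletal muscle, 50% is this package's
round-number choice for the rapidly equilibrating organs (which sit at
61–79%).

The packaged reference statistics reproduce the published percent
changes for K_ECF (−37), K_ICF3 (−15), K_ICF2 (−10), k12 (−37), k13
(−34) and k21 (−6). The k01 (−93 vs printed −95) and k31 (−10 vs
printed −9) changes are not reproducible from the rounded printed means
(presumably computed from unrounded per-animal values) and are not
asserted anywhere.

## Numerical choices and limitations

- ODE/LM tolerances: LM ftol = xtol = 1e−12; exact solver has no
  truncation error; LSODA cross-check at rtol 1e−8/atol 1e−10.
- Problem sizes: the bundled studies use 200 Monte Carlo replicates per
  condition, 20 noisy-recovery replicates, and 1000 null simulations
  for the calibration checks — sizes chosen to put Monte Carlo standard
  errors well below the effects being asserted.
- Degenerate inputs: zero infusion rate yields identically zero deltas;
  identically zero observations raise; estimates that collapse to zero
  or overflow count as unidentifiable in the MC study.
- The 2-pool-vs-3-pool comparison asserts only the direction of the ICF
  underestimation (the single-ICF fit to two-ICF data on a 3-h,
  10-sample window understates K_ICF2 + K_ICF3); the magnitude depends
  on the exact legacy schedule, which is not published.
- Fitting is maximum-likelihood only; between-animal dispersion (FSD)
  is the precision measure. No Bayesian posteriors, no asymptotic CIs,
  no structural (rank-based) identifiability analysis.
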