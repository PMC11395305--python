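# kflux

Whole-body potassium kinetics from stable-isotope (⁴¹K/³⁹K) tracer data.

Plasma K⁺ must stay within narrow limits; the body achieves this by
shifting K⁺ between the extracellular fluid (ECF) and intracellular
stores while the kidney matches excretion to intake. `kflux` implements
the compartmental analysis behind stable-isotope studies of this system
in rats: a constant intravenous infusion of ⁴¹K-enriched potassium
perturbs the plasma ⁴¹K/³⁹K ratio, and the time course of Δ⁴¹K/³⁹K
(‰ change from the animal's baseline) is inverted to estimate pool
sizes and transfer rate constants. It is written for physiologists and
modelers who design or analyze such tracer experiments.

## The model

Three well-mixed pools — ECF (1), a "fast" intracellular pool (2:
heart, kidney, stomach, …) and a "slow" one (3: chiefly resting
skeletal muscle) — with first-order exchange and renal loss:

    dy₁/dt = −(k₀₁ + k₂₁ + k₃₁)·y₁ + k₁₂·y₂·K_ICF2/K_ECF
             + k₁₃·y₃·K_ICF3/K_ECF + Inf(t)/K_ECF
    dy₂/dt = −k₁₂·y₂ + k₂₁·y₁·K_ECF/K_ICF2
    dy₃/dt = −k₁₃·y₃ + k₃₁·y₁·K_ECF/K_ICF3

where y_i is Δ⁴¹K/³⁹K (‰) in pool i, K_* are pool sizes (mEq/300 g BW),
k_ij are rate constants (min⁻¹) and Inf(t) is the infusion forcing
(constant for the infusion duration, then zero). Steady-state flux
balance ties efflux to influx: k₁₂ = K_ECF·k₂₁/K_ICF2,
k₁₃ = K_ECF·k₃₁/K_ICF3.

Per animal, five parameters (K_ECF, K_ICF2, K_ICF3, k₂₁, k₃₁) are fit
to the plasma curve by Levenberg–Marquardt least squares in log space,
with the renal constant constrained by the measured urinary K⁺
excretion U as k₀₁ = U/K_ECF at every iterate. The package also
provides a two-pool (single-ICF) variant, an exact dual-isotope
mass-balance simulator used as an independent oracle, a synthetic
cohort generator, a Monte Carlo protocol-identifiability study, and
diet-group comparison statistics. See `docs/methods.md` for the full
account.

## Worked example

```python
from kflux import (PROTOCOLS, FitOptions, control_spec, generate_cohort,
                   fit_3c, simulate_3c, CONTROL_MEANS)

# forward-simulate the production protocol (60-min infusion, 20 samples)
y1, y2, y3 = simulate_3c(CONTROL_MEANS, PROTOCOLS["#4"])
print(f"plasma plateau at 60 min: {y1.delta_permil[7]:.2f} permil")

# generate a noisy synthetic animal and re-fit it
spec = control_spec(n_animals=1, seed=0)
animal = generate_cohort(spec)[0]
fit = fit_3c(animal, spec.protocol, FitOptions(multistart_count=3))
print(f"slow ICF pool: {fit.params.k_icf3:.1f} mEq "
      f"(truth {animal.true_params.k_icf3:.1f})")
print(f"renal flux k01*K_ECF = {fit.params.k01 * fit.params.k_ecf:.5f} "
      f"= measured urine {animal.urinary_k_excretion:.5f} mEq/min")
```

Output:

```
plasma plateau at 60 min: 1.83 permil
slow ICF pool: 17.5 mEq (truth 18.0)
renal flux k01*K_ECF = 0.00290 = measured urine 0.00290 mEq/min
```

The plateau is the calibrated control-mean signal; the fitted slow pool
lands within the ~10% precision typical for this parameter at
instrument-level (0.15‰) noise; and the renal tracer-loss flux equals
the urine measurement exactly, by construction.

A command line covers the same pipeline end to end:

```
kflux simulate --seed 1 --out cohort/
kflux fit --cohort cohort/ --out fits/
kflux montecarlo --seed 1 --out mc/
kflux compare --control fits_ctrl/ --deficient fits_kdef/ --out report/
```

Every output directory includes a `manifest.json` (config + seed +
version) sufficient to reproduce it.

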