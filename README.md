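# tumornlme

Population modelling of preclinical mammary tumour growth under
P2X7-antagonist treatment.  The package is aimed at pharmacometricians and
quantitative biologists who analyse longitudinal tumour-volume data from
mouse studies (here: orthotopic 4T1 tumours in BALB/cJ mice, treated with
the P2X7 antagonists A438079 or AZ10606120 once tumours reach 80 mm³) and
want the full analysis chain as tested, scriptable code:

- a **generalized Gompertz growth model** with a treatment effect,
- a from-scratch **SAEM** (stochastic approximation EM) estimator for the
  nonlinear mixed-effects population model, with importance-sampling
  log-likelihood and **likelihood-ratio covariate tests**,
- a **study simulator** that generates synthetic cohorts with the trial's
  design and noise structure,
- **prediction bands**, a **Hill-equation EC50 fit** for the ATP
  dose–response of the receptor, and the **Gehan–Breslow–Wilcoxon**
  survival comparison.

## Model

Tumour volume V(t) (mm³) follows

    dV/dt = k_eff(t) · V · [ln(V_max / V)]^γ,   V(0) = v0,
    k_eff = k_growth · (1 − EFF · 1{treated, t > t_start})

with log-normal inter-individual variability on `k_growth`, `V_max` and
`EFF` (sd ω on the log scale), a fixed power coefficient γ, and combined
residual error sd(y|V) = σ_add + σ_prop·V.  The substitution
u = ln(V_max/V) makes the ODE separable, so trajectories (and
humane-endpoint crossing times) are evaluated in closed form — this is
what makes whole-cohort SAEM and the Monte-Carlo calibration suites fast.
An adaptive Runge–Kutta integrator is kept as an independent cross-check.

The reference population values used throughout the defaults are
k_growth = 0.64/day (ω 39%), V_max = 1620 mm³ (ω 64%), EFF = 0.52
(ω 82%), γ = 0.17; EFF = 0.52 means treatment slows growth by a factor
1/(1 − 0.52) ≈ 2.

## Worked example

Simulate a three-arm study (vehicle / A438079 / AZ10606120, 20 animals per
arm, twice-weekly caliper volumes for 28 days) at the reference values and
refit it:

```python
import tumornlme as t

pop = t.PopulationParams()                      # reference values
design = t.StudyDesign(n_per_arm=20, seed=101)
dataset, survival = t.simulate_cohort(design, pop)

fit = t.saem_fit(dataset, t.FitSettings(seed=101, loglik_samples=0))
e = fit.estimates
print(f"k={e.k_growth_mean:.3f}/day  Vmax={e.v_max_mean:.0f} mm3  "
      f"EFF={e.eff_mean:.3f}  gamma={e.gamma:.3f}")
print(f"growth slowdown factor: {1/(1 - e.eff_mean):.2f}")

res = t.gehan_breslow_wilcoxon(survival, "vehicle", "AZ10606120")
print(f"survival: chi2={res.statistic:.2f}, p={res.p_value:.3f}")
```

Output:

```
k=0.549/day  Vmax=1586 mm3  EFF=0.417  gamma=0.172
growth slowdown factor: 1.72
survival: chi2=1.66, p=0.197
```

A single 60-animal replicate carries visible sampling noise (ω_eff is
82%); averaged over replicate studies the estimates centre on the
generating values — over seeds 101–103 the means are k = 0.635/day,
V_max = 1702 mm³, EFF = 0.545, γ = 0.182, and the implied slowdown factor
rounds to 2.

The receptor-level dose–response analysis:

```python
table = t.simulate_dose_response(ec50=4.3, hill_n=1.5,
                                 concentrations=(0.3, 1, 3, 5, 10),
                                 n_cells=6, noise_sd=0.05, seed=1)
hill = t.fit_hill(table["concentration_mM"], table["response"])
print(f"EC50 = {hill.ec50:.2f} mM, Hill n = {hill.hill_n:.2f}")
```

```
EC50 = 4.12 mM, Hill n = 1.50
```

(Responses are normalized to the 10 mM reference, so the fitted maximal
response sits above 1.)

A command-line pipeline wraps the same stages
(`tumornlme simulate|fit|lrt|predict|hill|survival|pipeline`); see
`tumornlme --help`.  Identical config and seed reproduce every output
byte for byte.  `docs/methods.md` describes the model, the estimator and
the design decisions in detail.

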