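# medlongsim

Mixed models versus structural equation models for **mediated longitudinal
data**: does a random intercept/slope linear mixed model (LMM) estimate the
*total* effect of a baseline exposure as well as the latent growth curve
SEM that explicitly models the mediation?

The motivating setting is an HIV cohort: heavy alcohol use (binary
exposure, z₂) may lower CD4 count (outcome Y, measured six times) both
directly and by worsening antiretroviral-therapy adherence (continuous
baseline mediator, x), with age (z₁) as a covariate. The package

* **simulates** cohorts from the mediated latent growth SEM

      U₃ = α₃ + γ₃₁z₁ + γ₃₃z₂ + ζ₃               x  = U₃
      U₁ = α₁ + γ₁₁z₁ + γ₁₃z₂ + b₁₃U₃ + ζ₁       Y_j = U₁ + t_j U₂ + ε_j
      U₂ = α₂ + γ₂₁z₁ + γ₂₃z₂ + b₂₃U₃ + ζ₂

  where the exposure's total effect on the latent intercept is
  γ₁₃ + b₁₃γ₃₃ (direct + indirect), including six non-normal residual
  regimes (uniform, centered lognormal, contaminated normal, two Fleishman
  power-method presets with intermediate-correlation matching);
* **fits** by maximum likelihood: the SEM (`MediatedGrowthSEM`, with
  delta-method total-effect inference and χ²/RMSEA/SRMR/AIC/BIC fit
  statistics) and random intercept/slope LMMs with and without the
  mediator (`GrowthCurveLMM`; LMM1/LMM2);
* **evaluates** the estimators by Monte-Carlo: relative bias, coverage of
  95% CIs and power for the total effect across sample sizes, standardized
  effect sizes (Cohen's 0.2/0.5/0.8, calibrated by root-finding) and error
  regimes.

The headline phenomenon: LMM2 (mediator excluded) tracks the SEM almost
exactly for the total effect, while LMM1 (mediator adjusted) estimates the
*direct* effect instead — biased by −50% under an equal effect split, with
coverage that collapses as n grows.

## Worked example

```python
import medlongsim as m

params = m.calibrate_effects(m.EffectTarget(0.5, "equal"), m.SEMParameters())
print("total effect:", round(m.total_effect(params), 4),
      "| direct:", round(params.gamma13, 4),
      "| indirect:", round(params.b13 * params.gamma33, 4))

ds = m.simulate_dataset(params, 500, m.ErrorSpec(), seed=7)
print(m.fit_sem(ds).summary())
print(m.fit_lmm(ds).summary())          # LMM2: mediator excluded
```

prints

```
total effect: 0.5774 | direct: 0.2887 | indirect: 0.2887

Mediated growth curve SEM — ML, 500 subjects, converged
log-likelihood -5953.603
   param   estimate       se
  ...
 gamma13     0.1965   0.1180
 gamma33     0.5157   0.0906
     b13     0.5673   0.0565
  ...
total effect (gamma13 + b13*gamma33): 0.4890 (SE 0.1253, 95% CI [0.2433, 0.7347], p=9.57e-05)

Growth-curve LMM (LMM2) — ML, 500 subjects, converged
log-likelihood -5314.084
     param   estimate       se
     const     0.0269   0.0897
        z1     0.2192   0.0660
        z2     0.4890   0.1253
      time    -0.0721   0.0264
G = [[1.4440, 0.1432], [0.1432, 0.2907]], sigma2 = 0.9897
exposure effect (z2): 0.4890 (SE 0.1253, 95% CI [0.2433, 0.7347], p=9.58e-05)
```

A medium standardized effect (0.5) split equally gives a true total effect
of 0.5774. Both the SEM and LMM2 estimate it at 0.4890 with identical SEs
on this cohort — the two estimators of the total effect are numerically
near-interchangeable. Adjusting for the mediator
(`m.fit_lmm(ds, include_mediator=True)`) would instead center on the
direct effect 0.2887.

Scenario grids (sample-size sweep, effect-size × split grid, error-regime
sweep) run through `medlongsim.reproduce_table` or the CLI:

```bash
medlongsim reproduce --table T1 --reps 300 --out t1.csv
medlongsim simulate --config scenario.yaml --n 250 --seed 1 --out cohort.csv
medlongsim fit cohort.csv --model lmm2
```

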