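# Methods

## The estimation problem

A binary baseline exposure (think heavy alcohol use) affects a continuous
outcome measured at six occasions (CD4 count every six months for three
years), partly directly and partly through a continuous baseline mediator
(ART adherence). The scientific estimand is the exposure's **total effect**
— direct plus mediated — on the outcome's latent growth process. The
package compares three estimators of that estimand:

* **SEM** — the mediated latent growth curve model itself, fit by maximum
  likelihood; the total effect is γ₁₃ + b₁₃γ₃₃ (intercept component) or
  γ₂₃ + b₂₃γ₃₃ (slope component), with a delta-method standard error.
* **LMM2** — a random intercept/slope linear mixed model *excluding* the
  mediator; its exposure coefficient is a consistent total-effect estimator
  because the marginal mean of the outcome given (z₁, z₂) absorbs the
  mediated path.
* **LMM1** — the same mixed model *including* the mediator as a covariate;
  conditioning on the mediator blocks the indirect path, so its exposure
  coefficient targets the **direct** effect and is badly biased for the
  total effect (−50% under an equal split).

## Data-generating model

Structural model (per subject, covariates z₁ continuous, z₂ binary):

    U₃ = α₃ + γ₃₁z₁ + γ₃₃z₂ + ζ₃            (mediator)
    U₁ = α₁ + γ₁₁z₁ + γ₁₃z₂ + b₁₃U₃ + ζ₁    (latent intercept)
    U₂ = α₂ + γ₂₁z₁ + γ₂₃z₂ + b₂₃U₃ + ζ₂    (latent slope)

Measurement model:

    Y_j = U₁ + t_j·U₂ + ε_j   (j = 1..6, t = 0..5),    x = U₃

The mediator indicator x loads on U₃ with coefficient 1 and **zero**
residual variance: x equals the latent mediator exactly, and ψ₃₃ carries
all of its residual variance. Cov(ζ) = Ψ with ψ₁₃ = ψ₂₃ = 0; the
measurement residuals are iid with variance σ².

The implied conditional moments of v = (Y₁..Y₆, x) given (z₁, z₂) follow
from the linear structure: mean E[v|z] = Λ(I−B)⁻¹(α + Γz), covariance
Λ(I−B)⁻¹Ψ(I−B)⁻ᵀΛᵀ + diag(σ²·1₆, 0). Componentwise, E[Y_j] = E[U₁] +
t_j·E[U₂] and Cov(Y_j, Y_k) = Var(U₁) + (t_j+t_k)Cov(U₁,U₂) +
t_j·t_k·Var(U₂) + 1{j=k}σ². These expressions are verified in the test
suite against a brute-force construction of the full 9-dimensional joint
(ζ, ε) covariance pushed through the linear maps, to 1e−12.

## Default parameters

| parameter | default | why |
|---|---|---|
| times t_j | 0,1,2,3,4,5 | six half-year visits on a unit time scale |
| ψ₁₁, ψ₂₂, corr(ζ₁,ζ₂) | 1, 0.25, 0.3 | unit-scale intercept variance; slope variance a quarter of it; moderate positive intercept–slope coupling |
| ψ₃₃, σ² | 1, 1 | unit scales so the variance-one error regimes plug in unchanged |
| γ₁₁, γ₂₁, γ₃₁ | 0.2 | weak covariate (age) effects; they affect no headline quantity |
| γ₃₃ | 0.5 | moderate exposure→mediator path; fixed during calibration |
| z₁ | N(0,1) | standardized age |
| z₂ | Bernoulli(0.5) | balanced exposure prevalence |

All defaults are overridable through `SEMParameters` / the YAML config.

## Effect-size calibration

The standardized effect on the latent intercept is the total effect
divided by the **total latent SD** sd(U₁) = √(b₁₃²ψ₃₃ + ψ₁₁) — the
marginal SD induced by the mediator path plus the structural residual,
excluding covariate variance, so the quantity reads as a Cohen's-d-like
standardized group difference. (Slope analogue: √(b₂₃²ψ₃₃ + ψ₂₂).)

`calibrate_effects` fixes γ₃₃, Ψ, σ² and solves for the direct coefficient
and the mediated coefficient so that (i) the standardized effect hits the
target (0.2 small, 0.35 medium-small — a repo convention, 0.5 medium, 0.8
large) and (ii) the split contract holds: *equal* puts half the total on
each path; *primarily direct*/*primarily indirect* put a fraction w = 0.8
(configurable) on the named path. Because the mediated coefficient also
inflates the denominator SD, the total effect solves a scalar root-finding
problem (Brent, |residual| < 1e−14).

**Feasibility cap.** The standardized effect from a primarily-indirect
split is bounded: as the total effect grows, b₁₃ = w·c/γ₃₃ grows with it
and the ratio c/√(b₁₃²ψ₃₃ + ψ₁₁) tends to γ₃₃/(w√ψ₃₃) — 0.625 at the
defaults. A large (0.8) effect with an indirect-heavy split is therefore
uncalibratable; the grid runner reports that cell with an explanatory note
instead of silently renormalizing.

For the slope-component (exposure-by-time) setting the calibration also
zeroes γ₁₃ and b₁₃, treating the slope effect as the sole estimand.

## Non-normal error regimes

All regimes are centered and (except one, deliberately) standardized to
the target variance. `level` selects whether only the measurement errors
ε or also the structural residuals ζ are non-normal.

* **uniform**: Uniform(−√3, √3) — unit variance, strongly platykurtic.
* **lognormal**: exp(√s·Z) − exp(s/2) with log-scale variance s solving
  (eˢ−1)eˢ = 1, i.e. s = ln((1+√5)/2) ≈ 0.4812; centered, unit variance,
  heavily right-skewed.
* **contaminated normal**: N(0,1) with probability 0.6, N(0, 10²) with
  probability 0.4. Its variance — 0.6 + 0.4·100 = 40.4 per unit of target
  variance — is **not** rescaled: the regime exists to stress the
  estimators with gross-error outliers, and the fitted residual variance
  is expected to inflate to ≈40. A flag flips the reading of the
  contamination parameter from an SD (default) to a variance.
* **fleishman1 / fleishman2**: cubic power-method transforms a + bZ + cZ² +
  dZ³ of a standard normal. Preset targets — measurement errors
  (skew, excess kurtosis) = (0.75, 0) and (1.75, 3.75); structural streams
  (0.53, −1.5), (0.5, −1.9), (0.75, −3) and (1.2, 0.4), (1.4, 0.5),
  (1.8, 0.8). The coefficient system is solved by a Newton hybrid with
  residuals below 1e−10.

**Feasibility clamp.** The six structural preset pairs all lie outside the
Fleishman-feasible region (excess kurtosis −3 is below the universal −2
bound; the positive-kurtosis pairs sit below the family's skew-dependent
boundary). The solver walks the kurtosis up to the feasible boundary
(bisection to ~1e−2), keeps the stated skewness exactly, and emits a
`RuntimeWarning` recording the substitution.

**Correlated non-Gaussian streams.** The structural residuals must keep
Cov(ζ) = Ψ. All families use a Gaussian-copula intermediate correlation
ρ_Z chosen so the transformed pair hits the target correlation r:
for power-method margins, ρ_Z solves the cubic
r = ρ_Z(b_ib_j + 3b_id_j + 3d_ib_j + 9d_id_j) + ρ_Z²(2c_ic_j) + ρ_Z³(6d_id_j);
for uniforms, ρ_Z = 2 sin(πr/6) exactly; for equal-log-variance
lognormals, ρ_Z = ln(1 + r(eˢ−1))/s exactly. The contaminated structural
streams instead share one per-subject contamination indicator, which
preserves their correlation under the variance inflation.

**Seeding.** One root seed per replicate; sub-streams for covariate draws,
structural residuals and measurement residuals are spawned from it
(`numpy.random.SeedSequence`), so changing the effect split or the error
family of one stream leaves the others' draws untouched.

## Estimation

**SEM.** Case-wise conditional ML: v|z is MVN with the implied moments
above, so the log-likelihood depends on the data only through VᵀV, VᵀW,
WᵀW (W the n×3 design (1, z₁, z₂)) — each evaluation is O(1) in n.
Conditioning on the covariates is exact for a binary exposure (no
pseudo-normality assumption on z), and the maximizer minimizes the
distance between observed and model-implied mean and covariance
structure. Sixteen free parameters; variances on a log scale and the
(ψ₁₁, ψ₁₂, ψ₂₂) block log-Cholesky, which keeps iterates inside the
parameter space (no Heywood excursions). L-BFGS-B from data-driven starts
(two-stage OLS), with up to three perturbed restarts; convergence is
declared when the optimizer reports success or the finite-difference
gradient is at its noise floor (1e−6·|loglik|). Standard errors come from
the inverse observed information — a central-difference Hessian in the
natural parameterization. The total-effect SE is delta-method:
g = (1, γ₃₃, b₁₃) on the (γ₁₃, b₁₃, γ₃₃) block of the vcov (verified
against a nonparametric bootstrap within 10%).

**LMM.** ML (not REML, so −2LL/AIC/BIC are comparable across fixed-effect
specifications). With fixed times and complete data the per-subject
marginal covariance V = ZGZᵀ + σ²I₆ is shared by all subjects; the fixed
effects are profiled out by GLS and the four covariance parameters
(log-Cholesky G, log σ) optimized by L-BFGS-B. Fixed-effect SEs are the
GLS/profile (ΣXᵀV⁻¹X)⁻¹ at the ML covariance estimates — the exact
observed information for the mean block, since the likelihood is quadratic
in β. Point estimates and maximized likelihoods agree with statsmodels
MixedLM (ml) to ~1e−5 in the tests; MixedLM's joint-Hessian SEs differ by
up to ~10% at n=150 through β–θ cross terms, a convention difference, and
are checked only coarsely.

**Equivalence.** With the mediator paths removed and no covariate-by-time
terms, the SEM subclass and LMM2 are the same marginal model; the tests
verify their maximized likelihoods agree to 1e−6.

## Fit statistics

The SEM's saturated reference frees an intercept and (z₁, z₂) coefficients
for each of the 7 observed variables (21 mean parameters) plus an
unstructured 7×7 covariance (28), so df = 49 − 16 = 33. χ² = 2(llₛₐₜ −
ll); RMSEA = √(max(χ²−df, 0)/(df(N−1))); SRMR is the root mean square of
the standardized residuals between saturated and model-implied moments
(lower-triangle covariances plus means at the average covariate value,
standardized by saturated SDs). The saturated definition and the SRMR mean
convention are package choices — software packages differ here. AIC/BIC
use −2ll + 2k and −2ll + k·ln(N) with N the number of subjects. LMMs
report −2LL/AIC/BIC only.

## Monte-Carlo study

Per scenario: calibrate, simulate `reps` cohorts (replicate i uses seed
base+i), fit the requested models, and summarize over converged replicates:

* relative bias% = 100·(mean estimate − truth)/truth. The sign convention
  follows the published tables (an estimator converging to half the truth
  reports −50%); the verbal "true minus mean over true" definition would
  flip it.
* coverage% of nominal 95% Wald CIs; power% of two-sided Wald z-tests at
  α = 0.05.
* `mc_ci_width(p, reps)` = 200·z₀.₉₇₅·√(p(1−p)/reps) percentage points —
  the precision yardstick (≈5.0 pp for power 0.8 at 1000 reps, ≈2.7 pp for
  coverage 0.95).

Non-converged replicates are excluded and counted (`n_converged`); a
scenario where every replicate fails raises.

Problem sizes: the packaged checks run the n=500 sample-size scenario at
300 replicates, the contaminated-normal scenario at 200 replicates of
n=250, and moment checks on 10⁶ draws; `reproduce_table` defaults to 1000
replicates with `--reps` for smaller runs. At 300 replicates the
Monte-Carlo half-width around 95% coverage is ≈2.5 pp.

## Known limitations

* Complete data only: no dropout or intermittent missingness, so the
  ML fitters never face unbalanced designs.
* One mediator, measured once, without error; no time-varying exposures.
* The non-normal structural-correlation mechanism (Gaussian copula /
  shared contamination indicator) is one defensible construction among
  several; published variance/correlation targets are matched but joint
  tail behaviour is construction-specific.
* Absolute fit-statistic values depend on nuisance parameters (N, Ψ, σ²)
  and are not comparable across parameterizations; only their formulas and
  qualitative behaviour are exercised.
* Wald (z) inference throughout; no small-sample t or Satterthwaite
  corrections, so coverage at n ≲ 25 runs slightly below nominal.
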