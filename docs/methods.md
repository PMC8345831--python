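# Methods

## Problem setting

A national two-stage cluster survey measures a binary outcome (HIV status)
on a few dozen to a few hundred respondents per district. Direct
design-weighted estimates are unbiased but unstable at that sample size;
small-area estimation borrows strength across districts through auxiliary
data. The package implements the two classical model families — an
area-level (Fay-Herriot) model on aggregated direct estimates and a
unit-level logistic mixed model on individual records — plus the precision
and consistency diagnostics used to compare them, and a synthetic survey
generator that makes every stage testable against known truth.

## Direct estimation

Per district i the Hájek ratio p̂ᵢ = Σ wᵢⱼ yᵢⱼ / Σ wᵢⱼ over its sampled
records (invariant to the weight scale). Variance by Taylor linearization of
the ratio: scores zᵢⱼ = wᵢⱼ(yᵢⱼ − p̂ᵢ)/Σw are totalled per cluster (PSU) and
the single-stratum with-replacement formula nₚ/(nₚ−1)·Σ(Z_c − Z̄)² is
applied. Consequences users should know:

- The with-replacement approximation is accurate when the first-stage
  sampling fraction is small (the regime of real national surveys); at
  fractions ≳50% it is conservative. No finite-population correction is
  applied.
- Normal-theory CIs p̂ ± 1.96·se (truncated to [0,1]) undercover when a
  district has few PSUs — the variance estimate has ~(nₚ−1) df, and 1.96
  understates the matching t quantile.
- A district with a single PSU has no internal variance information; its
  variance is computed by collapsing with a neighbouring district's PSUs
  (which carry zero score for this district's domain), with a logged
  warning. `on_single_psu="error"` raises instead.
- Districts with p̂ ∈ {0, 1} keep their direct estimate and truncated CI but
  are flagged ineligible for the area model: ψᵢ is undefined there. They
  re-enter the FH output with the synthetic prediction (γ = 0).

The logit transform uses the delta method: θ̂ = logit(p̂),
ψ = se²/(p̂(1−p̂))². ψ is treated as known downstream and is not smoothed
(no generalized variance function); smoothing would be a natural extension.

## Fay-Herriot area-level model

Sampling model θ̂ᵢ = θᵢ + eᵢ, eᵢ ~ N(0, ψᵢ); linking model θᵢ = zᵢᵀβ + vᵢ,
vᵢ ~ N(0, σᵥ²). σᵥ² is estimated by maximizing the profile (restricted)
Gaussian likelihood with bounded scalar optimization on [0, max(10·var(θ̂),
10·max ψ)], converged to 1e-10 and truncated at the boundary whenever the
boundary value is at least as good — so σ̂ᵥ² = 0 is an admissible outcome
and γᵢ = 0 for all districts there, with no ad-hoc floor. REML is the
default (smaller small-m bias of σ̂ᵥ²); ML is used when models with
different fixed effects are compared by AIC = −2·loglik + 2(p+1), ties going
to fewer parameters. β̂ is GLS with weights 1/(σ̂ᵥ² + ψᵢ).

MSE of the EBLUP follows the Prasad-Rao decomposition g₁ + g₂ + 2g₃ with
g₁ = γᵢψᵢ, g₂ = (1−γᵢ)² zᵢᵀ cov(β̂) zᵢ, g₃ = ψᵢ²(σᵥ²+ψᵢ)⁻³·V̄(σ̂ᵥ²),
V̄ = 2/Σ(σᵥ²+ψⱼ)⁻²; under ML the Datta-Lahiri bias-correction term
−b(σ̂ᵥ²)·(1−γᵢ)² is added. Districts without a direct estimate get the
synthetic-prediction MSE σ̂ᵥ² + zᵢᵀ cov(β̂) zᵢ.

Prevalence-scale output: p = expit(θ̂ᶠᴴ), MSE_p = MSE_logit·(p(1−p))²
(delta method), and CIs symmetric on the logit scale, back-transformed —
hence always inside (0,1). Whether real-data CIs should instead be
prevalence-scale symmetric is not determined by the method; the logit
construction was chosen because it respects the parameter space.

## Unit-level model and EBP

Random-intercept logistic regression logit P(yᵢⱼ=1|xᵢⱼ,vᵢ) = xᵢⱼᵀβ + vᵢ,
vᵢ ~ N(0, σᵥ²), fit by maximum likelihood. The per-district likelihood
integrates vᵢ out with *adaptive* Gauss-Hermite quadrature (15 nodes by
default): nodes are centred at the posterior mode of vᵢ (found by a
vectorized, globally convergent Newton iteration on the strictly concave
log-posterior) and scaled by the posterior curvature. A 50-node version
agrees with 201-point brute-force trapezoid integration to below 1e-6 in
log-likelihood on test fixtures. The optimizer is L-BFGS-B on (β, log σᵥ)
with log σᵥ ∈ [log 1e-4, log 10]; the gradient uses the Fisher identity
(posterior-weighted complete-data score) evaluated on the same quadrature
nodes, and is verified against finite differences in the test suite. The fit
is also cross-checked against R lme4's `glmer` (nAGQ=25) on a fixture.

Design weights are **not** used in fitting: the likelihood is the unweighted
population model. On an informative (unequal-probability) design the
estimates are model-based, not design-consistent — users with strongly
informative designs should be aware. Treatment contrasts use the first
listed category as reference (age 15-19, male, no education, single, 0
partners).

The EBP plugs the empirical-Bayes modes v̂ᵢ into
p̂ᵢⱼ = expit(xᵢⱼᵀβ̂ + v̂ᵢ) and sums observed outcomes over the sampled set S
and predictions over the non-sampled set S′: p̂ᵢ = (Σ_S y + Σ_{S′} p̂)/Nᵢ.
This is the plug-in form; a full conditional-expectation EBP would integrate
over vᵢ|y and differs only at third order for district-mean functionals.
When the prediction frame is an auxiliary subsample rather than the full
non-sampled population, the mean prediction is scaled up to Nᵢ − nᵢ.
Districts absent from the fitting sample use v̂ᵢ = 0 (synthetic prediction);
`skip_unsampled=True` drops them instead, as an analyst without auxiliary
data for those districts would.

### Parametric bootstrap MSE

Finite-population bootstrap with the sampled units held fixed: per replicate
draw v*ᵢ ~ N(0, σ̂ᵥ²), regenerate yᵢⱼ* ~ Bernoulli(expit(xᵢⱼᵀβ̂ + v*ᵢ)) for
every unit in every frame, record the replicate's realized finite-population
prevalence p*ᵢ, refit the model on the original sampled units (warm-started
at the original estimates), recompute the EBP, and average (p̂*ᵢ − p*ᵢ)²
over B replicates (default B=200). Replicates with a degenerate outcome
vector or a failed refit are skipped; more than 20% failures raises. The
nested Monte-Carlo check in the acceptance suite (100 outer replicates ×
B=100 at 20 districts × 100 units, 30 sampled each) finds the bootstrap MSE
within a factor 2 of the empirical EBP MSE for ≥90% of districts.

## Synthetic survey generator

The generator emulates the structure the models assume, at the documented
scale: 70 districts with populations log-uniform on [2,000, 20,000], ~20
clusters per district with log-normal sizes, two-stage samples (systematic
PPS-by-size with certainty selections at the first stage, SRS of 25 per
cluster at the second, weights = inverse inclusion probabilities, which
calibrate exactly to Nᵢ), district sample sizes ~50-500, and covariate
marginals matching published national survey distributions of sex, age,
education, marital status and partner count.

Choices made where realism had to be designed in, with their defaults:

- **District random effect** σᵥ = 0.25 on the logit scale — unexplained
  district heterogeneity.
- **Cluster random effect** σ_cluster = 0.9 — enumeration areas correlate
  strongly in HIV risk (fishing villages, transport corridors); this yields
  district design effects around 2-3, as population HIV surveys exhibit.
  Without it the synthetic direct estimates would be unrealistically precise
  and no direct-vs-model contrast would exist.
- **District covariate composition** drawn Dirichlet(10 × national
  marginals): districts differ demographically, so the unit-level model has
  genuine composition signal — the mechanism behind its close tracking of
  direct estimates. `composition_concentration=None` gives identical
  composition everywhere. Covariates remain mutually independent given the
  district: only marginal, not joint, structure is emulated; this is a known
  limitation.
- **Outcome coefficients**: prevalence higher for women, rising with age,
  elevated after marital dissolution and with 2+ partners; intercept set so
  the marginal national prevalence is ≈6%.
- **ANC-style area proxy** zᵢ = logit(pᵢ) + 0.3 + N(0, 0.4²): antenatal
  surveillance prevalence is a biased, noisy proxy of general-population
  prevalence. It is generated at district level directly (the FH model
  consumes only the aggregate); no pregnant-women subpopulation is
  simulated.

Under these defaults the pipeline reproduces the qualitative pattern
documented for real data — SD(direct) > SD(unit-level) > SD(area-level),
bias-regression slopes ≈0.65 (unit) and ≈0.4 (area) — without any of those
quantities being targeted. What passing tests show is that the *methods*
behave as theory predicts on data with this structure; they cannot show that
real survey data satisfy the models' assumptions (no non-response, no weight
calibration, no informative sampling within district, no spatial correlation
between districts, outcome model correctly specified).

## Problem sizes used in the test suite

Simulation-based assertions are sized for tight Monte-Carlo control at
desk-scale runtimes: 200 replicates for area-model parameter recovery and
EBLUP dominance (m=70), 100 replicates for unit-model recovery (70×200) and
for the comparison pattern (default generator scale), and a 100×(B=100)
nested design at 20 districts × 100 units for bootstrap calibration.
Tolerances are stated as multiples of the replicate Monte-Carlo standard
error, or as the documented qualitative inequality.

## Pipeline

Stage seeds derive from the master seed by SHA-256 hashing of the stage
name, so the random streams of earlier stages never change when later stages
are added or re-run; identical configurations produce byte-identical
outputs. Input validation (schema, weight positivity, binary outcome,
district cross-references) runs before any computation. All tabular IO is
headered CSV; configuration YAML; the manifest (config hash, seeds, package
version, record counts) JSON.

## Known limitations

- No spatial correlation between district effects (a CAR extension is out of
  scope); no hierarchical-Bayes FH; no design-weighted pseudo-likelihood for
  the unit model; no replicate-weight variance estimation.
- ψᵢ is treated as exactly known; its estimation error is ignored by the FH
  model, as is conventional.
- The single-PSU collapse and the normal-theory CIs are pragmatic
  conventions, inappropriate for districts with very few PSUs.
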