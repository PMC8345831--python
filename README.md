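# saeprev

Small-area estimation (SAE) of district-level HIV prevalence from complex
survey data, for epidemiologists and survey statisticians who need
district-resolution estimates from surveys powered only for regional
estimates.

National household surveys (PHIA-type two-stage cluster samples) yield
design-unbiased *direct* prevalence estimates per district, but with sample
sizes of a few dozen to a few hundred per district these are too unstable for
local decision-making. `saeprev` implements the two standard model-based
remedies and the diagnostics used to compare them:

1. **Direct estimation** — the Hájek ratio
   p̂ᵢ = Σⱼ wᵢⱼ yᵢⱼ / Σⱼ wᵢⱼ with Taylor-linearization standard errors
   (clusters as with-replacement PSUs within the district stratum), and its
   logit transform θ̂ᵢ = logit(p̂ᵢ) with delta-method sampling variance ψᵢ.

2. **Fay-Herriot area-level model** — on the logit scale,
   θ̂ᵢ = zᵢᵀβ + vᵢ + eᵢ with vᵢ ~ N(0, σᵥ²), eᵢ ~ N(0, ψᵢ), ψᵢ known; the
   EBLUP is the shrinkage combination
   θ̂ᵢᶠᴴ = γᵢ θ̂ᵢ + (1 − γᵢ) zᵢᵀβ̂, γᵢ = σ̂ᵥ²/(σ̂ᵥ² + ψᵢ),
   with σᵥ² estimated by REML (ML for AIC-based covariate selection), the
   Prasad-Rao g₁+g₂+2g₃ MSE, and a district-level auxiliary covariate such as
   logit antenatal-care (ANC) prevalence.

3. **Unit-level logistic mixed model** — logit P(yᵢⱼ=1) = xᵢⱼᵀβ + vᵢ, fit by
   maximum likelihood with adaptive Gauss-Hermite quadrature; district
   prevalence by the empirical best predictor (EBP)
   p̂ᵢ = (Σ_{j∈S} yᵢⱼ + Σ_{j∈S′} p̂ᵢⱼ)/Nᵢ over sampled (S) and non-sampled
   (S′) individuals, with MSE from a finite-population parametric bootstrap.

4. **Comparison diagnostics** — coefficients of variation with the CV < 20%
   reliability rule, OLS bias regression of model-based on direct estimates,
   MSE-ratio precision gains, and seven-number summary tables.

A synthetic-survey generator (district and cluster random effects on the
logit scale, district-varying covariate composition, PPS-by-size two-stage
sampling, a biased noisy ANC-style proxy) makes the whole pipeline testable
end-to-end against known truth.

## Worked example

```python
from saeprev import PipelineConfig, run_pipeline

config = PipelineConfig(master_seed=1, bootstrap_B=100, out_dir="demo_out")
run_pipeline(config)   # simulate -> direct -> FH -> unit-level -> compare
```

This writes `sample.csv`, `direct_estimates.csv`, `fh_estimates.csv`,
`unit_estimates.csv`, `comparison.csv` plus model summaries and a manifest.
On the default configuration (70 districts, ~14,000 respondents) the
comparison report contains, for seed 1:

| quantity | direct | area-level (FH) | unit-level (EBP) |
|---|---|---|---|
| mean prevalence | 0.061 | — | — |
| SD of estimates | 0.036 | 0.017 | 0.025 |
| bias slope vs direct | — | 0.39 | 0.65 |
| r² vs direct | — | 0.69 | 0.93 |
| mean CV (%) | 46.3 | 24.9 | 26.8 |

Read: the direct estimates are over-dispersed (their SD includes sampling
noise); both model-based estimators shrink toward their synthetic parts, the
area-level model hardest (smallest SD, flattest slope); the unit-level
estimates track the direct ones most closely (slope 0.65, r² 0.93) because
they exploit each district's covariate composition. Both model families cut
the mean squared error against the simulated truth — the printed precision
gains are ~81% (area) and ~83% (unit) for this configuration — and bring far
more districts under the CV < 20% reliability bar than the direct estimator.

The same stages are available as a CLI:

```sh
saeprev run-all --seed 1 --out-dir demo_out
saeprev direct demo_out/sample.csv --out direct.csv
```

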