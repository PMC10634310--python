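# bpvar

Bayesian panel vector autoregression (BPVAR) for country-year panels, built
for studying how macro-level shocks — e.g. a surge in economic uncertainty —
propagate to population-health outcomes across a large cross-section of
countries. It targets applied researchers in health economics and
macro-epidemiology who have a long-format panel of a few jointly endogenous
variables (an uncertainty index, GDP per capita, CO₂ emissions, healthcare
expenditure, a health indicator) for many countries over a few decades.

## The model

For country *i* and year *t*,

```
y_it = α_i + β_i·t + A_1 y_{i,t-1} + … + A_P y_{i,t-P} + u_it,   u_it ~ N(0, Ω)
```

Lag dynamics `A_j` and the innovation covariance `Ω` are pooled across
countries; country heterogeneity is absorbed by fixed effects `α_i` and
country-specific linear trends `β_i·t`. Shrinkage is imposed with **dummy
observations** — artificial data rows appended to the sample so that
conjugate least squares implements a Minnesota-type prior (own first lags
centred on γ, tightness τ, linear lag decay, AR(1)-based residual scales σ),
a loose prior on the deterministic terms (scale c), and a
sum-of-coefficients prior (scale λ). Defaults are the loose reference
settings γ=1, τ=1, c=0.001, λ=10.

Estimation alternates the two exact conditional posteriors (Gibbs sampling)
on the dummy-augmented sample `(Y*, X*)`:

```
B | Ω ~ N(B*, Ω ⊗ (X*′X*)⁻¹),   B* = (X*′X*)⁻¹X*′Y*
Ω | B ~ IW(S*, n* − K),          S* = (Y* − X*B)′(Y* − X*B)
```

Structural shocks are identified recursively via the Cholesky factor
`Ω = A0·A0′` with the uncertainty index ordered first and the health
indicator last; impulse responses are propagated through the companion
matrix and summarized by the posterior median with a 68% band (16th/84th
percentiles). Chain quality is reported as inefficiency factors (Parzen-
windowed autocorrelation time; ≈1 for well-mixing chains).

A synthetic-data module generates balanced panels from a known stable truth
— including a study-scale fixture of 103 countries × 25 years × 5 variables
with emerging/developing and income-tier labels — so the entire pipeline is
testable offline with ground truth in hand.

## Worked example

```python
import bpvar as bv

panel, truth = bv.make_study_fixture(seed=42)            # 103 × 25 × 5 panel
spec   = bv.VARSpec(tuple(panel.variable_order), lag_order=1)
design = bv.build_design(panel, spec)
hyper  = bv.default_hyperparams(panel, spec)             # γ=1, τ=1, c=0.001, λ=10
dummies = bv.build_dummies(spec, hyper, panel.n_countries)
draws  = bv.run_gibbs(design, dummies,
                      bv.GibbsConfig(n_total=2000, n_burn=1000, seed=42), spec=spec)

irfs    = bv.compute_irfs(draws, "uncertainty", shock_size=0.01, horizons=10)
summary = bv.summarize_irf(irfs)
print(summary.table[summary.table.response == "health_indicator"].head(4).to_string(index=False))
print(bv.convergence_report(draws))
```

prints

```
      shock         response  horizon   median       p16      p84
uncertainty health_indicator        0 0.001439  0.001218 0.001667
uncertainty health_indicator        1 0.000319  0.000117 0.000535
uncertainty health_indicator        2 0.000107 -0.000061 0.000275
uncertainty health_indicator        3 0.000071 -0.000047 0.000185

{'n_retained': 1000, 'coefficients': {'n_monitored': 25, 'min': 0.835, 'max': 1.106},
 'covariance': {'n_monitored': 15, 'min': 1.052, 'max': 1.257}}
```

Reading: a 1% uncertainty shock moves the (synthetic) health indicator by
+0.14% on impact, decaying toward zero within a few years; the 68% band
excludes zero only at short horizons. Inefficiency factors near 1 say the
1,000 retained draws carry nearly iid information.

The same analysis runs from the shell: `bpvar simulate`, `bpvar prepare`
(quarterly→annual averaging, logs, balancing), `bpvar fit`, `bpvar irf`,
`bpvar grid` (health-indicator × lag × subsample grids from one YAML
config), and `bpvar compare` (emerging vs developing overlays). See
`bpvar --help`.

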