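# Methods

## Model and estimator

The package estimates a homogeneous-dynamics panel VAR(P) with country fixed
effects and country-specific linear trends,

    y_it = α_i + β_i·t + Σ_{j=1..P} A_j y_{i,t−j} + u_it,  u_it ~ N(0, Ω),

on a balanced panel of N countries and T years. Each country contributes
T − P stacked rows; lags never cross country boundaries. The regressor block
X has K = M·P + ex columns: the M·P lag columns (lag-major), then one dummy
column per country, then one trend column per country holding that country's
within-sample time index (0…T−1, of which rows P…T−1 are used). The time
index is anchored at each country's first panel year; any other origin is
absorbed into the fixed effect, so the anchoring only affects the reported
α_i, not dynamics or impulse responses.

The model deliberately excludes cross-sectional interdependencies,
unit-specific slopes, and time variation in parameters: heterogeneity enters
only through the deterministic terms.

## Prior via dummy observations

The prior is imposed by appending TD = M·P + M + 1 + M artificial rows to
(Y, X) and running conjugate least squares on the augmented sample:

1. **Coefficient block** (M·P rows). The row for variable m at lag j has
   X-entry j·σ_m/τ on the matching lag column and Y-entry γ·σ_m/τ on column
   m when j = 1 (zero otherwise): own first lags shrink toward γ, all other
   lag coefficients toward zero, with tightness growing linearly in the lag
   index. σ_m are residual scales from pooled AR(1) regressions with country
   intercepts (within-country demeaning), matching the pooled-dynamics
   assumption; a per-country variant was considered and rejected as
   inconsistent with homogeneous A_j.
2. **Covariance block** (M rows): Y = diag(σ), X = 0, anchoring the scale of Ω.
3. **Deterministic-terms block** (1 row): X = c on every fixed-effect and
   trend column. Small c (default 0.001) makes this prior essentially
   uninformative; a single row keeps TD independent of N.
4. **Sum-of-coefficients block** (M rows): diag(γ·μ)/λ on Y and replicated
   across every lag block of X, shrinking each variable's summed lag
   coefficients toward γ persistence. μ are pre-sample means (each
   variable's first P observations per country, averaged over countries).

Defaults γ=1 (random-walk prior, suited to persistent log levels), τ=1,
c=0.001, λ=10 — a loose belief in which the data dominate; all exposed in
`PriorHyperparams` and the pipeline config.

## Gibbs sampler

Two-block sampler on the stacked data: Ω | B ~ IW(S*, n* − K) with
S* = (Y* − X*B)′(Y* − X*B), then B | Ω ~ N(B*, Ω ⊗ (X*′X*)⁻¹). The degrees
of freedom use the stacked row count n* = n_obs + TD, consistent with S*
being computed on the augmented residuals. The chain starts at (B*, S*/dof).
B* and the Cholesky factor of X*′X* are computed once (they do not change
along the chain); coefficient draws use the matrix-normal factorization
B = B* + L⁻ᵀ Z C′ (L the Gram factor, C the Cholesky factor of Ω), so the
(K·M)² covariance is never materialized. No explicit matrix inversion
anywhere; rank deficiency of X*′X* raises an error suggesting dummies or
column pruning rather than silently regularizing. The reference schedule is
55,000 total / 45,000 burn-in / thin 1 (10,000 retained), available as the
`reference` profile; the default `desk` profile (2,000/1,000) is the
problem size used throughout the tests and the acceptance script, chosen
because the chain mixes nearly iid (inefficiency factors ≈ 1) so longer runs
sharpen nothing but Monte-Carlo noise.

## Identification and impulse responses

Ω = A0·A0′ with A0 lower triangular: the recursive ordering places the
uncertainty index first (treated as contemporaneously exogenous to the
macro block) and the health indicator last. A shock of size s to variable k
uses A0's k-th column rescaled so the shock variable's impact response is
exactly s; horizons propagate through companion-matrix powers, excluding
deterministic terms. The "1% shock" convention: variables other than the
uncertainty index enter in logs, so s = 0.01 is one percent; for the
unlogged index, s = 0.01 is one percent of unit scale. Both are
configurable. Bands are pointwise 16th/84th percentiles (68%) plus the
median across retained draws.

## Convergence diagnostics

Inefficiency factor IF = 1 + 2·Σ_k w(k)·ρ̂(k), with sample autocorrelations
tapered by a Parzen window of bandwidth 4·(n/100)^0.25 and truncated at the
first adjacent lag pair whose summed autocorrelation is nonpositive. An iid
chain gives IF ≈ 1; mildly negative autocorrelation legitimately yields
values below 1. Monitored scalars: all lag-block coefficients and the unique
entries of Ω (deterministic-term coefficients excluded by default, as their
count grows with N and they mix as well as the rest).

## Synthetic data

The generator simulates exactly the model above: a stable truth (companion
spectral radius capped, default 0.9), SPD innovation covariance, country
effects drawn N(0, 1) and trend slopes N(0, 0.01²) — modest drift against
unit-scale innovations, since no empirical heterogeneity magnitudes are
available. Each country starts at its deterministic steady state and 100
burn-in periods are discarded. The study-scale fixture (103 countries ×
25 years × 5 variables, VAR(1), own lags centred near 0.6–0.95) mimics the
dimensions and persistence of a real uncertainty-and-health panel, with
deterministic group labels (first 40% "emerging"; income tiers round-robin)
for subsample runs. What it does **not** emulate: ragged country coverage,
measurement error, non-Gaussian tails, structural breaks, or any real-world
marginal distributions — passing tests demonstrate the estimator's internal
correctness and frequentist behaviour under its own assumptions, not
robustness to real data pathologies.

## Validation results and a known limitation

With no dummy rows the posterior location reproduces equation-by-equation
OLS to 1e-10, and conditional-draw moments match their closed forms
(mean B*, covariance Ω ⊗ (X*′X*)⁻¹; inverse-Wishart mean S*/(dof−M−1)).
As τ → 0 the posterior mean first-own-lag coefficients approach γ
monotonically.

On 20 synthetic panels at the study's cross-section (N=50, T=25, M=3),
posterior medians recover the lag matrix with RMSE ≈ 0.06, but the 68%
bands cover the truth only ~44% of the time. This is the dynamic-panel
(Nickell) bias: demeaning implicit in fixed effects plus trends biases
own-lag estimates by roughly −2(1+ρ)/T, which at T=25 is several posterior
standard deviations wide of the truth. The same code shows coverage rising
to 0.53 at T=100 and 0.64 at T=400 with vanishing bias, confirming the
sampler is calibrated and the shortfall is intrinsic to short-T panels
under this (entirely standard) estimator. Users should read short-T
credible bands for lag coefficients — and to a lesser degree for IRFs — as
optimistic.

## Numerical choices

- SPD checks symmetrize and require the smallest eigenvalue above
  −1e-10·trace; S* exactly singular (zero residuals) is an error.
- Percentiles use linear interpolation (numpy default).
- Balancing is listwise by country over a year range; no imputation. Logs
  are natural; non-positive values in a log variable raise an error naming
  the country/year/variable rather than being patched.
- Quarterly→annual conversion averages the available quarters (1–4), since
  uncertainty-index coverage is ragged for some countries.
- Grid runs derive per-run seeds as seed + 1009·run_index (mod 2³¹−1) for
  independent yet reproducible streams; one failed model is recorded in the
  manifest and does not stop the grid.
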