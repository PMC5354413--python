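# Methods

This note records the generative model, the testing strategies, the
default parameter choices and the numerical decisions behind
`interscreen`. Nothing here asserts an empirical result that is not
computed by the test suite or by `scripts/acceptance.py`.

## Generative model

A cohort of `n` individuals is drawn as

```
Y = γ0 + γG·G_std + γE·E0 + γGE·G_std·E0 + γZ·Z + ε
```

* `G` — genotype dosage, `Binomial(2, caf)` (Hardy–Weinberg), then
  standardized by its theoretical moments: `G_std = (G − 2p) / √(2p(1−p))`.
  Theoretical rather than sample moments keep coefficients comparable
  across replicates and make monomorphic draws detectable rather than
  silently rescaled.
* `E0`, `Z` — standardized exposures, normal or right-skewed. A nonzero
  `mean_e` only shifts the exposure that is *recorded* in the cohort; the
  outcome is always assembled from the centered component, so variance
  fractions are unaffected by the exposure's location.
* `ε` — residual noise, normal or right-skewed.
* Right-skewed variables are skew-normal with slant 5 (skewness ≈ 0.851),
  constructed as `δ|Z0| + √(1−δ²)·Z1` with `δ = 5/√26` and standardized
  analytically by the closed-form mean `δ√(2/π)` and variance
  `1 − 2δ²/π`, so their first two moments are exact, not estimated.

Coefficients are parameterized by variance fractions `τ`: with
standardized predictors, `γX = √τX` makes `τX` the share of `var(Y)`
explained by that term, the shares add (the terms are uncorrelated under
this design), and `var(ε)` is scaled to `1 − Στ` so that `var(Y) = 1`.
Configurations with `Στ ≥ 1` are rejected.

## Interaction tests

All strategies test the `G×Z` coefficient with a Wald statistic referred
to χ²₁ (a t-reference is available behind a flag). OLS is computed by a
reduced QR decomposition; rank deficiency raises an error naming the
offending columns via a pivoted QR. P-values are floored at 1e-300 so
that downstream −log10 and χ² transforms stay finite.

* `std` — naive covariance `σ̂²(XᵀX)⁻¹`.
* `hc0` — White sandwich, meat `Σ xᵢxᵢᵀ δᵢ²`.
* `hc3` — jackknife-style sandwich, meat `Σ xᵢxᵢᵀ δᵢ²/(1−hᵢᵢ)²` with hat
  diagonals `hᵢᵢ`; a leverage-1 observation makes HC3 undefined and is
  reported as an error rather than clipped.
* `bin` — `Z` replaced by `1{Z ≥ median(Z)}` before the standard fit, so
  ties at the median all land in the upper group.
* `sat` — genotype saturated as dummies `G1`, `G2` plus `Z` and `Z²`
  main effects; the ordinal `G·Z` term is tested. Dummy columns for
  absent genotype classes are dropped and reported.
* `rkt` — optional rank-based inverse-normal transform of the outcome
  before any strategy: `Φ⁻¹((r − 0.5)/n)` with ties averaged (a Blom
  offset `(r − 3/8)/(n + 1/4)` is available). The half offset makes the
  transformed values exactly symmetric about zero.

Batched simulation paths fit all replicates at once via `einsum`-based
normal equations, chunked to bound memory (~2 M scalar rows per chunk);
the scalar QR path and the batched path are cross-checked in the tests,
and the sandwich estimators are additionally verified against both a
brute-force definition oracle and an independent library implementation.

## Evaluation metrics

* Type I error — fraction of p-values at or below `α`.
* λ_GC — median of the χ²₁-transformed p-values divided by the null
  median 0.454936…; 1 under calibration.
* QQ data — observed vs expected −log10 p at plotting positions
  `(i − 0.5)/N`, with a pointwise beta-distribution envelope.
* Variance heterogeneity — within-genotype-class variances of the fitted
  residual δ and the generative residual ε; their difference has the
  closed form `(γE + γGE·g_std)²` when the interaction partner is
  unmeasured, which the tests verify at n = 10⁶.

## Default parameter choices

These problem sizes are the package's own defaults, chosen so every
pipeline runs in minutes on one CPU while leaving Monte Carlo error well
below the effect sizes being measured:

* Inflation sweep: n = 400, CAF 0.1, 10,000 replicates per τ point
  (binomial SE at the 5 % level ≈ 0.002).
* Robustness grid: n ∈ {100, 500, 1000, 5000} × CAF ∈ {0.05, 0.3, 0.5} ×
  residual/exposure distribution ∈ {normal, right-skewed} × main-effect
  regime ∈ {both, E only, Z only, neither} — 96 cells, with `γG, γGE ~
  U(0,1)` always present and the total explained variance drawn
  `U(0, 0.8)` per replicate (`var(ε) = S·(1/R² − 1)`; an alternative
  unit-variance residual rule is available). Each cell draws its RNG from
  a `SeedSequence` spawn key, so cells are reproducible in any order.
* The aggregate robustness condition (`run_robustness`) mixes the regime
  axes randomly per replicate at one (n, CAF) pair: `γE` always active,
  `γZ` active in half the replicates, distributions random.
* Screening: cis window 250 kb, BH q ≤ 0.01, top SNP per probe; TF
  marginal p < 0.05; 10 Mb SNP–TF exclusion (other chromosomes always
  eligible); interaction significance p < 1e-8; stratified λ over
  TF-marginal-p bins with strata under 100 tests flagged unreliable.
* Synthetic screening datasets place probes and SNPs uniformly on 22
  chromosomes of 100 Mb; planted cis effects get a co-located SNP within
  100 kb; per-SNP CAF ~ U(0.05, 0.5). Planted variance fractions that
  would exceed 90 % of `var(Y)` on one target are proportionally
  renormalized and the realized values recorded in the dataset's truth
  ledger.

## Null selection expectation

For `m` null single-predictor tests at `n` samples with `k` discoveries
declared at Benjamini–Hochberg level `q`, the per-test p threshold is
reconstructed as `q·k/m`. The null r² is `Beta(1/2, (n−2)/2)`; the p
threshold maps to an r² threshold through `F = r²(n−2)/(1−r²)` with
`F(1, n−2)`, and the expected r² among selected tests is the mean of the
Beta distribution truncated above that threshold,
`(a/(a+b))·(1−I_t(a+1,b))/(1−I_t(a,b))` with regularized incomplete beta
`I`. A simulation route (drawing `m` Beta variates in chunks) is provided
and agrees with the analytic route in the tests. The practical point: at
biobank-like `m`, tests that survive selection under the global null
still carry a mean r² of roughly 0.14 at n = 121 — "significant" is not
"large" once selection is accounted for.

## Generator realism and limitations

* Genotypes are independent across SNPs — no linkage disequilibrium — so
  the cis-eQTL step's "top SNP per probe" choice is easier than on real
  data, and clumping/fine-mapping behavior is out of scope.
* Expression is generated per probe from the linear model above; no
  shared batch effects, count noise, or probe cross-hybridization.
* Exposures and TF levels are skew-normal at most; heavier-tailed or
  discrete exposures are not modeled (the rank transform strategy is the
  intended remedy and is tested only under these distributions).
* The saturated strategy protects against quadratic exposure effects and
  nonlinear genotype coding, but not against general model
  misspecification.
* HC3's calibration is demonstrated down to n = 100 cells in the grid;
  below that, small-sample behavior of sandwich estimators is not
  characterized here.
* All pipelines are single-threaded; the per-cell RNG substreams make
  external parallelization trivial but none is built in.

## Numerical choices

* OLS via reduced QR (scalar path) and batched normal equations with
  `np.linalg.solve` (simulation path); `xtx⁻¹` kept explicitly for the
  sandwich bread.
* P-values floored at 1e-300; λ_GC computed from the median, so the
  floor cannot bias it.
* Dosage standardization uses theoretical HWE moments and broadcasts
  over per-SNP allele frequencies.
* Reproducibility: every public entry point takes a seed; grid cells and
  screening replicates derive independent `SeedSequence` substreams, so
  results are identical regardless of execution order; results files are
  written with fixed float formats so repeated runs are byte-identical.
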