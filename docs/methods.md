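# Methods

## Model and assumptions

The package tests a family of null hypotheses through their p-values
`p_1 … p_L` alone. The only substantive assumption is that each p-value is
valid (stochastically no smaller than Uniform(0,1) under its null); no
model of the dependence between tests is required. The motivation comes
from model averaging: for likelihood-ratio tests with two degrees of
freedom the p-value is exactly the inverse maximized likelihood ratio, so
the weighted mean likelihood ratio `R̄ = Σ w_i R_i` — a classical analogue
of a model-averaged Bayes factor — equals the inverse of the weighted
harmonic mean p-value. The package maintains this identity exactly
(`mean_max_lr` vs `harmonic_mean_p`, property-tested to 1e-12 relative).

Because `1/p_i` is heavy-tailed with infinite mean under the null, the
ordinary CLT does not apply to `R̄`; the generalized CLT gives convergence
of `1/p°` to a Landau distribution — the maximally skewed α-stable law
with stability index 1 — with location `μ_L = log L + 0.874` (natural log)
and scale `σ = π/2`. The constant 0.874 is used as published; it is not
re-derived here.

## Tests and decision rules

- **Direct test**: reject subset R iff `p°R ≤ α·wR`. The boundary counts
  as rejection. Closure is algebraic: `1/p° ≥ wR/p°R`, so a rejected
  subset forces `p° ≤ α`. The test is slightly anticonservative (the
  simulation harness shows FWER ≈ 0.08 at L = 100, α = 0.05).
- **Asymptotically exact test** (default): reject iff the Landau tail
  probability of `1/p°R` (location `μ_L` from the *full* family size) is
  ≤ `α·wR`. This is implemented so that the two published formulations
  agree on every input: `exact_p ≤ α·wR` iff `p°R ≤ 1/q_{α·wR}` where
  `q_x` is the Landau upper-`x` quantile — i.e. the threshold is taken at
  level `α·wR`. The familiar table of adjusted-HMP critical values
  `α_|R|` is the `wR = 1` case, `threshold(L, α) = 1/q_α`.
- Subsets use the full-family location `log L + 0.874` for `exact_p`.
  With equal weights the subset's inverse HMP is the mean of |R| inverse
  p-values, whose finite-|R| location is smaller; using the family
  location shifts mass rightward and is therefore the conservative choice,
  and keeps one null law per analysis. Closure for the exact method is
  consequently approximate (it is exact for the direct method and asserted
  there); the headline result is always computed and reported alongside.
- α above 0.05 triggers a warning: the calibration argument behind both
  tests degrades at large α.
- p-values equal to 0 are rejected as input errors (the statistic and the
  model-probability ratio are undefined; a zero signals upstream
  underflow). p = 1 is allowed. Weights must be non-negative with a
  positive sum; unnormalized weights are renormalized with a warning;
  the default is equal weights.

## Landau numerics

All quantities derive from the integral representation
`f(x|μ,σ) = 1/(πσ) ∫₀^∞ exp(−t s − (2/π) t log t) sin(2t) dt`,
`s = (x−μ)/σ`. Integrating analytically over x gives the survival
function integrand `exp(−t s − (2/π) t log t) sin(2t)/t`.

- **Density.** For `s ≥ −2.4`: adaptive quadrature on each lobe between
  consecutive zeros of `sin(2t)` (`t = kπ/2`), summed until lobes are
  negligible; agreement with a 10×-resolution fixed-grid trapezoid oracle
  and with an independent stable-law implementation is ≤ 1e-7 relative.
  For `s < −2.4` the real-axis integral cancels catastrophically in double
  precision, and a steepest-descent asymptotic derived from the same
  integral is used: `f ≈ ½ √ρ e^{−(2/π)ρ} (1 + π/(48ρ))` with
  `ρ = e^{−πs/2 − 1}`. Relative accuracy there is ~2e-4 at the crossover
  (density < 8e-5) improving rapidly leftward; this region is far below
  any significance computation.
- **Survival function.** Lobe-split quadrature for `−3 < s ≤ 3`; for
  `s > 3` the substitution `u = t·s` renders the integrand smooth
  (the sine completes only a fraction of a period within the `e^{−u}`
  decay) and a single adaptive quadrature suffices out to `x = 10⁹`
  (verified ≤ ~1e-5 relative against the independent implementation);
  for `s ≤ −3`, `sf = 1 − e^{−(2/π)ρ}/(2√ρ)` (the doubly-exponentially
  small left-tail mass).
- **Quantiles.** Brent root-finding on `sf`, bracketed by the index-1
  tail expansion `sf(x) ≈ (2σ/π)/(x−μ)`, with the bracket widened
  geometrically on failure. Round-trip accuracy `sf(isf(q)) = q` is
  ~1e-7 relative or better over `q ∈ [1e-6, 0.5]`.
- **Thresholds.** `threshold(L, α) = 1/isf(α)` for the L-test null,
  cached per `(L, α)`. Reproduces the published 27-cell table at its
  2-significant-figure precision; monotone decreasing in L, increasing
  in α, and always below α.

`scipy.stats.landau` (whose `loc`/`scale` was verified to coincide exactly
with this (μ, σ) parameterization) is used in the test suite as an
independent cross-check only; the package's own quadrature of the defining
integral is the implementation everywhere.

## Simulation harness

- **Dependence model**: a single-factor equicorrelated Gaussian copula,
  `z_i = √ρ·z₀ + √(1−ρ)·e_i`, one-sided `p_i = Φ(−z_i)`. ρ is the
  equicorrelation of the latent statistics; ρ = 0 gives iid uniform
  p-values. This is one explicit, parameterized stand-in for "positive
  dependence"; real dependence structures (e.g. linkage disequilibrium
  blocks) are block-wise and non-exchangeable, so passing tests here show
  robustness to equicorrelation specifically, not to every dependence
  shape.
- **Alternatives**: mean shifts of the latent z-scores (`effect`, in SD
  units) on the first `n_signals` tests. Effect sizes are scenario
  parameters, not estimates of any particular study.
- **Likelihood-ratio draws**: `R = 1/U`, U uniform — the exact null law
  of a 2-df maximized likelihood ratio, with `p = 1/R`.
- **Familywise rejection**: for combined tests (HMP variants, Fisher),
  rejection of the headline null over all L tests; for per-test
  procedures (Bonferroni, BH), any individual rejection.
- **Defaults**: reps = 10⁴ (binomial SE ≈ 0.002 at α = 0.05), seed
  mandatory; summaries are bit-reproducible given the scenario. All
  stochastic test assertions are stated as multiples of the binomial or
  empirical-quantile standard error, never as bare constants.
- The exact test's vectorized decision uses the threshold formulation
  (`p° ≤ threshold(L, α)`), which is identical to evaluating the Landau
  tail per replicate at `wR = 1`.

Observed behavior at the default scales: empirical FWER of the exact test
0.050 ± 0.002 at L = 100, ρ = 0; under strong equicorrelation (ρ = 0.5)
it stays within ~0.007 of nominal, slightly above — consistent with the
test being exact only up to the Landau approximation; the direct test runs
at ≈ 0.08, its documented anticonservatism.

### Convergence to the Landau limit

The equal-weight mean of L inverse-uniform draws approaches
Landau(`log L + 0.874`, `π/2`) as L grows. At L = 10³ with 10⁵
replicates, the central quantiles (0.15–0.95) agree within Monte-Carlo
error, but the extreme left quantiles (0.05–0.10) carry a reproducible
finite-L bias of ≈ 0.5% in x (≈ 0.004 in CDF units) — about 3–6
Monte-Carlo standard errors at that replicate count. The bias shrinks
roughly like 1/L (visibly: z ≈ +25 at L = 10², +3–6 at 10³, +1–3.5 at
10⁴) and is immaterial for significance testing, which depends on the
*upper* tail where the calibration error is a fraction of a percent (the
calibration checks show `sf(1/p°)/p°` within 0.03% of 1 by p° = 10⁻⁵).
The corresponding distribution-matching test asserts the pre-registered
Monte-Carlo band and documents this left-edge deviation rather than hiding
it.

## Window scanning

- Coordinates are half-open `[start, end)`, 0-based internally, 1-based
  in I/O. Variants must be position-sorted within each chromosome
  (validated; the offending row is named).
- Default sizes 10 kb, 100 kb, 1 Mb, 10 Mb with half-overlapping steps
  (`step = size/2`), configurable to non-overlapping; chromosome- and
  genome-level results are always emitted. Edge windows are truncated to
  the observed chromosome bounds; empty windows are skipped, not
  zero-filled. Multi-allelic variants (identical positions) share windows.
- Under equal weights `wR = |R|/L`, so each level automatically faces its
  proportionate threshold `α·wR`. Significance is also reported as
  `−log₁₀(adjusted p)` for Manhattan-style display, and regions can be
  exported as BED (score = that quantity).
- Missing p-values in input tables are dropped with a warning, never
  imputed.

## Fixture generators

`make_fixture` writes TSV families with coordinates: `null` (iid uniform),
`spiked` (planted p-values at named positions), and `correlated-blocks`
(equicorrelated latent blocks, emulating locally dependent tests). These
emulate the *calibration* structure of association-scan summary statistics
— valid marginal p-values with optional local positive dependence — not
their genomic realism: no allele frequencies, no linkage maps, no effect
heterogeneity. Tests passing on these fixtures demonstrate the combining
machinery, not end-to-end GWAS validity.

## Problem sizes

Deterministic checks (threshold table, calibration, identities) run in
seconds. Monte-Carlo checks use 10⁴ families for FWER/closure/identity
sweeps and 10⁵ replicates for the convergence study at L = 10³ — sizes at
which the binomial standard errors (≈ 0.002 on a 5% rate) are small enough
to make the calibration claims meaningful on a single CPU.

## Known limitations

- The Landau location constant 0.874 and the ν = 2 (two-degree-of-freedom)
  parameterization are the only ones supported; other degrees of freedom
  change the stable-law constants and are out of scope.
- Comparator methods (Bonferroni, Simes, BH, Fisher) are unweighted;
  weighted variants are not provided.
- The far left Landau tail (standardized s < −2.4) is served by an
  asymptotic with ~1e-4 relative error — irrelevant for p-value
  computation but not suitable for, e.g., left-tail moments.
- The exact test's strong-FWER control is asymptotic in L and approximate
  under dependence; at very small L (≲ 10) and large α it can be
  slightly anticonservative, which is why α > 0.05 warns.
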