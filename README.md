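# harmonicp

Combine large numbers of dependent p-values with the **harmonic mean
p-value (HMP)** while controlling the strong-sense familywise error rate
(FWER).

## The problem

Big exploratory analyses — genome-wide association scans, tests of
higher-order interactions, any model-selection exercise where many
alternatives are compared against one null — produce thousands to billions
of p-values that are often strongly positively dependent. Bonferroni
correction controls the FWER but penalizes every additional test linearly,
and its conservatism grows with the dependence. The HMP offers a different
trade: combine the evidence across any group of tests, reward groups of
comparably small p-values, and keep strong FWER control no matter how many
(possibly overlapping) groups are examined.

## The statistic

For p-values `p_1 … p_L` with weights `w_1 … w_L` (`Σ w_i = 1`), the
weighted HMP of a subset `R` is

```
p°R = ( Σ_{i∈R} w_i ) / ( Σ_{i∈R} w_i / p_i )
```

Two tests of the null restricted to `R`, both at FWER level α:

- **direct**: reject when `p°R ≤ α·wR`, with `wR = Σ_{i∈R} w_i` — simple,
  valid because the HMP is asymptotically well calibrated when small, but
  very slightly anticonservative;
- **asymptotically exact** (default): the inverse HMP converges under the
  null, by the generalized central limit theorem for heavy-tailed summands,
  to a Landau distribution (the maximally skewed stable law with tail
  index 1) with location `log L + 0.874` and scale `π/2`. Reject when the
  Landau tail probability of `1/p°R` is ≤ `α·wR`, equivalently when the
  adjusted HMP `p°R / wR` falls at or below the inverted-threshold
  `α_|R|` (e.g. 0.040 for 10 tests at α = 0.05, 0.027 for 10⁶ tests).

Rejection of any subset implies the whole-family ("headline") HMP is itself
significant — a closed testing procedure — so subsets need no further
correction. Conditional on rejection, the evidence splits over the members
of `R` as approximate model probabilities `q_i ∝ w_i / p_i`.

## Worked example

A hundred tests, none individually significant after Bonferroni correction,
containing a cluster of four modest signals:

```python
import numpy as np
from harmonicp import HarmonicMeanP, Subset

rng = np.random.default_rng(7)
p = rng.uniform(size=100)               # a hundred null tests...
p[10:14] = [2e-3, 8e-4, 3e-3, 1.5e-3]   # ...plus a cluster of modest signals
cluster = Subset(indices=tuple(range(10, 14)), label="cluster")
res = HarmonicMeanP(p).fit(alpha=0.05, subsets=[cluster])
print(res.summary())
```

```
Harmonic mean p-value results
================================================================
Tests (L):            100
Method:               exact
FWER level alpha:     0.05
Headline HMP:         0.0270579
Asymptotically exact p: 0.0344003
Adjusted-HMP threshold alpha_|R|: 0.03639
Headline significant: True
----------------------------------------------------------------
  label   n   wR      hmp  adjusted  exact_p  significant
    ALL 100 1.00 0.027058  0.027058 0.034400         True
cluster   4 0.04 0.001455  0.036364 0.001478         True
```

The headline exact p-value (0.034) and the cluster (exact p 0.0015 against
its threshold `α·wR = 0.002`) are both significant, while the Bonferroni
combined statistic `L·min p = 0.08` is not
(`res.comparators()["bonferroni"]`). The evidence within the cluster splits
as `res.model_posteriors(cluster)` → `[0.182, 0.455, 0.121, 0.242]`: the
smallest p-value carries just under half the posterior weight.

## Command line

The `hmp` script exposes the same functionality on TSV tables
(columns `p`, and optionally `id`, `w`, `chrom`, `pos`):

```sh
hmp threshold -L 1000000 --alpha 0.05    # adjusted-HMP and Bonferroni cutoffs
hmp combine pvalues.tsv                  # whole-family combined test
hmp scan pvalues.tsv --out regions.tsv --bed regions.bed   # windowed GWAS-style scan
hmp simulate -L 100 --reps 10000 --seed 1                  # FWER/power comparison
hmp fixture spiked --out fx.tsv --spike chr1:5000:1e-9 --seed 7
```

`scan` combines per-variant p-values over sliding windows (default 10 kb /
100 kb / 1 Mb / 10 Mb, half-overlapping), per-chromosome and genome-wide,
reporting each region's adjusted HMP and significance at its own threshold
`α·wR`.

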