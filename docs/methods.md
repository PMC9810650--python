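# Methods

## The fidelity problem and the metric

An immunoassay comparison of analyte expression between two sample groups
produces a differential signal that is contaminated by assay-associated
noise: cross-reactivity, pre-analytical variability, operator effects.
Whether a measured group difference is *valid* — distinguishable from that
noise — is logically prior to any significance test on it.

Both the signal and the noise are observable. With groups `X` and `Y` and a
repeat measurement on a second aliquot of every sample (`X′`, `Y′`):

* per-sample noise: `N_X = |X − X′|`, `N_Y = |Y − Y′|`, combined as the
  worst case `N = max(N_X, N_Y)`;
* paired differential expression: `Z = |X − Y|` (equivalently
  `max(X, Y) − min(X, Y)`, the lattice form, which makes the pairing
  assumption explicit);
* unpaired differential expression: `Z = X − Y` at the summary level, so
  `μ_Z = |μ_X − μ_Y|` and `σ_Z = √(σ_X² + σ_Y²)`.

A general relative-change function `f(a, b) = log10(a/b)` compares any
effect-size measure of Z against the same measure of N: zero iff they are
equal, positive iff the signal's exceeds the noise's, monotone, and
additive over measures. Applying it to the first two moments and summing
gives the metric:

```
rxCOV(Z, N) = log10(μ_Z/μ_N) + log10(σ_Z/σ_N) = log10( (σ_Z/μ_N) / (σ_N/μ_Z) )
```

Properties relied on throughout (each property-tested):

* **Additivity** — the value is exactly the sum of the mean term and the
  dispersion term.
* **Scale invariance** — multiplying all four statistics (equivalently all
  raw measurements) by any α > 0 leaves the value unchanged; the verdict
  does not depend on units. (The log-ratio is invariant, not homogeneous,
  under joint scaling.)
* **Sign semantics** — `rxCOV > 0 ⇔ σ_Z/μ_N > σ_N/μ_Z`; zero is classified
  *low* fidelity: at the balance point signal and noise cannot be told
  apart.
* **Smoothness** — the partial derivative with respect to each variable `x`
  is the hyperbola `±1/(x ln 10)` on `(0, ∞)`, so the metric responds
  continuously to small changes in any statistic; verified by central
  finite differences at random interior points.

## Estimators and degeneracy policy

`moment` estimation uses the arithmetic mean and the sample standard
deviation with the n−1 denominator (small assay groups; the common default
of general statistical environments). `robust` substitutes the median and
the interquartile range (Q3 − Q1, linear interpolation between order
statistics — the most widespread quantile convention, fixed here for
reproducibility); for unpaired data the robust dispersions are combined in
quadrature by analogy with the moment formula, an extension flagged as such.

All four statistics must be strictly positive — the logs are otherwise
undefined. Degenerate inputs raise an error naming the offending statistic;
there is no epsilon floor, because silently perturbing a fidelity metric
defeats its purpose. In batch (per-analyte) mode, degeneracy becomes a
status on that analyte's row and the rest of the panel proceeds. A fully
noise-free analyte (every repeat aliquot identical, `μ_N = 0`) is reported
with status `noise_free` and a trivially high verdict rather than a number.
Exact zeros in the data are legal (ratio scale); missing values are dropped
with a logged count, never imputed.

## The per-analyte batch workflow

Input is a tidy table, one row per (sample, analyte, aliquot[, replicate]).
The aliquot-1 value is the primary expression measurement and feeds Z;
aliquot 2 serves only to reveal noise via `|a1 − a2|`. When a replicate
column is present, replicates are averaged per (sample, aliquot) before
analysis. Optional division by a tissue-weight column removes specimen-size
variation.

Noise combination across groups defaults to `elementwise_max` for paired
(sample-aligned) designs and `cross_product_max` — exact enumeration of
`max(N_X[i], N_Y[j])` over all pairs, the faithful realization of the max
of independent noise variables — for unpaired designs with unequal group
sizes. Both modes, plus `single_group`, are selectable; the enumerated
multiset is summarized with the same estimator as everything else so that
results are bit-reproducible.

## Simulation framework

The noise-injection model observes `d = s + γ·n`: clean per-sample signals
`s` drawn once per scenario, base noise `n` drawn i.i.d. per measurement,
and a scale factor γ sweeping noise severity. Each measurement is simulated
twice with independent noise (the two aliquots), so the realized per-sample
noise is `γ·|n − n′|`; with zero-mean normal base noise of scale σ_n this
is half-normal with mean `2γσ_n/√π` and standard deviation
`γσ_n·√(2 − 4/π)`, which the tests verify by Monte Carlo. Observations are
clipped at zero (ratio-scale data) with clip events logged; heavy clipping
signals an ill-posed scenario, and at extreme γ it shapes the limiting
value of the metric (the tail constant is computed by a brute-force Monte
Carlo oracle on the clipped limit law in the tests).

The **canonical scenario** used as the package default and test condition:
12 samples per group, signals `s_X ~ Normal(10, 2)` and
`s_Y ~ Normal(12.5, 2)` (a clean difference that is statistically
significant at typical group sizes), base noise `Normal(0, 1)` (scenario 1)
or `Normal(0.2, 1.1)` (scenario 2, a slightly biased and wider assay). The
underlying real experiment these emulate was not published, so these are
package choices: plausible cytokine-like magnitudes with an effect around
1.25 group standard deviations. What the generator does *not* emulate:
skewed/lognormal biological heterogeneity (available via the lognormal
family but not default), heteroscedastic or expression-dependent assay
noise, plate/batch effects, and detection limits other than the zero clip —
so passing tests demonstrate correctness of the machinery, not performance
on any particular real assay.

A **γ-scan** reuses the same clean signals across the grid (only noise
varies), records rxCOV and a two-group p-value (Welch's t by default;
Student's t and Mann-Whitney selectable) per γ, and locates two thresholds
by linear interpolation between grid points:

* **γ\*** — first downward zero crossing of the rxCOV track: the
  experiment-specific noise level beyond which the analyte loses fidelity.
  Later re-crossings (possible under Monte-Carlo jitter) are reported as
  warnings. γ = 0 is excluded from grids: with no noise the denominators
  vanish and the metric diverges.
* **γ_sig** — first upward crossing of the p-value track through α.

Beyond γ\*, a significant p-value is *spurious*: the scan flags every grid
point past γ\* whose p-value still claims significance. The flag is driven
by γ\* rather than by the pointwise metric value, which is what "regardless
of the p-value" means operationally.

Tracks can be smoothed by averaging k independent noise realizations per γ
(`k_smooth`, default 1, recorded in outputs); the scan-based analyses in
the tests use 2,000 samples per group with k = 8, sizes chosen to pin the
crossing within a few percent while keeping a full run in seconds. A
`fixed` noise mode scales a single base realization across the grid instead
of redrawing, giving a deterministic smooth track; whether a real scan
should redraw per γ is a modeling choice, and redraw is the default.

**Replication.** Averaging R independent replicates shrinks the effective
noise standard deviation by 1/√R while leaving the signal untouched, so γ\*
scales approximately with √R — verified at R ∈ {1, 4} with a ratio tolerance
of 25% to absorb crossing-estimation noise. On real tables with replicate
columns, `replicate_sufficiency` averages replicates 1..R cumulatively and
returns the smallest R with rxCOV > 0, or an explicit "insufficient at max
R" verdict.

## Numerical and design choices

* Seed discipline: a scenario seed spawns independent child streams for
  signals and noise, so identical configurations are bit-reproducible and
  consuming more noise (more replicates, more γ points) never perturbs the
  signal draw.
* Crossing detection: first sign change with linear interpolation; an exact
  zero on a grid point returns that point.
* Output floats are serialized at 6 significant digits; determinism
  contracts are byte-level on CSVs (manifest timestamps excluded).
* CLI errors are structured messages, never tracebacks; per-analyte skip
  reasons are logged at warning level.

## Known limitations

* The half-normal closed forms hold for zero-mean normal base noise only;
  other noise families are simulated, not given closed forms.
* The unpaired robust dispersion combination (IQRs in quadrature) is an
  analogy, not a derived identity.
* Clipping at zero biases scenarios whose signal scale is comparable to the
  noise scale; clip counts are logged so such scenarios can be detected.
* The ΔrxCOV sensitivity surface bounds (minimum −0.301, maximum
  log10(1.5) ≈ 0.176 over deviations up to 50%) describe summary-level
  sensitivity to the paired-vs-unpaired assumption; the pairing itself is a
  property of the study design, not a free choice.
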