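# Methods

## Data-generating model

Every simulated group is skew-normal, SN(ξ, ω, α), with density
2/ω · φ((y−ξ)/ω) · Φ(α(y−ξ)/ω); α = 0 recovers the normal and the family's
mean and SD are

    μ = ξ + ωγ√(2/π),   σ = ω√(1 − 2γ²/π),   γ = α/√(1+α²).

A scenario prescribes population *moments* (mean difference δ, SD σ, slant α
for group 2; group 1 fixed at N(0,1)), and the generator solves the moment
equations for (ξ, ω). This is what makes the factorial design clean: changing
α changes only the shape, never the mean or SD, of group 2. The inversion is
exact (roundtrip residual < 1e-10 over the whole design region) because
1 − 2γ²/π > 1 − 2/π for every finite α.

Sampling uses the stochastic representation Z = γ|U| + √(1−γ²)V with U, V iid
standard normal, then Y = ξ + ωZ — exact, rejection-free, O(n). γ is computed
once per spec and cached. The density itself is delegated to
`scipy.stats.skewnorm`; the test suite checks it pointwise against a direct
evaluation of the erf formula, and the sampler against `skewnorm.cdf` by
Kolmogorov–Smirnov.

## Estimators

* **Cohen's d** uses unbiased sample variances and the df-weighted pooled SD;
  direction is group 1 minus group 2, so d is negative when group 2's mean is
  higher. No small-sample (Hedges) correction is applied — the estimator under
  study is d itself.
* **CLES** has two estimators. The ordered-pairs form counts strict
  inequalities over all n1·n2 pairs and excludes ties from both counts (no
  half credit); it is computed by sorting + binary search, O(n log n), and is
  tested against a brute-force double loop. The transform form Φ(|d|/√2) is
  folded (≥ 0.5 always). The simulation records the transform form by default
  because the CLES interval is built by transforming d's interval, and a point
  estimate should be coherent with its own interval; `cles_estimator =
  "empirical"` switches to the ordered-pairs form.
* **Parametric overlap** is the deterministic map η_p = 2Φ(−|d|/2).
* **Nonparametric overlap** integrates the pointwise minimum of two Gaussian
  KDEs on one shared grid. Defaults mirror R's `density()`: bandwidth
  0.9·min(sd, IQR/1.34)·n^(−1/5) per group, 1024 grid points spanning the
  pooled sample range extended by 3 × the larger bandwidth, trapezoid
  integration, each density renormalized to unit mass on the grid first
  (truncation would otherwise leak mass and bias η downward). All four knobs
  sit in `KdeConfig`. Each KDE is evaluated by linear binning onto the grid
  followed by FFT convolution with the kernel (also `density()`'s scheme),
  which is O(n + G log G) rather than O(nG); a retained direct-summation
  evaluator bounds the binning error below 1e-4 in the test suite.

## Population targets

Each index is judged against its own estimand:

* θ_d = −δ/√((1+σ²)/2) — the population value of the pooled-SD standardizer at
  equal n (exact for every α thanks to moment matching).
* θ_CLES = max(p, 1−p) with p = P(Y2 > Y1) = ∫Φ(y)f2(y)dy by adaptive
  quadrature; folded to match the folded estimator. A config switch
  (`theta_cles_rule = "transform_of_theta_d"`) instead uses Φ(|θ_d|/√2), the
  value the transform estimator targets under normality; the two differ under
  skewness or heteroscedasticity and both are defensible targets, so both are
  implemented and the choice is explicit.
* θ_overlap = ∫min(φ, f2) — shared by η_p *and* η. Judging η_p against the
  true overlap (rather than against a transform of θ_d) is the reading under
  which η_p is unbiased for equal variances but biased under a 5:1 SD ratio,
  which is precisely the behaviour of interest; against its own transform it
  would be trivially consistent and the comparison vacuous.

The overlap integrand has kinks where the densities cross, so the crossings
are bracketed on a 4001-point scan, refined with Brent's method, and
`scipy.integrate.quad` runs piecewise between them (abs. tolerance 1e-10 per
piece; each piece is smooth).
Closed normal-theory forms (2Φ(−|δ|/2) at σ=1; the crossing-point construction
at σ≠1) and 10⁶-draw Monte-Carlo estimates validate the quadrature to 1e-6.

## Confidence intervals

* **d** — noncentral-t inversion: with t = d̂√(n1n2/(n1+n2)) and df = n1+n2−2,
  the bounds are the noncentrality parameters at which the noncentral-t CDF at
  t equals (1±level)/2, scaled back by √((n1+n2)/(n1n2)). Root finding is
  Brent's method on a geometrically expanding bracket seeded at four
  normal-approximation SDs of the ncp, which stays robust at n=1000, |d|≈2;
  xtol 1e-10 keeps the inversion identity good to 1e-6 in tail probability.
* **CLES / η_p** — the respective transform evaluated at both d-bounds, sorted.
  Both transforms fold at |d| = 0, so when d's interval straddles zero the
  literal endpoint rule yields intervals that cannot reach CLES = 0.5 from
  both sides nor η_p = 1 at all; this deliberately reproduces the (poor) null
  behaviour of the transformed intervals. A `widen_null` switch optionally
  sets the η_p upper bound to 1 whenever 0 ∈ CI(d), as the monotone-map-of-a-
  folded-parameter correction; the default is the literal rule.
* **η** — percentile bootstrap: both groups resampled independently with
  replacement, η recomputed, the (1±level)/2 empirical quantiles taken with
  linear interpolation (numpy's default), making intervals bit-reproducible
  given the seed. 1000 draws by default (reducible for desk runs); a
  zero-spread resample is redrawn, capped at 100 attempts.

## Engine and seeding

The full design is 8 contrasts × 6 sizes × 2000 replicates. Every replicate's
generator derives from `SeedSequence(master_seed, spawn_key=(w(δ,σ,α), n, rep,
attempt))`, where `w` encodes the *values* of the cell's parameters as uint32
words — so results are bit-identical across reruns and invariant to the order
conditions are visited in. Group 1 is drawn fresh each replicate. The eta
bootstrap uses a spawned child of the replicate sequence. A degenerate
replicate (zero pooled SD or zero bandwidth, possible only at tiny n) is
redrawn under the next attempt key, keeping the replicate count constant; the
run aborts if more than 1% of a condition's replicates needed redrawing.
Intervals and the bootstrap can be switched off (`compute_intervals`, `boot =
None`) for correlation- or bias-only studies, which is how the desk-scale
summaries keep to minutes on one CPU.

## Performance metrics

RMB = mean((θ̂_b − θ)/θ); when θ = 0 exactly, ε = 10⁻⁶ replaces it, which is
numerically stable but explosive by design — a replicate mean of 0.001 reports
an RMB of 1000. The summary therefore carries a companion `raw_bias` column
(mean(θ̂) − θ) so δ=0 cells remain interpretable; the literal ε values are
reported, not suppressed. NRMSE = RMSE/(max − min) of the B estimates; a
zero-range column reports 0 when RMSE = 0 and missing otherwise. Coverage uses
closed endpoints. Correlations pool replicate-level estimates across all
conditions; both signed and magnitude (`absolute=True`) versions are exposed,
the magnitude version being the meaningful one since d's sign convention makes
it negative exactly where its folded transforms rise.

## Desk-scale defaults and what the tests show

The test suite and the reproduction script run the grid at 200 replicates per
condition (correlations, bias) and a single cell at 2000 replicates
(coverage) — sizes chosen so the whole suite runs in minutes on one CPU while
keeping Monte-Carlo error visible and quantified in each assertion. Two
properties of that scale are worth knowing:

* The pooled correlation split (d-family > 0.90, η moderate at ≈ 0.46–0.48) is
  extremely stable across seeds at 200 replicates.
* The bias band of d is *not* comfortably inside ±0.10 at 200 replicates: the
  true RMB of d̂ at (δ=2, σ=5, n=10) is ≈ 0.086 — roughly double the
  normal-theory small-sample value 3/(4df−1) ≈ 0.044, because with a 5:1 SD
  ratio the pooled variance is no longer a scaled chi-square and 1/s_p picks
  up extra upward bias — and the per-cell Monte-Carlo SE of RMB there is
  ≈ 0.04, so the max over the 24 δ=2 cells fluctuates around 0.09–0.13
  depending on the seed. At the full 2000 replicates the band holds.

## What the generator does and does not emulate

It emulates controlled violations of normality (one-sided slant up to α=10,
skewness ≈ 0.95) and variance homogeneity (SD ratio 5:1) with exactly matched
means/SDs, at equal group sizes. It does not emulate heavy tails beyond the
skew-normal's (kurtosis ≈ 0.8 excess at most), contamination/outliers,
discreteness or bounded scales, unequal group sizes, or dependence between
groups — so passing tests say nothing about, e.g., Likert floors or paired
designs. The kernel overlap's known structural bias — two finite samples from
identical populations never overlap perfectly, so η̂ < 1 and its bootstrap
interval undercovers at the fully-null cell — is a property of the estimator,
not an artifact, and the suite asserts its direction rather than hiding it.

## Known limitations

* The nonparametric overlap inherits KDE boundary and smoothing bias; at n=10
  it is visibly biased toward more overlap for well-separated groups.
* The ε rule makes RMB at θ=0 cells a presentation problem, not an estimation
  one; use `raw_bias` there.
* Only two-group designs; no Hedges/Glass variants; no BCa bootstrap.
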