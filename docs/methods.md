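# Methods

This note documents the statistical model behind `phenodrought`, the
choices made where the procedure was genuinely open, and what the
synthetic experiments do and do not establish.

## Data model and preprocessing

The unit of raw data is one per-plant measurement of one image-derived
trait on one imaging day, labelled by genotype, treatment (control /
drought), carrier (the tray of pots — the biological replicate) and
plant. Missing observations are absent rows; every downstream mean and
correlation is pairwise-complete. Day indices are 1-based and
contiguous; if a calendar day is skipped during imaging the series is
still analysed as consecutive time points, and any mapping to days after
sowing is metadata only.

**Grubbs outlier removal.** The two-sided Grubbs statistic
`G = max|x_i − x̄|/s` is compared against
`((n−1)/√n)·√(t²/(n−2+t²))`, `t` the upper `α/(2n)` quantile of
Student's t on `n−2` df, removing the extreme value and iterating.
Open choices, resolved here: the grouping cell is
(genotype, treatment, day, trait) pooling the plants of both carriers —
the smallest homogeneous cell with workable `n` (≤ 8 in the default
design); `α = 0.05`; at most 2 removals per cell. Samples with `n < 3`
or zero variance pass through untouched, so the procedure is total and
idempotent once nothing is flagged. At `α = 0.05` roughly 5% of clean
cells lose one value to a false flag; this is inherent to the test, not
a defect, and is harmless after carrier averaging.

**Repeatability filter.** Per trait and condition, the two carriers'
values are paired over all (genotype, day) cells and a single pooled
Pearson correlation is computed; a trait is accepted iff both
per-condition correlations are defined and strictly exceed 0.2. The
pooled-per-condition reading was chosen over per-genotype correlations
(both are implemented; `per_genotype=True` averages per-genotype
coefficients) because acceptance is a per-trait decision and pooling
uses all cells at once. Traits with no observations are reported as
empty rather than silently dropped, so the bookkeeping
`total = empty + rejected + accepted` always closes.

## The per-day bivariate mixed model

For one trait and day, carrier means follow

    y_gtc = μ_t + β x_g + u_gt + ε_gtc,
    (u_gC, u_gD) ~ N(0, G),   ε_gtc ~ N(0, σ²_e,t),

with `G` an unstructured symmetric 2×2 matrix and the covariate term
(`β x_g`, e.g. a phenology score) optional. Estimation is REML on the
5-parameter profile likelihood; fixed effects are solved by GLS at each
parameter value. Numerical choices:

* **Sign-unconstrained G diagonal.** The genotype variances are not
  forced non-negative. Negative REML estimates are meaningful (they
  arise whenever the between-genotype scatter falls below its residual
  expectation) and the genetic correlation is reported as undefined in
  that case rather than forced to a boundary.
* **Heterogeneous residuals** by treatment (default). Drought changes
  measurement scatter for most image traits, and the restriction costs
  nothing; `pooled_residual=True` ties them for the classical variant.
* **Optimizer.** L-BFGS-B with an analytic REML gradient, started at the
  closed-form ANOVA moment estimates (between-genotype covariance of
  condition-wise genotype means minus residual/carriers; residual from
  within-cell mean squares). On balanced data the moment start already
  satisfies the REML stationarity condition exactly, which the gradient
  check confirms before any optimization step; unbalanced slices (e.g. a
  carrier losing all plants to outlier removal) take the full
  quasi-Newton path. Convergence: relative objective change below
  1e−10, at most 200 iterations. Non-positive-definite V during a step
  returns a penalty value.
* **Standard errors** from the observed information (numerical Hessian
  of −2·restricted log-likelihood), computed lazily.
* **Wald test.** `W = (μ̂_D − μ̂_C)² / Var(μ̂_D − μ̂_C)` with the variance
  from the GLS covariance at the REML solution, referred to χ²(1). With
  ~100 genotypes the χ² reference is adequate (empirical type-I error
  0.05 ± 0.01 in the calibration suite); no denominator-df approximation
  is attempted.
* `r_g = g_CD/√(g_CC·g_DD)` is truncated into [−1, 1] with a flag when
  the unconstrained estimates push it outside; `log2FC = log2(g_DD/g_CC)`
  is undefined unless both diagonals are positive.

Post-harvest traits are analysed by the same model with plants in the
replicate role.

## Relative drought effects

`RDE = 100·(m_D − m_C)/m_C` per genotype (means over carriers for
in-time traits, over plants for post-harvest traits), undefined when
`|m_C|` falls below a floor (1e−8 in trait units) to avoid blow-up for
near-zero-background traits. Per-day mean profiles average defined
genotype RDEs. Significant-effect counting applies the Wald p-values at
`α/m` (Bonferroni over the `m` accepted traits, `α = 0.05`).

## Profile clustering

Lloyd k-means minimizing the within-group sum of squares, k-means++
seeding, best of 100 restarts, k = 1…10, deterministic given the seed.
Profiles are clustered **unscaled** — mean-RDE profiles share the
percent scale and correlation profiles live in [−1, 1]; a z-scaling
switch exists but is off. Missing entries (days where `r_g` is
undefined) are ignored in distance sums with each distance renormalized
by the count of available days, and centroids are available-day means.

**Choosing k.** The scree is summarized by the second difference of
`log WSS(k)`; the chosen k maximizes it over 2 ≤ k ≤ k_max−1. The log
scale is what makes the rule scale-free: a geometric, elbow-less decay
is exactly linear in log (flagged ambiguous, falling back to a
configured k), whereas the raw-scale second difference is dominated by
the first, largest drop and returns k = 2 on almost any multi-scale
cluster geometry. A curve reaching ~0 at some k means exactly that many
distinct profiles and short-circuits to it. The chosen k is always
overridable in the pipeline config, mirroring how scree plots are read
by eye in practice.

Joint classification crosses two labelings of the same trait set; the
number of combined clusters is the number of occupied cells, and merge
maps can collapse labels before crossing.

## Linkage, day counting, and the selection rule

Pearson correlation with the two-sided t test (`t = r√(n−2)/√(1−r²)`,
n−2 df) across genotypes, per day, between each image trait's RDE and
each post-harvest target's RDE. Days with `p < 0.001` are counted split
by the sign of r. For the spike complex (LSm, NSm, NGm, GWm) the
correlation profiles are additionally averaged over the four members for
clustering purposes (no significance is attached to an averaged r), and
the complex's day count for selection is the sum of the members' counts
— the members are strongly inter-correlated, so the sum rewards traits
consistently linked to the whole complex.

The selection rule: within each joint category, the trait(s) attaining
the category-maximal day count are selected iff that maximum strictly
exceeds the upper quartile (75th percentile, linear interpolation at
rank `1 + 0.75(n−1)`) of counts over all traits. Ties at the maximum are
all retained — determinism without an arbitrary tie-break. Per-target
selections and their intersection are reported.

PCA of a genotype × trait RDE matrix (SVD of the centered matrix, each
component's largest-magnitude loading oriented positive) reports the
genotypes with extreme first-component scores — the most contrasting
drought-response lines.

## PLS and PRESS

NIPALS PLS (scikit-learn's implementation behind the module surface)
with both blocks autoscaled using training-fold statistics; trait units
are heterogeneous, so autoscaling is the conventional default. Two-group
cross-validation: deterministic alternation over genotypes sorted by
identifier (a seeded random split is available); PRESS accumulates
held-out squared errors on the training-fold standardized-target scale,
making curves comparable across predictor sets. Default 2 components
(the biplots are two-dimensional); a training fold too small for the
requested components truncates with a warning. Zero-variance predictors
are dropped with a warning. At full rank the PLS solution coincides with
least squares, which the test suite exploits as an independent oracle.

## The synthetic generator

The generator emulates the design and the statistical structure the
analysis assumes — it is the package's study system, not a fixture:

* planted mean-RDE archetypes (null; early-negative recovering;
  late-positive no-recovery; transient mid-window; negative
  no-recovery): zero before onset, linear rise to the peak, then either
  held (no-recovery) or decaying to zero by the last day;
* a persistent per-genotype deviation δ_g (SD in percent units) that
  scales with the profile's activity — the genotype's own drought
  response, and the quantity post-harvest traits are linked to;
* day-wise genotype effects drawn from an unstructured, possibly
  time-varying G(day), giving the genetic-correlation profile its
  planted shape (an invalid covariance raises, naming the day);
* carrier effects, per-plant noise with treatment-specific SD, and
  gross outliers injected with a stated probability and magnitude;
* post-harvest traits whose per-genotype RDE is
  `base + Σ_j w_j δ_g(j) + noise`, realized as control/drought plant
  values around genotype means.

Planted RDE semantics are on the genotype-mean scale (the estimand), so
with zero noise and zero G the pipeline reproduces planted profiles to
machine precision. All randomness descends from one seed through named
substreams (genotype effects, noise, outliers, deviations, post-harvest)
so stages re-simulate independently.

**Demonstration scenario.** The bundled scenario keeps the full panel of
97 genotypes and 2 carriers per condition but uses 2 plants per carrier,
20 imaging days (drought on days 5–14) and 24 image traits — sizes
chosen so the complete 50-seed end-to-end suite runs in minutes while
every stage still operates in its intended regime. The 24 traits form
six tight families (five effect shapes plus nulls), emulating the heavy
redundancy of image pipelines where many traits measure near-identical
features; one trait per non-null family carries a large deviation SD
(5%) and drives the post-harvest targets. Each spike-complex member has
one dominant planted driver (weight 2.0 vs 0.4–0.5 for the shared ones),
so the complex stays internally correlated while every linked trait is
strongly identifiable; TGW is driven by three of the five. Expected
per-day trait–target correlations for dominant links are ≈ 0.8, far
above the P < 0.001 critical value (≈ 0.33 at n = 97), so recovery
failures indicate pipeline defects rather than sampling bad luck.

**What the synthetic experiments do not show.** Genotype effects are
independent across days (no temporal autocorrelation beyond the planted
profile); carriers are exchangeable (no conveyor position effects, which
the real design handles by shuffling); traits are generated
independently given their family archetype (no residual cross-trait
correlation); outliers are additive shifts, not the structured failure
modes of image segmentation; and phenology is not simulated, so the
ANCOVA covariate path is exercised only with synthetic covariates.
Passing tests therefore validate the statistical machinery and its
bookkeeping, not robustness to those real-data features.

## Known limitations

* Exactly two conditions and two carriers per condition are assumed by
  the repeatability filter; the mixed model itself tolerates unbalanced
  carrier counts.
* The Wald reference is χ²(1); for very small panels a
  denominator-df-adjusted test would be preferable.
* The scree rule is a heuristic stand-in for reading the plot by eye;
  for publication-grade cluster counts, inspect the WSS curve and pin
  `chosen_k_*` in the config.
* Spline smoothing of profiles, shown in typical figures, is cosmetic
  and deliberately not part of the pipeline.
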