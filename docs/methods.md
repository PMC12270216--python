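# Methods

This note documents the models, the synthetic data they are tested
against, and the numerical and design choices, in the package's own
terms.

## Generalized-gamma normative model

Regional grey-matter volumes are positive and right-skewed, and their
location, spread and skew all change with age. The normative model
therefore regresses all three parameters of a generalized gamma
distribution on covariates (GAMLSS style). We use the (μ, σ, ν)
parameterization with `z = (y/μ)^ν` and `θ = 1/(σ²ν²)`:

```
f(y) = |ν| θ^θ z^θ exp(−θz) / (Γ(θ) y)
F(y) = P(θ, θz)        ν > 0
     = 1 − P(θ, θz)    ν < 0
```

(`P` = regularized lower incomplete gamma). The family nests the gamma
(ν = 1) and the log-normal (ν → 0); |ν| < 1e-4 switches to the
log-normal limit analytically, avoiding the 0/0 in θ. All densities are
computed in log space.

**Predictors.** `log μ` takes an intercept, a fractional polynomial of
age, and additive sex and handedness effects; `log σ` takes an intercept
and optionally its own age FP; ν is a free intercept. Fractional
polynomial powers come from the standard set {−2, −1, −½, 0, ½, 1, 2, 3}
(0 ≡ log, repeated powers multiply in another log factor). Age is first
rescaled to `t = (age − age_min + 1)/10`, which keeps `t` positive (so
every power is defined) and of order one (so coefficients are
comparable); `age_min` is stored with the fit so centiles are
reproducible out of sample.

**Estimation.** Maximum likelihood by L-BFGS-B with analytic gradients,
initialized from the OLS regression of log-volume on the μ design
(σ from the residual SD, ν = 1), plus two perturbed restarts with ν
pushed toward 0.5 and 2. Convergence: projected-gradient norm 1e-6 or
500 iterations. Standard errors come from the finite-difference observed
information at the optimum.

**Study random intercept.** An optional Gaussian intercept on `log μ`
per study absorbs residual between-cohort offsets. It is fitted by
penalized joint likelihood; τ² is profiled on an outer grid
(τ²/Var(log y) ∈ {1e-4 … 1}) against a Laplace-approximate marginal
likelihood, using the closed-form Hessian of the generalized-gamma
log-likelihood in the log-μ direction (−θν²z per observation).

**Model selection.** Candidates (FP degree for μ, σ; random effect
in/out) are compared by `BIC = −2ℓ + k log n` with k the number of free
fixed parameters (+1 for τ²). The candidate grid is capped at three μ
terms and two σ terms, mirroring growth-chart practice; the default σ
model is age-only and the default μ model carries sex and handedness —
whether σ should also take sex/handedness is genuinely open, so it is a
switch, not a fixed decision.

**Centiles.** A scan's centile is the fitted CDF at its volume given its
age, sex and handedness; an unknown study gets the population-level
(random intercept = 0) prediction, and outputs are clamped to
(1e-12, 1−1e-12). Centile curves are the inverse CDF per quantile and
cannot cross, by monotonicity of the quantile function.

## Harmonization (ComBat) and QC

Scanner effects are modelled as location–scale distortions of the
residual around the covariate-conditional mean — exactly the classical
parametric empirical-Bayes ComBat model. The implementation follows the
standard algorithm: batch-fraction-weighted grand model, pooled-SD
standardization, per-batch location/scale estimates, normal/inverse-gamma
EB shrinkage iterated to 1e-6, adjustment, covariate reinstatement.
With shrinkage disabled the output equals direct per-batch
standardization, which is the oracle the tests compare against. EB
hyperparameters are moment-matched across regions, so a single-region
call silently uses the direct estimates. ComBat is applied within
cohort (batch = site nested in cohort) before pooling. The
non-parametric prior variant is an exposed flag but not implemented.

QC excludes scans with any regional volume outside
`[Q1 − 4·IQR, Q3 + 4·IQR]` (quartiles by linear interpolation). The
fence is anchored at the quartiles, not the median — the standard
Tukey-fence generalization; with the multiplier at 4 the two readings
differ by 0.5·IQR on each side and exclusions are nearly identical.
Cross-sectional visit selection keeps baseline scans except for cohorts
flagged as irregular-follow-up, where one visit is drawn per participant
with probability proportional to the reciprocal of that visit wave's
scan count ("frequency-standardized" sampling; we read the wave-level
scan count as the frequency in question).

## Trajectory comparison

Group mean curves use a penalized natural cubic regression spline in age
with K = 3 basis functions (knots at the age minimum, median, maximum; a
linear column plus curvature columns), second-derivative penalty
integrated numerically on a 200-point grid, and the smoothing parameter
chosen by REML on a 33-point log grid (λ ∈ 1e-8 … 1e8). Prediction SEs
come from the Bayesian posterior covariance σ̂²(XᵀX + λS)⁻¹.

Covariate adjustment (sex, handedness, study dummies) is estimated on
the pooled case+control sample with the age effect modelled as a
6-basis spline, and the centered covariate contributions subtracted.
Pooling embodies the assumption that covariate effects are independent
of case status; group is deliberately absent from this model.

The two group curves are compared at each grid age (default 8–70y, step
0.05y → 1241 ages, clipped to the common fitted support) with
`z = (m₁ − m₂)/√(se₁² + se₂²)`, two-sided normal p, and BH adjustment
**across grid ages within region** — grid points are strongly
correlated, so the FDR bound is conservative and the null tests check a
`≤ 2α` bound rather than equality. Contiguous significant runs shorter
than 10 grid ages (0.5y) are suppressed as isolated points; the minimum
run length is our addition and configurable. A smoothed z curve (and the
log p curve) are emitted for continuous displays; smoothing is applied
to z, with log p provided because either could be the display quantity.

Longitudinal validation regresses follow-up-minus-baseline change on
group + baseline age + sex and compares the group coefficient's sign
with the cross-sectional spline slope difference at the mean baseline
age. External validation uses the Spearman correlation of z curves on
the overlapping age support (threshold r ≥ 0.25) and inverse-variance
weighted pooling (`w = 1/se²`) for combining trajectories across
samples.

## Behavioral and atlas factors

Composite scores use iterated principal-axis factoring on the item
correlation matrix, retention by the Kaiser rule (eigenvalues > 1, with
a 1e-10 tolerance so an exact-identity correlation retains zero),
varimax rotation, and regression-method scores. Principal-axis +
varimax was chosen for the behavioral composites because the atlas
decomposition explicitly uses varimax and consistency aids
interpretation; the maximum-likelihood alternative is available in
scikit-learn and is used as an independent cross-check in tests only.

The atlas decomposition treats regions as observations and terms as
variables (so factor scores live per region and form the factor-level
brain map); factors explaining > 1% of variance are retained, and a term
is retained for a factor when its loading exceeds 0.2 **and** sits at or
above that factor's 50th loading percentile. Whether the factor-level
map should be regression scores or retained-loading-weighted term sums
is not determined by the procedure itself; both are implemented, scores
by default. With fewer regions than terms the correlation matrix is
singular; it is eigenvalue-smoothed and scores use the pseudo-inverse.

Per-age association of a factor map with the case–control z pattern is
the simple-regression R², with permutation p-values
`p = (1 + #{null R² ≥ observed})/(N + 1)` from region-label permutation
(the same permutation reused across ages within a draw, preserving the
track's spatial consistency). Spherical parcel coordinates are not
shipped, so spin nulls cannot be generated internally; precomputed spin
or variogram null maps are accepted through `null_maps=` and take the
place of label permutation. BH runs across ages within factor.

## Genomics

Case status over longitudinal visits: case iff flagged on more than half
of visits (a tie is a control). Association scans are score tests —
residualized-genotype linear score tests for quantitative traits,
null-model logistic score tests for binary traits — with per-SNP mean
imputation of missing calls and monomorphic SNPs skipped. This is a
deliberate plain-score-test design suited to the moderate imbalance of
the synthetic phenotypes; saddlepoint-corrected mixed models are out of
scope.

`wGMV = Σ_r w_r · centile_r` with weights taken from the per-region
case–control z statistics (the brain-score reading of the weight
definition; a GWAS-z weighting is accepted through the same interface).

**Conditional FDR.** For SNP i,
`F̂(p1ᵢ | p2 ≤ p2ᵢ) = #{j: p1ⱼ ≤ p1ᵢ ∧ p2ⱼ ≤ p2ᵢ} / #{j: p2ⱼ ≤ p2ᵢ}`
and `condFDR = min(1, p1ᵢ/F̂)` (π₀ = 1, conservative). The raw per-SNP
estimator is anticonservative for isolated doubly-extreme SNPs whose
conditioning strata hold only a handful of variants; we therefore
enforce monotonicity by taking the running maximum of the raw values
over `{j: p1ⱼ ≤ p1ᵢ ∧ p2ⱼ ≥ p2ᵢ}` — condFDR is non-decreasing in p1,
and a tighter conditioning stratum can never claim more signal than any
looser stratum did at the same p1. The sweep is O(n log n) with a
Fenwick tree and agrees exactly with the O(n²) double-loop oracle.
conjFDR is the maximum of the two conditional FDRs; significant SNPs are
clumped greedily by distance (250 kb window around index SNPs in
ascending conjFDR order) because no LD reference panel is shipped.

PGS: PLINK-style sliding-window pruning (50 kb window, 5-variant step,
r² > 0.1 removes the larger-p member), allele alignment on id + alleles
with sign flips for swaps and removal of strand-ambiguous A/T–C/G
variants, dosage-weighted score, then partial correlation with the
phenotype given covariates. An externally derived multiplicative bias
correction can be plugged in; none is applied by default because its
formula is not reproducible from available sources.

## What the synthetic generator emulates — and what it does not

`TruthSpec` defaults encode the study conditions: four cohorts (ages
9–13, 14–23, 22–37, 45–73; ≥ 2 sites each), site location shifts
(SD 40 mm³) and scale factors (log-SD 0.07), additive sex (+150 mm³) and
handedness (+25 mm³) effects, generalized-gamma volume noise (σ = 0.15,
ν = 0.7 — positively skewed), median-volume age curves rising in
childhood and declining thereafter, and case–control difference curves
in within-age SD units: inverted-U for cortical regions (amplitude 0.3,
peak 45y, width 12y) and exponential decay for subcortical regions
(amplitude 0.3–0.4, time constant 20y). 30% of the adolescent cohort
receives a follow-up visit 2 years later, re-using the participant's
latent quantile so within-person correlation is high. Behavioral items
load 0.7 on two latent factors, one of which is correlated 0.3 with a
target region's centile. GWAS truth: 20k–50k SNPs on 4 chromosomes,
causal fraction 1%, shared-causal fraction 0.1–0.2%, shared mean shift
|z| = 6, LD by an allele-copying Markov chain (adjacent-SNP genotype
correlation = the block r, geometric decay).

Volumes are generated from the same generalized-gamma family the
normative module fits, so calibration tests are exact by construction; a
log-normal switch exists for misspecification checks. The generator does
**not** emulate: realistic LD from reference panels, population
stratification, scanner drift over time, item nonresponse mechanisms
beyond cohort-level instrument masks, diagnosis measurement error, or
attrition. Passing tests therefore demonstrate correctness of the
machinery under its stated model, not robustness to those real-data
features.

## Problem sizes and runtime choices

The test suite and acceptance script run everything at sizes chosen to
make Monte-Carlo bounds sharp but keep a full run in minutes on one CPU:
normative recovery and BIC selection at n = 5000 × 20 seeds; centile
coverage at n = 10⁴; grid operating characteristics at n = 1000/group ×
50 null seeds and n = 3000/group × 20 planted seeds; ComBat at
300/batch × 3 batches; conjFDR at 50k SNPs × 20 null seeds; permutation
calibration at 200 repetitions × 200 permutations. The pipeline default
of 2000 per cohort with 12 regions is the intended interactive scale.

## Known limitations

- ν is modelled as a constant; strongly age-varying skew would be
  absorbed into σ and μ.
- The REML grid for the spline smoothing parameter is discrete; between
  grid points the smoother is marginally off-optimal (with K = 3 the
  effect is negligible).
- The Laplace marginal for τ² is approximate; with very few studies the
  τ² point estimate is noisy (BIC comparisons remain stable).
- Distance clumping without LD can split one haplotype block into two
  loci or merge adjacent independent signals.
- The atlas factorization with regions as observations has n < p; the
  smoothed-correlation pseudo-inverse makes scores well-defined but not
  unique in the null space.
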