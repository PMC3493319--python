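# Methods

`vqtlscan` detects variability-controlling QTL (vQTL): loci whose allelic
state predicts the *variance* of a quantitative trait around its
genotype-specific mean. A vQTL signal typically flags an unmodeled
interaction — epistasis with another locus, or a gene-by-environment
effect — so variance tests double as a one-dimensional screen for
interactions whose partner need not be measured. The package implements
three families of tests, the diagnostics that guard them, and a
Monte-Carlo benchmark of their calibration and power.

## Models and tests

### Group-based non-parametric tests (`classical`)

Dosages are rounded to hard genotype classes {0, 1, 2}
(round-half-to-even, so 0.5 maps deterministically; clearly fractional
dosages, |dosage − round| > 0.1, are counted and surfaced as a warning
because grouping discards genotype-probability information). Classes
with fewer than two observations are dropped; if fewer than two classes
remain the marker is treated as monomorphic and skipped.

*Levene's test* computes z_ij = |y_ij − c_j| with c_j the class mean
(classical form, the default of `levene_test`) or median (the
Brown-Forsythe variant) and refers the one-way ANOVA F statistic on z to
F(k−1, N−k). *Fligner-Killeen* ranks |y_ij − median_j| across all N
observations (midranks for ties), maps ranks to normal scores
a(r) = Φ⁻¹(½ + r/(2(N+1))), and refers
X² = Σ_j n_j (Ā_j − ā)²/V² to χ²(k−1), where V² is the sample variance
of the scores. Both are robust to distributional misspecification but
cannot adjust for continuous covariates or fractional dosages.

If every deviation is identical the statistic is 0 and p = 1 (no
evidence either way); constant-within but different-between deviations
yield an infinite F with p = 0 — both flagged with warning codes.

### Double generalized linear models (`dglm`)

The fully parametric route fits mean and dispersion jointly. Gaussian
model:

    y_i ~ N(x_i'β, σ_i²),   log σ_i² = z_i'λ.

Estimation alternates (a) weighted least squares of y on X_m with
weights 1/σ_i², yielding residuals e_i and hat values h_ii of the
weighted projection, and (b) a log-link gamma GLM of the
leverage-corrected squared residuals d_i = e_i²/(1 − h_ii) on X_d with
prior weights (1 − h_ii)/2. The leverage correction removes the
downward bias E(e_i²) = (1 − h_ii)σ_i²; the ½-weights encode that a
squared Gaussian residual is a scaled χ²₁ variable (gamma with
dispersion 2). The outer loop stops when the largest scaled coefficient
change max |Δθ|/(1 + |θ|) over (β, λ) falls below `tol` (default 1e-8;
the hybrid absolute/relative form keeps the criterion meaningful for
coefficients near zero), or at `max_iter` (default 100), in which case
the fit is returned with `converged=False` and a warning. A dispersion
linear predictor beyond ±700 would overflow exp() and raises a
divergence error. The Gaussian log-likelihood is monitored across outer
iterations; a decrease is recorded as a convergence diagnostic warning.

With an intercept-only dispersion design the cycle collapses to OLS:
the weighted gamma fit of e²/(1−h) with prior weights (1−h)/2 has the
closed form σ̂² = RSS/(n − p), and unit weights are then a fixed point.
This identity is the engine's primary correctness oracle.

For Poisson counts the mean submodel is a log-link Poisson IRLS fit
with prior weights 1/φ_i, and the dispersion response is the unit
deviance d_i = 2[y_i log(y_i/μ̂_i) − (y_i − μ̂_i)] (0·log 0 = 0), floored
at 1e-10 (the gamma response must be positive), leverage-corrected and
modelled exactly as above. Inference uses the extended quasi-likelihood
(EQL) −½Σ[d_i/φ_i + log φ_i], implemented up to an additive
data-only constant: the conventional −½ log(2πV(y_i)) term is
parameter-free (and unbounded at y = 0 under V(y) = y), so dropping it
leaves every likelihood-ratio comparison unchanged while keeping the
reported value finite.

The vQTL test compares dispersion design [1, g] against [1], with the
mean design [1, covariates, g] kept in both fits so the statistic
isolates the variance effect. The default statistic is the likelihood
ratio 2(ℓ_full − ℓ_null) on χ²(1) (floored at 0; a value below −1e-8 is
flagged); a Wald alternative uses λ̂_g and its standard error from the
gamma-submodel covariance (X_d' diag((1−h)/2) X_d)⁻¹. Genotype enters
as an additive dosage (1 df), which also accommodates imputed genotype
probabilities directly.

### Two-stage approximations (`twostage`)

SVLM and relatives condition on a stage-1 OLS mean fit (intercept,
covariates, and — by default — the SNP, since an ordinary GWAS model
contains the SNP; a switch reproduces covariates-only pre-correction).
Stage 2 regresses squared residuals on [1, g] by OLS (`normal_sq`,
SVLM), by a log-link gamma GLM (`gamma_sq`, with a Pearson-moment
dispersion estimate scaling the Wald covariance), or uses absolute
residuals (`normal_abs`). Covariates are excluded from stage 2 by
default (they were removed in stage 1); stage-2 OLS inference uses the
t reference with n − p₂ degrees of freedom. No leverage correction is
applied inside the two-stage tests themselves — their defining shortcut
is precisely that residuals are treated as known — so the package
instead exposes `hat_screen`, which flags any stage-1 hat value at or
above 0.05; a passing screen means prediction error in the residuals
cannot materially distort the squared-residual regression. A stage-2
response that is numerically an exact linear function of the design
(e.g. constant squared residuals) returns W = 0, p = 1 with a warning
rather than a 0/0 t-statistic.

### Scale diagnostics (`boxcox`)

A locus that shifts the mean of a trait measured on an unfortunate
scale drags the variance along with it (volume of a cylindrical
organism vs the length the gene actually controls). `boxcox_profile`
grid-searches the power-family exponent λ over [−2, 2] in steps of 0.05
(grid search is reproducible and exponent resolution below 0.05 has no
practical use), maximising the Gaussian profile log-likelihood of the
transformed trait under a mean-effects design plus the Jacobian term
(λ−1)Σlog y, and reports a χ²(1) profile interval. The transform uses
the expm1 form (y^λ−1)/λ = expm1(λ·log y)/λ, which is numerically
stable as λ → 0 — with the naive form, grid points adjacent to zero are
garbage and the log case can never win the profile search. The
transform is user-invoked preprocessing; tests never apply it
implicitly. Per-class coefficients of variation (sd/mean, flagged
undefined for non-positive means) cover the positive-trait case where a
mean-tracking sd is expected under the null.

## Simulation scenarios (`simulate`)

All scenarios draw g ~ Bin(2, 0.4) independently per individual (a
marker in Hardy-Weinberg proportions at allele frequency 0.4; the count
scenario reuses the same genotype law) with n = 10,000 by default:

* **interaction_vqtl** — F ~ N(0,1) latent, y ~ N(0.85·F + 0.06·g·F, 1).
  Marginally Var(y|g) = 1 + (0.85 + 0.06g)² while E(y|g) = 0: a pure
  variance signal produced by an interaction. F is stored for
  truth-checking but deliberately kept out of every test-facing
  interface, mirroring an unmeasured interacting factor.
* **gaussian_null** — y ~ N(0,1) independent of g.
* **poisson_null** — y ~ Poisson(exp(−1 + 0.05·g)): a mean effect whose
  variance tracks the mean only through the Poisson law. Not a vQTL;
  any dispersion rejection on the raw scale is a misspecification
  artifact.

Datasets are deterministic functions of (scenario, parameters, seed);
studies derive per-trial seeds as seed + trial index, so they are
reproducible and pairable across methods.

What the generators do **not** emulate: linkage between markers,
polygenic background and relatedness, covariate structure, genotyping
or imputation error, and ascertainment. Passing benchmarks therefore
demonstrate correctness of the statistics under clean sampling
assumptions, not robustness to population structure — the latter is
explicitly out of scope.

## Benchmark (`benchmark`)

`run_study` simulates one dataset per trial and applies every requested
method to the *same* dataset, so method contrasts are paired. Rejection
rates at α (default 0.05, the "95% significance level") come with the
binomial Monte-Carlo standard error √(r(1−r)/trials); stored per-trial
p-value vectors make rejection rates at other α exact recomputations.
Non-converged fits contribute their p-value but are counted, and a
method exceeding 2% non-convergence is flagged. `run_power_study` adds
the Pearson correlation between the SVLM and Gaussian-DGLM per-trial
p-values on the interaction scenario.

The benchmark's Levene runs median-centered by default. The choice was
open — descriptions of the test name mean centering first — but on the
Poisson-null scenario the two variants differ sharply (mean-centering
rejects ~0.78 of trials, median ~0.47) and only the median-centered
rates line up with the published comparison; it is also the default of
the widely used R implementation (`car::leveneTest`). `levene_test`
itself keeps classical mean centering; pass `levene_center="mean"` to
benchmark that variant.

Known reproduction gap: the Poisson-family DGLM's false-positive rate
on the Poisson null lands at ~3.5–4.6% across seeds versus the
published 5.5% (within three Monte-Carlo standard errors, but
consistently below). With counts this small (μ ≈ 0.37) the unit
deviances have variance well under the 2μ² the gamma dispersion
submodel assumes, which makes the deviance-based EQL ratio test mildly
conservative; the exact statistic behind the published figure is not
recorded, and the LRT/Wald choice does not close the gap (both give the
same rates here).

## Numerical and design choices

* All small dense solves go through Cholesky factorisation of the
  normal equations; rank deficiency raises immediately. With a log link
  the gamma IRLS working weights reduce to the prior weights, so the
  dispersion fit is a fixed-weight WLS iteration — this is what makes
  3,000 DGLM fits per benchmark study cheap.
* Squared residuals are floored at 1e-300 (Gaussian dispersion
  response) and 1e-12 (two-stage gamma variant, with a warning); unit
  deviances at 1e-10. These only matter for exact zeros.
* Multiple-testing adjustment (none / Bonferroni / Benjamini-Hochberg)
  is applied per method across markers at write-out time.
* Alignment keeps phenotype-file sample order, making downstream fits
  independent of genotype file ordering; missing trait/covariate values
  are handled by listwise deletion (no phenotype imputation).
* The benchmark study sizes (1000 trials of n = 10,000) match the
  published comparison; the full three-study acceptance run completes
  in about a minute on one core.

## Limitations

* No population-structure or polygenic random-effect correction
  (HGLM-style extensions); results on structured samples will be
  confounded.
* Single-marker tests only; no multi-marker or haplotype models.
* The Poisson DGLM's EQL inference is approximate for very low counts
  (see above); for traits with mean ≪ 1 its dispersion test errs on the
  conservative side.
* Group-based tests silently lose information for imputed genotypes;
  the fractional-dosage warning count should be monitored.
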