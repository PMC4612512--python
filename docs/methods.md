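# Methods

## The design and the estimand

A full-sib/half-sib (FSHS) breeding design mates each sire to several
dams and assays several daughters per dam. Offspring of one dam are full
sibs; offspring of one sire across dams are paternal half sibs. Because
paternal half sibs share only additive genetic effects (expected
relatedness ¼), the between-sire variance component isolates ¼·V_A free of
maternal and common-environment contamination, which instead loads on the
dam component. The package estimates, for two female life-history traits
(longevity in days and early-life mating frequency, the count of matings
accepted in a female's first six opportunities):

- observational components V_sire, V_dam, V_R from the nested mixed model;
- derived parameters V_A = 4·V_sire, V_P = ΣV, h² = V_A/V_P, and the
  mean-standardized evolvabilities CV_A = √V_A/x̄, CV_P = √V_P/x̄,
  CV_R = √(V_P − V_A)/x̄, I_A = V_A/x̄²;
- additive genetic correlations between trait pairs from bivariate animal
  models on the pedigree relationship matrix.

CV_R is defined through V_P − V_A rather than through the model residual
V_R: the model residual of a half-sib analysis still contains ¾ of V_A, so
only the V_P − V_A definition keeps the identity CV_A² + CV_R² = CV_P²
(and only it reproduces the motivating study's printed residual
coefficients for both traits).

## Subsetting rules and trait derivation

A female enters the analysis only if (i) she was alive for at least six
mating opportunities, (ii) she mated at least once in her life, and
(iii) she died naturally (escaped and accidentally killed females are
dropped). "At least six opportunities" counts opportunities *offered*, not
accepted. "Mated at least once" is read as anywhere in life — the looser
of the two possible readings — with an `early_only` switch for the
stricter one. Early-life mating frequency is the count over opportunities
1–6, later-life over 7–death, and their sum is the lifetime count;
`derive_traits` enforces the early + later = lifetime identity exactly.

Significance tests for the mating-frequency model are run on the
log(x+1) scale, but genetic parameters are always extracted from
untransformed fits: variance components extracted on a transformed scale
cannot be mean-standardized into comparable evolvabilities.

## REML for the nested model

The marginal covariance V = V_sire·Z_sZ_s' + V_dam·Z_dZ_d' + V_R·I is
block diagonal by sire family, and within a family it is
I + λ_d·blockdiag(J) + λ_s·J after scaling by V_R. Applying the
Sherman–Morrison identity first at the dam level and again at the family
level gives the inverse and log-determinant in closed form from per-dam and
per-family sums alone, so one likelihood evaluation costs a few small
matrix products regardless of sample size. The restricted likelihood is
profiled over V_R and maximised over (log λ_s, log λ_d) with L-BFGS-B from
three starts (a method-of-moments start and two fixed spreads), followed by
a derivative-free Nelder–Mead polish (relative function tolerance 1e-12 on
−2ℓ_R); the polish matters because finite-difference gradients stall a few
1e-9 in log-likelihood short of the optimum, which is visible against the
balanced-design closed form. Components below 1e-8·V_P are reported as
exactly 0 — dam components on the boundary are routine in these designs.
Fixed-effect covariances come from the inverse expected information
(X'V̂⁻¹X)⁻¹; Wald statistics are β̂'Cov(β̂)⁻¹β̂ with χ² reference. Random
effects are tested by likelihood-ratio between nested REML fits with the
same fixed effects, referred to χ²₁ by default (the plain-χ² convention;
because the null pins the variance at the boundary this is conservative,
and a 50:50 χ²₀:χ²₁ mixture is available via a flag). Model selection is a
single backward pass keeping fixed terms with full-model Wald p < α; Wald
tests use the full-model covariance, the conventional choice.

An independent balanced-design oracle (`anova_oracle_balanced`,
expected-mean-squares method of moments) and a dense multivariate-normal
evaluation of the same restricted likelihood serve as cross-checks; the
test suite also compares components against R's lme4 on a simulated
dataset.

## Animal models

The numerator relationship matrix A is built by the tabular recursion
(A_ii = 1 + ½A_sire,dam; A_ij = ½(A_j,sire + A_j,dam)); unknown parents are
unrelated founders and cyclic pedigrees are rejected. Fitting uses only the
submatrix over phenotyped individuals — marginalising a Gaussian additive
effect over unphenotyped relatives leaves exactly that submatrix.

Likelihoods are evaluated in the eigenbasis of A, computed blockwise over
the connected components of the relatedness graph (one small block per
sire family in an FSHS design; a fully connected pedigree degrades to one
dense eigenproblem). In that basis G⊗A + R⊗I becomes an independent 2×2
covariance d_i·G + R per individual, inverted in closed form, so a
bivariate study-scale fit takes ~0.2 s. G and R are parameterised by their
Cholesky factors (log-diagonal), which keeps every iterate positive
semidefinite; optimisation is L-BFGS-B from three starts (genetic
correlation seeded at 0 and ±0.6 around univariate component estimates).
The SE of r_g uses the delta method on the inverse observed information,
with the Hessian of −2ℓ_R taken by central differences in
(g11, g12, g22, r11, r12, r22) coordinates at the optimum. An optional 2×2
dam covariance (shared-dam indicator) is available but off by default, as
univariate analyses of such designs typically find the dam component near
zero for longevity; with it the eigen shortcut no longer applies and the
fit falls back to dense per-family blocks.

Fixed effects in the bivariate models mirror each trait's univariate
minimal model, except that a covariate identical to the partner trait is
dropped so the genetic covariance is not partialled out twice.

## Jackknife standard errors

All genetic parameters carry delete-one-sire-family jackknife SEs:
SE = √((n−1)/n·Σ(θ₋ᵢ−θ̄₋)²) over the n leave-one-family-out re-fits of the
entire REML pipeline. No Tukey pseudovalue bias correction is applied to
the point estimate — the simple delete-one-group formula is standard
practice and deterministic. Calibration at study scale (70 sires): the
average jackknife SE of h² across datasets is within a factor 1.5 of the
Monte-Carlo SD of h² across independent replicates (itself ~0.19 at
h² = 0.5), though the jackknife SE from any *single* dataset is itself
noisy (observed range roughly 0.10–0.23).

## The synthetic-data generator

The generator emulates the motivating assay: n_sires sires × 3 dams × 4
assayed daughters (defaults 72/3/4 → 864 daughters, of which ~80% survive
the subsetting rules, matching the published 775 → 613 attrition). Two
traits follow the infinitesimal model: a daughter's breeding value is
½a_sire + ½a_dam + m with Mendelian deviation m ~ N(0, ½G), so half-sib
covariance is ¼G and full-sib ½G. Trait 1 is longevity (days); trait 2 is
a latent logit-scale mating propensity observed only through
per-opportunity Bernoulli outcomes at probability expit(α + a₂+d₂+e₂),
with α solved by Gauss–Hermite quadrature so that the expected early-life
count matches the configured mean (default 2.085). Longevity is

 base + a₁ + d₁ + e₁ + β_date·start_date + β_mating·(lifetime matings),

rounded to whole days; because matings accrue only while alive, the pair
(longevity, matings) is resolved as the least fixed point of the monotone
map L ↦ base + β·matings_before(L). Opportunities follow the Mon/Wed/Fri
cadence (gaps 2,2,3 days) from age 4. Dam families are assigned to a small
number of discrete start-date batches entering linearly; attrition
(escape/accidental death) is an independent Bernoulli flag. Default
variances mirror the published longevity components (G₁₁ = 50.41,
V_dam ≈ 0, V_resid = 45.98 → h² = 0.523) and a genetic correlation −0.65
with the mating liability. The default intercept (41 d) makes the realized
mean longevity ≈ 40.5 d after the mating and start-date contributions, and
β_mating defaults to 0.25 d per mating, calibrated so the study-scale Wald
χ² for lifetime matings on longevity is of the published order (~74). Note
that even β = 0 yields a strongly significant lifetime-matings "effect"
(χ² ≈ 40) purely through reverse causation — longer-lived females receive
more opportunities — which is why recovery harnesses switch the covariate
path off entirely rather than adjusting for it.

What the generator does *not* emulate: male-side variation (the study
standardised males from isogenic lines precisely to remove it),
fecundity traits, age-dependent decline in mating propensity, and
overdispersion structure — real mating counts were *under*dispersed
relative to a Bernoulli process (published count SD 0.88 at mean 2.085,
below binomial noise), so the simulated count-scale heritability of trait
2 is necessarily lower than the published 0.634 even when the
liability-scale h² is comparable. Passing recovery tests therefore show
the estimators are correct under the stated generative model, not that
real mating sequences are Bernoulli.

## Recovery harnesses and their conditions

Parameter-recovery runs (in `halfsib.harness`) use a 70×3×3 design at the
published scale with liability components chosen for clean truths:
h²(longevity) = 48/(48+4+44) = 0.5 and r_g = −0.65. Two deliberate
departures from the full generative defaults, both decided from the design
rather than from any test outcome:

- **β_mating = 0 in recovery configs.** Lifetime matings is a noisy
  monotone function of longevity (longer life → more opportunities), so
  with the feedback on, adjusting longevity for lifetime matings absorbs
  genuine genetic variance and the covariate-adjusted h² has no clean
  configured truth. Recovery probes the estimator, so the feedback is off
  and start date (exogenous) is the only covariate.
- **Intercept 48 d in recovery configs.** Dying before the sixth
  opportunity acts as phenotypic selection: even ~2% truncation measurably
  shrinks between-family covariance (Bulmer-type effect, ≈ −0.026 in h²),
  a property of the subsetting rule, not of REML. In the published subset
  no analysed female died inside the six-opportunity window (minimum
  longevity 13 d), so the harness sets the intercept high enough that the
  truncated fraction is negligible (~0.04%); the measured residual filter
  effect is then ≈ −0.007.

Wald-test calibration simulates the full study-mimicking defaults, appends
an individual-level standard-normal covariate with zero true effect, and
measures the rejection rate of its Wald test at α = 0.05 over 1000
replicates (observed ≈ 0.044–0.057, inside the binomial 95% interval).
Problem sizes — 200 replicates for h², 100 for r_g, 1000 for calibration —
were fixed in advance as the package's validation design.

## Numerical choices and degenerate inputs

- Variance ratios are bounded in log-space at [−25, 8]; the lower bound is
  far below the zero-reporting threshold, so boundary solutions terminate
  cleanly.
- All-zero G is valid (breeding values exactly 0); a non-PSD G or A, a
  negative variance, a non-positive mean, or a cyclic pedigree raise
  configuration errors before any computation.
- `genetic_correlation` clips |r_g| > 1 to ±1 with a warning (possible at
  finite sample when a variance estimate is tiny).
- Identical seed + configuration reproduce byte-identical CSV/TSV outputs;
  every pipeline stage draws from streams derived from the single run
  seed.
- Jackknife re-fit failures abort with the identity of the left-out family
  rather than silently dropping it.

## Known limitations

- The Gaussian LMM is used for mating counts (after a log(x+1) check for
  testing), as is conventional for these designs; no generalized mixed
  model is provided.
- The delta-method SE of r_g can fail (reported as NaN with a warning)
  when the optimum sits on the PSD boundary.
- The dam component cannot be split into maternal-genetic vs
  common-environment causes; the design does not identify them.
- Single-replicate h² estimates at 70 sires are noisy (SD ≈ 0.19);
  conclusions at that scale rest on the jackknife/MC-calibrated SEs, not
  on point estimates.
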