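# Methods

This note documents the models, the synthetic-data generator, the
numerical conventions, and the design choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Loss-aversion estimation

Per subject, accept/reject decisions over mixed gambles (gain `G`, loss
`L`, win probability 0.5) are modeled as

    P(accept) = logistic(β₀ + β_gain·G − β_loss·L),  λ = β_loss / β_gain.

Losses enter with a negative sign and a positive weight, so λ is the
classic "ratio of betas". Estimation is maximum-likelihood logistic
regression (statsmodels). Degenerate records (all-accept/all-reject) and
complete or quasi separation fall back to a Jeffreys-prior (Firth)
penalized fit — Newton scoring on the hat-value-adjusted score
`X'(y − p + h(½ − p))` — which keeps λ finite; the subject is flagged
(`separation_flag`), never silently dropped. If the fitted gain weight
is non-positive, λ is reported as undefined (NaN), never as 0.

**Intercept.** `estimate_lambda` includes an intercept by default, which
absorbs an overall acceptance bias in real data. The synthetic generator
plants no acceptance bias (β₀ = 0), and with 104 trials the
three-parameter fit inflates the ratio estimator's noise several-fold
(error SD ≈ 0.4–0.8 vs ≈ 0.1–0.25 for the matched two-parameter fit).
All recovery simulations, the pipeline default, and the acceptance
script therefore fit without the intercept — the estimator matched to
the generating process. Set `include_intercept=True` (or the pipeline
config flag) for real choice data.

**Choice-consistency scale.** λ fixes only the ratio of the weights; the
gain-weight scale `DEFAULT_BETA_GAIN = 0.25` sets choice stochasticity.
At this scale the λ-estimate reliability at 104 trials is ≈ 0.85, so the
SD of *measured* λ is close to the latent group SDs — the regime the
study populations' printed group SDs imply. Much smaller scales make
choices so noisy that measurement error dominates the between-subject
spread and no downstream coupling is detectable at n = 22; much larger
scales make most subjects perfectly consistent (separation). 12–33% of
simulated subjects (rising with λ) hit the Firth fallback at this scale;
their estimates remain accurate.

**Residualization.** λ is residualized against the risk-attitude score
by a single-predictor OLS pooled over the whole sample; residuals have
exactly zero mean and zero sample correlation with the score. A constant
score degenerates to mean-centering, with a warning.

## 2. Behavioral inference

Two-sample t-test (Student by default, Welch optional), ANCOVA by
nested-model F (partial η² = SS_group/(SS_group+SS_resid), Cohen's
f = √(η²/(1−η²))), 2×2 group-by-sex ANOVA with Type-III sums of squares
under sum-to-zero coding (the SPSS convention, appropriate for
unbalanced cells), Kolmogorov–Smirnov normality with the
Lilliefors-corrected p by default (parameters are estimated from the
sample; the known-parameter variant is available), Pearson correlation
screening, and Benjamini–Hochberg FDR applied independently within
declared test families.

## 3. Synthetic data

**Gamble design.** Gains and losses are integers uniform on [1, 99],
rejection-sampled until |Pearson corr| ≤ 0.10 (a concrete, testable
version of "symmetric range, not significantly correlated"); a constant
column counts as correlation 0.

**Cohort.** 22 AUD (9 female) and 19 control (8 female) behavioral
subjects, plus 42 age/sex-matched imaging-only controls. True λ is
drawn per group from N(1.90, 0.23²) (AUD) and N(2.13, 0.38²) (HC),
truncated below at 0.2. Covariates (age, education, smoking, BMI,
ordinal clinical scores, disease duration 10.4 ± 6.4 y clipped to
[1, 26] for patients) are plausible but carry no planted associations;
the risk score is independent N(0, 1), so residualization is close to
centering by construction.

**Volumes.** Default grid 40×48×40 at 4 mm (a desk-scale stand-in for
2 mm standard space), RAS+ affine with the origin at the grid center,
ellipsoidal brain mask. Voxel values are

    baseline (100)
    + group amplitude · 1[AUD] · (hypo/hyper sphere masks)
    + slope_LA · (λ_true − mean λ) · LA sphere
    + slope_sex(sex) · (λ_true − mean λ) · interaction sphere
    + u_subject · interaction sphere            (regional variability)
    + age slope · (age − mean) · brain mask
    + smoothed Gaussian noise (post-smoothing SD 4, FWHM 8 mm)
    all × exp(N(0, 0.1²))                        (global uptake factor)

The LA sphere overlaps the hypometabolism sphere so the conjunction has
a nonempty true intersection. The global factor is removed by SUVR
scaling (verified to 1e-8). Out-of-brain voxels are ≈ 0 and are excluded
by the two-pass global rule.

**Planted amplitudes** (hypo −8, hyper +8, LA slope −45, interaction
male −150 / female 0, noise SD 4) were set by a closed-form power
analysis of the *full* analysis chain: volumes are planted on true λ but
analyzed against estimated λ, so apparent slopes are attenuated by the
measurement reliability (≈ 0.85) and the λ-error contributes
slope²·Var(error) of extra voxel noise. The chosen values put the
expected in-cluster t at ≈ 5–8 against a forming threshold of ≈ 3.6.
The in-cluster interaction t has an asymptote in the slope magnitude
(the λ-error noise term also scales with the slope), so amplitudes
beyond these buy nothing.

**Regional variability** (`interaction_regional_sd = 10`): every subject
receives a λ-independent scalar offset in the interaction region. Real
regional metabolism varies between subjects for reasons unrelated to
loss aversion; without this term the no-coupling sex has near-zero ROI
variance and its simple slope in the inverse (λ-on-metabolism)
moderation regression is ill-conditioned — its sign would be decided by
noise amplified by a vanishing denominator.

**What the generator does not emulate:** PET physics, attenuation or
motion artifacts, spatial misregistration, anatomically shaped regions,
spatially varying baseline anatomy, or covariate–outcome confounding.
Passing tests therefore demonstrate the *statistical machinery* —
estimator consistency, error control, recovery of planted effects —
not robustness to acquisition or registration pathology.

## 4. Voxelwise statistics

SUVR scaling uses the SPM-style two-pass rule (global = mean of voxels
above one-eighth of the whole-volume mean; output = input/global, so
the global target is 1 — any constant target cancels in all
statistics). Smoothing is a separable Gaussian with
σ = FWHM/(2√(2 ln 2)) per axis in voxel units, zero-flux boundaries.

The GLM is ordinary least squares per in-mask voxel, vectorized;
`t = c'β̂ / √(σ̂² c'(X'X)⁻¹c)` with df = n − rank(X). Contrasts are
one-sided in the stated direction (hypo- and hyper-metabolism tested
separately). The interaction design centers λ before forming the
sex×λ product; sex is coded male = 1, female = 2, matching the
moderation module.

**Cluster-level FDR** is implemented as permutation-derived cluster
p-values followed by BH across clusters, rather than random-field
theory: suprathreshold voxels (one-sided forming p < 0.001, t with the
model's df) are labeled with 18-connectivity (6/26 configurable); the
null distribution of the *maximum* cluster extent is built by
Freedman–Lane permutation (reduced nuisance-only fit; residuals
permuted and added back; full model refit) — with an intercept-only
nuisance this reduces to ordinary data permutation; each observed
cluster gets p = (1 + #{max null ≥ K})/(B + 1); BH is applied across
the observed clusters. Weak familywise/FDR control is verified on 100
null datasets in the acceptance suite. The permutation resolution floor
1/(B+1) multiplied by the BH factor means small B can leave a true
cluster just above q = 0.05; the default B = 1000 keeps the floor at
≈ 0.001·m.

**Conjunction** is the minimum-statistic rule: a voxel survives iff it
exceeds its forming threshold in both maps; the surviving set is exactly
the intersection of the suprathreshold sets (tested). Because the two
parent maps come from different cohorts (group map: patients +
imaging controls; coupling map: patients only), no joint permutation
null is defined; a conjunction cluster instead inherits the larger of
its parents' corrected cluster p-values — it can be no more significant
than its weaker parent.

**Peaks** are within-cluster local maxima over the 26-neighborhood, up
to 3 per cluster, sorted by t with lexicographic voxel-index
tie-breaking, reported in world mm via the affine.

## 5. Moderation

OLS of λ (residualized) on mean-centered ROI metabolism, sex, their
product and disease duration. Robust covariance default HC3 (HC0–HC4
implemented by hand and cross-checked against statsmodels), used for
all analytic CIs, conditional effects and the Johnson–Neyman quadratic.
The model F and the highest-order-interaction F are robust Wald tests
(the interaction F is exactly the squared robust t of the product
coefficient); the classical R²-based model F and ΔR²-based interaction
F are reported alongside, labeled — published conditional-process
tables of this kind print the robust versions.

Sex coding male = 1, female = 2, uncentered: this is the unique
convention under which a published table's focal and interaction
coefficients are mutually consistent with its printed per-sex
conditional effects (b1 + b3·1 and b1 + b3·2), and the package's
conditional-effect identity `b1 + b3·w` is exact by construction.

Bootstrap: case resampling, percentile intervals, default B = 50,000
(batched normal-equation solves, ≈ 1 s); rank-deficient resamples are
redrawn up to a cap and any residual failures reported. Point estimates
never depend on B or the seed. Coverage of the percentile interval for
the interaction coefficient is verified at B = 2,000 over 300
simulations (n = 60 per simulation, where percentile coverage is close
to nominal; at n ≈ 22 percentile intervals of this model over-cover
slightly).

Johnson–Neyman solves `(b1 + b3w)² = t²_crit·Var(b1 + b3w)` with the
robust covariance; 0/1/2 real roots map to "entire range" / "nowhere" /
a bounded region, a degenerate quadratic falls back to a 100,001-point
grid; binary moderators report per-level significance instead.

Effect sizes: f = √(η²/(1−η²)), f² = ΔR²/(1−R²_full). Post-hoc power is
the noncentral-F tail probability; both circulating noncentrality
conventions (ncp = f²·N and ncp = f²·(df1+df2+1)) are computed and
labeled, as published "achieved power" values do not state theirs.

## 6. Pipeline, seeding, problem sizes

`run_pipeline` derives every stochastic substream (cohort, imaging
controls, volumes, three permutation streams, bootstrap) from one
top-level seed via `SeedSequence.spawn`, so a rerun is byte-identical.
Stage failures abort with the stage name. The moderation ROI defaults
to the largest significant sex×λ cluster, falling back (flagged) to the
largest suprathreshold cluster and then to the planted truth mask.

Problem sizes in the shipped analyses and tests are desk-scale choices:
default grid 40×48×40 at 4 mm with 1000 permutations for the full runs;
the error-control suite uses a 16×20×16 grid with 500 permutations and
100 null datasets; λ-recovery suites use 200–500 simulated subjects.

## 7. Known limitations

- At the study's sample sizes the behavioral group test has power
  ≈ 0.55 against the generating group difference (0.23 on SDs of
  0.23/0.38 plus measurement noise), so roughly half of simulated
  cohorts do not show a significant behavioral difference; the imaging
  couplings, planted per subject, are far more reliably detected.
- Recovery of the moderation interaction's *sign* from the inverse
  (λ-on-metabolism) regression is intrinsically noisy when one sex has
  no coupling: with 9 females its per-seed reliability has a ceiling of
  ≈ 90% regardless of planted amplitudes (the female simple slope's
  sampling noise scales with 1/(ROI SD·√n_f)). Across seeds 0–7 at the
  default configuration the full qualitative structure reproduces in
  most but not all runs; the shipped end-to-end check uses the
  package's default seed 0.
- Cluster p-values are extent-based only (no mass or TFCE), and no
  random-field theory is implemented.
- The conjunction's inherited p-value is a bound, not a calibrated
  joint test.
- Anatomical labeling, registration and PET reconstruction are out of
  scope; volumes are assumed aligned.
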