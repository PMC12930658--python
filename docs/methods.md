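# Methods

`memtraj` implements a longitudinal analysis of how within-person change in
the CSF pTau181/Aβ42 ratio tracks within-person change in verbal memory,
and how that coupling is moderated by sex and disease stage (preclinical AD
vs MCI). Because the motivating data source (ADNI) is access-controlled,
the package ships a synthetic cohort generator with the same statistical
structure, and validates the estimator by parameter recovery against the
generator's truth.

## Pipeline

1. **Normative scoring** (`norms`). Each of six neuropsychological tests
   (TMT-A, TMT-B, Category Fluency, Boston Naming, RAVLT Delayed Recall,
   RAVLT Recognition) is regressed on baseline age, sex and education in a
   robust normal control group — participants cognitively normal at every
   visit. Only control *baseline* visits enter the regression, avoiding
   practice-effect contamination (which control visits enter is otherwise an
   open choice). z = (observed − predicted) / residual scale, where the
   residual scale is the RMS residual with denominator n − p (immaterial at
   n ≫ p; fixed for determinism). Timed tests are sign-flipped so impairment
   is uniformly z < −1. Sex can be dropped from the norms (`--no-sex-norms`)
   to reproduce the sex-adjusted vs non-adjusted comparison discussed in the
   sex-differences literature: sex-adjusted memory norms raise female and
   lower male MCI rates.

2. **Actuarial staging** (`staging`). MCI iff (a) both tests within one
   cognitive domain have z < −1 (strict), or (b) at least one test in each
   of the three domains does. Diagnosis is anchored to baseline. Cognitively
   normal participants positive on any AD biomarker — CSF ratio ≥ cutpoint,
   amyloid PET, or tau PET — are staged preclinical AD; a dementia flag
   excludes. The CSF cutpoint defaults to 0.025 (higher ratio = more
   pathology, ≥ convention at the boundary) and is configurable; published
   ADNI cutpoints vary by assay and no single value is canonical.

3. **Change scores** (`change`). The memory outcome is the mean of the
   within-sample standardized (population-SD) RAVLT Learning and Delayed
   Recall scores; standardization uses the full analysis sample across all
   visits. Change in any repeated measure is the *lag-1 residual*: all
   within-participant consecutive visit pairs are pooled per variable, the
   current value is regressed on the prior value by OLS (one global
   autoregression — per-participant fits are infeasible with 2–5 visits),
   and the residual is the change score. Residuals are exactly mean-zero and
   orthogonal to the prior value on the fitting sample; this removes the
   autocorrelation bias of raw difference scores. Change scores are computed
   once on the full sample and reused by stratified models, so stratified
   coefficients refer to a common change metric. Lag pairs ignore calendar
   gaps by default (`max_gap_years` can restrict them).

4. **Inference** (`models`). The primary model is a linear mixed model with
   a participant random intercept, estimated by REML:

   `memory_change ~ biomarker_change * sex * group + age_c + educ_c + apoe`

   with female, preclinical and APOE-ε4 non-carrier reference levels. CIs
   and p-values use the Wald normal approximation (portable; a Satterthwaite
   option is out of scope). ICC = τ00/(τ00+σ²) holds to machine precision.
   R² is the marginal (fixed-effects) variance share. Standardized effect
   sizes come from refitting with the outcome and all continuous predictors
   z-scored, binary predictors left 0/1 (the standardization method is a
   package choice, recorded in output); |weight| < 0.20 is labeled small,
   0.20–0.39 moderate, ≥ 0.40 large. Stratified models fit the 2-way
   interaction within diagnostic group (and optionally within sex). Income
   is accepted as a covariate but off by default. Secondary outcomes
   (Trails B, CDR-SB change) use median (τ = 0.5) regression for their
   non-normal distributions, with participant-level bootstrap CIs
   (B = 500 default, seeded); no multiple-testing correction is applied,
   matching the raw-p reporting convention of the design. A singular fit
   (τ00 → 0) is reported, never hidden; if no participant has two change
   rows the model falls back to OLS with a flag.

## Synthetic cohort generator

Defaults encode the study conditions: 78/73/104/146 participants per
sex-by-stage cell, 525 robust controls, five annual visits (mean follow-up
4 years; the source design reports ≈4 years and no missingness mechanism,
so dropout defaults to 0 and is available as MCAR truncation of trailing
visits), baseline age ≈ 74 (SD 6.5), education ≈ 16 (SD 2.6), APOE-ε4
carrier probability 0.57.

* **Biomarker**: random walk with participant drift,
  `B_t = B_{t−1} + drift_i + e_t`; baseline ≈ 0.044 with stage-specific
  spread; preclinical baselines are truncated above the positivity cutpoint
  (preclinical is *defined* by biomarker positivity); drift is higher in
  MCI (0.0045/visit) than preclinical (0.0020/visit); innovation SD 0.010.
* **Memory**: a single latent level feeds both RAVLT scores (the analysis
  averages them, so one factor suffices). Increments contain a
  stage-specific practice effect (+0.07 preclinical, −0.05 MCI), a male
  increment offset, the biomarker coupling, a participant random intercept
  u_i ~ N(0, 0.17²) on the increment mean, and innovation noise
  N(0, 0.20²). The coupling slope structure mirrors the published fixed
  effects: γ_B = −12.25, γ_B×sex = 8.27, γ_B×group = 5.10,
  γ_B×sex×group = −16.63 (z per unit ratio change; female/preclinical
  reference). Baseline cell means follow the observed-data pattern
  (preclinical-F 1.017 … MCI-M −0.246), which yields practice-driven memory
  gains in preclinical and decline in MCI, larger in males.
* **Observed scores** are affine maps of the relevant latent plus
  demographic gradients and test noise, clipped to published ranges (clips
  logged); TMT times decrease with better function and orientation is
  handled downstream by the per-test higher-is-better flag. CDR-SB is
  half-point quantized, giving the skewed, discrete distribution that
  motivates median regression.
* **Diagnostic separation**: true-MCI participants carry a deep latent
  deficit in the speed/executive and language domains, so the actuarial
  rules recover the generative stage labels with ≈95% agreement, while the
  *memory* latent keeps the moderate stage gap seen in the observed-data
  tables. Placing the diagnostic deficit outside the memory domain is a
  deliberate design choice (a non-amnestic presentation): it decouples the
  diagnostic rule from the memory outcome's scale so the two can be
  calibrated and tested independently.
* **Scale calibration** (design-time, frozen): the RAVLT noise SDs and
  variance components are set so that the pooled SD of each raw RAVLT score
  over the default analysis population equals its latent loading (measured
  1.001 and 0.998). The in-sample-standardized composite is then on the
  latent memory scale, so generative coupling coefficients are directly
  comparable to fitted ones — this is what makes parameter recovery of the
  three-way coefficient meaningful. A related numerical subtlety: memory
  *observation* noise induces a negative MA(1) correlation between
  consecutive lagged residuals that pushes the REML random-intercept
  variance to its boundary, so the generator carries most memory noise as
  random-walk innovation rather than observation error.
* A latent-truth sidecar (stages, latent levels, increments, random
  intercepts, drifts) is emitted separately and never consumed by the
  analysis pipeline.

## What the simulation studies show — and what they do not

Parameter recovery (200 study-shaped replicates, generative three-way
coupling −16), type-I error (null generator, α = .05 rejection in
[0.03, 0.07]), and the stratified sign pattern (coupling encoded only in
the MCI stratum) validate the change-score + mixed-model machinery against
the generator's truth, using true stage labels so estimator properties are
not confounded with actuarial misclassification (≈5–10% of cognitively
normal participants meet MCI criteria by chance — a realistic property of
the rules, exercised separately). The generator draws Gaussian latents with
linear observation maps and MCAR dropout; real cohort data have non-Gaussian
test distributions, floor/ceiling effects at higher pathology, informative
dropout, assay batch effects and calendar-irregular visits. Passing these
suites therefore shows the *method* is implemented correctly and is unbiased
under its own assumptions — not that those assumptions hold in ADNI.

## Numerical choices and limitations

* MixedLM uses the statsmodels default optimizer with a Powell retry on
  non-convergence; convergence status is carried in the result.
* Lag regressions require ≥ 3 pairs and non-constant prior values; the
  composite requires non-zero variance in both components; rank-deficient
  normative designs fail naming the collinear term (e.g. single-sex
  controls).
* Scores are clipped to published ranges; clipping is rare (< 1% of values
  at defaults) and logged.
* The quantile-regression bootstrap resamples participants, not rows, to
  respect clustering; its p-values are two-sided sign-crossing fractions
  and are granular at small B.
* Visit spacing is configurable (1-year default); the lag is defined by
  consecutive observed visits, not calendar time.
* The pipeline never attempts network access; real extracts are supplied as
  CSV with a user column map (ADNIMERGE-style aliases built in).
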