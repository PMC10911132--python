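# Methods

## Observation model

The package treats a participant's striatal specific binding ratio (SBR) as
a latent biological quantity seen through a site's acquisition chain. For
participant *j* at site *k*, scanner *s*, feature *g* (left/right striatum):

    latent_gj  = μ_dx(j) + shift_k·1[dx=PD] + β_age·(age_j − 65)
                 + β_sex·1[male] + u_gj
    observed_gj = a_s · latent_gj + b_s + c_k + ε_gj

* `u_j ~ N(0, σ²_dx · R(ρ))` — between-subject spread, shared across the G
  features through an equicorrelation matrix R(ρ); left and right striatal
  SBRs are highly but not perfectly correlated.
* `(a_s, b_s)` — affine scanner response (collimator, reconstruction,
  attenuation handling). A phantom scanned on every scanner sees exactly this
  map plus noise: `measured = a_s·r + b_s + η`, `η ~ N(0, σ_phantom)`.
* `c_k` — additive per-site procedure bias from local VOI-placement
  conventions. Phantom scans do *not* see it (the phantom analysis is
  standardized); only a standardized re-analysis of the patient images
  removes it, which is why the pipeline takes procedure-standardized SBRs as
  an input on real data and uses the generator's known `c_k` on synthetic
  data.
* `shift_k` — per-site shift of the PD mean expressing recruitment
  differences in disease severity. This is biology, not acquisition: scanner
  calibration deliberately leaves it in place, while ComBat — which cannot
  distinguish biological from technical site differences beyond its protected
  covariates — removes it along with the batch effect.
* `ε` — iid measurement noise. Observed values are floored at 0.05 (binding
  ratios are positive).

## Synthetic cohort defaults

The generator's defaults encode the four-site structure of the multisite
DAT-SPECT study the package models: site × diagnosis counts
(NCNP 45/16, KPUM 6/5, KU 21/48, FMU 0/12 — FMU contributes no controls),
truncated-normal age distributions and exact sex splits per cell from the
study's demographic table, and five scanners (two at NCNP; NCNP_A is the
calibration reference).

The remaining defaults were chosen once so that the *pooled original-stage*
group summaries land on the study's published values, 6.13 ± 1.54 (HC) and
2.03 ± 1.41 (PD), with large original-stage site ANOVA statistics in both
strata:

| parameter | default | reasoning |
|---|---|---|
| μ_HC, μ_PD | 7.05, 3.50 | reference-scale means at the female/age-65 baseline; pooled means then match after site effects and covariate mixes |
| σ_HC, σ_PD | 1.00, 0.60 | within-site spread; PD tighter per site, with between-site severity shifts providing the rest of the pooled PD dispersion |
| β_age | −0.04 /yr | binding declines a few % per decade |
| β_sex | −0.15 (male) | small male deficit |
| σ_ε | 0.12 | test-retest-scale measurement noise |
| gains a_s | 1.00, 1.05, 0.95, 0.83, 0.92 | KU's low gain makes it the outlying site, especially visible in PD |
| offsets b_s | 0, −0.10, 0.30, −0.50, 0.10 | |
| procedure c_k | 0, 0.05, −0.85, 0.05 | KU's VOI convention further lowers its values |
| pd shifts | +0.30, +0.35, −0.38, +0.25 | severity heterogeneity across sites |
| G, ρ | 2, 0.9 | left/right features; high inter-side correlation exercises the EB path while the feature mean stays comparable to a single averaged SBR |
| phantom | ratios {2,4,6,8} × 3 replicates, σ_phantom 0.04 | typical striatal-phantom fill series |

Averaged over 200 seeds the defaults give pooled original summaries
HC 6.18 ± 1.57 and PD 2.07 ± 1.29 — within 10% of the published values on
every number. The pooled PD SD sits ~9% low by necessity: a pooled PD
distribution with mean 2.03 and SD 1.41 built from within-site normals is
impossible without pushing an appreciable mass of the dominant low-SBR site
below zero. Real severe-PD SBR distributions are right-skewed near zero; the
truncated-normal generator trades that skew for positivity. A config whose
implied non-positive mass exceeds 1% (computed analytically per
site × diagnosis × scanner cell) triggers a warning, or an error in strict
mode.

Enabling PD severity shifts by default is a deliberate choice: without them
the published pooled PD dispersion, positivity, and normal within-site
distributions cannot hold simultaneously, and the study itself attributes
residual post-calibration PD site differences to between-site severity
(MDS-UPDRS III) disparities.

### What the generator does not emulate

No image formation: reconstruction, attenuation/scatter, VOI geometry are
collapsed into (a, b, c). No skewed or heavy-tailed within-site
distributions, no longitudinal structure, no missing data, no
diagnosis-uncertain participants (prodromal PD among "controls"). Passing
tests therefore demonstrate correctness of the statistical machinery under
the affine-site-effect model, not robustness to real-world distributional
pathology.

## Corrections

**Age/sex** — OLS of each feature on centered age and a male indicator,
healthy controls only (≥ 10 HCs spanning ≥ 5 years); subtract-and-recenter to
the female/age-65 baseline. Fitting on HCs keeps the disease effect out of
the normative slope. A cohort with a single sex or no age spread raises a
named degeneracy error.

**Scanner calibration** — replicate phantom measurements are averaged within
each true ratio; the reference scanner's series is regressed on each site
scanner's series, paired by ratio (prediction direction: the map *converts*
site values onto the reference scale — not orthogonal regression). The
reference scanner maps to the exact identity; a non-positive fitted slope is
rejected as pathological. Intercepts are always fitted; a proportional-only
variant can be emulated by supplying phantoms through the origin.

**Prospective** = procedure standardization followed by scanner calibration.
Procedure standardization is an input (externally recomputed SBR column,
joined by id) or, on synthetic data, subtraction of the generator's known
bias; it is not estimable from the participant table.

**ComBat** — the parametric empirical-Bayes location/scale model. Fitting
steps: (1) least squares of the feature matrix on batch indicators plus
covariates, with the batch-location constraint Σᵢ (nᵢ/N)·γ̂ᵢg = 0 (the
weighted grand mean is the intercept); (2) pooled residual variance σ²_g
(1/N convention); (3) standardization; (4) per-batch naive location/scale
estimates; (5) moment-matched hyperparameters — normal prior (γ̄ᵢ, τ²ᵢ)
across features, inverse-gamma prior (λᵢ, θᵢ) from the mean/variance of the
batch scale estimates; (6) iterated conditional posterior means for
(γ*, δ*²) until the maximum relative change drops below `tol` (default 1e-4,
`max_iter` 100). The adjusted value restores the covariate contribution:

    Y*_gj = σ_g · (Z_gj − γ*_ig) / δ*_ig + α_g + X_j β_g.

Numerical conventions worth knowing:

* Batch scale estimates use the 1/n convention, consistent with the pooled
  σ². This makes the non-EB adjustment exactly idempotent and removes
  affine-constructed batch effects to machine precision; Bioconductor `sva`
  uses 1/(n−1), a difference that decays as 1/n (the cross-implementation
  test agrees to ~1e-2 at 100 records/batch and documents this).
* Default batch = scanner (one site hosts two); site is a config option.
* A batch containing a single diagnosis class (FMU has no controls) is
  *warned about*, not rejected: β is pooled across batches, but that batch's
  location estimate partially absorbs the disease effect.
* EB needs ≥ 2 features to form across-feature priors; with one feature, or
  with degenerate scale moments (zero across-feature variance), fitting
  falls back to exact location/scale adjustment with a warning (error in
  strict mode).
* No reference-batch mode: output lives on the pooled scale, which is why
  ComBat-corrected means can sit below both inputs when a large low-valued
  site dominates the pool.

The pipeline applies ComBat to the age/sex-corrected stage, mirroring a
study design in which covariate correction precedes harmonization.

## Evaluation

* **ROC/AUC** — PD is the positive class; decision rule SBR ≤ t ⇒ PD. AUC via
  the Mann–Whitney rank identity with half-credit for ties (verified
  exhaustively against pair counting); thresholds are midpoints between
  adjacent distinct scores plus ±∞; Youden ties break toward higher
  sensitivity (the clinically conservative direction — favor catching PD).
  All-identical scores return AUC 0.5 with a degeneracy flag.
* **Hedges's g** — J·(m₁−m₂)/s_pooled, J = 1 − 3/(4(n₁+n₂) − 9), pooled
  variance with (nᵢ−1) weights.
* **Brown–Forsythe ANOVA** — F\* = Σ nᵢ(x̄ᵢ−x̄)² / Σ (1−nᵢ/N)sᵢ², numerator
  df k−1, denominator df by Satterthwaite on the (1−nᵢ/N)sᵢ² weights. Exact
  under homoscedasticity; known to run mildly liberal (≈ 6% at α = 5%) under
  strong variance ratios even at large n, because the numerator is a weighted
  chi-square mixture approximated by a single scaled chi-square. The
  calibration test uses a moderately heteroscedastic null (n = 30/40/50,
  SD = 1/2/3) where the classic statistic holds its level.
* **Post-hoc t-tests** — Welch by default (pooled df is a config away),
  Benjamini–Hochberg adjustment across the pairwise family within each
  diagnosis stratum. The cross-method comparison computes all stage pairs;
  which family a real analysis should adjust over is reported in the
  evaluation notes rather than decided silently.
* **Normality** — Shapiro–Wilk (3 ≤ n ≤ 5000) per diagnosis group.
* **Site ANOVA strata** — within each diagnosis, sites contributing ≥ 2
  records; a stratum with fewer than two such sites reports no test rather
  than a fabricated one.
* **Misclassification audit** — deterministic partition at a fixed threshold
  with per-id margins (score − threshold); PDs above threshold are the
  scan-negative ("SWEDD"-like) patients, and on synthetic data their margins
  track the latent severity, mildest first.

## Determinism

All randomness descends from one base seed through named substreams
(cohort, phantom, evaluation) via `numpy` `SeedSequence` spawning, so
re-running a pipeline with the same config and seed reproduces every CSV
byte for byte, and a change in one stage's draw count cannot perturb the
others. CSV floats are written with shortest round-trip repr and parsed with
`float_precision="round_trip"`, making read(write(x)) exact.

## Known limitations

* The affine scanner model is first-order; real scanner differences include
  resolution-dependent, non-linear partial-volume effects that an affine map
  only approximates.
* ComBat here is the cross-sectional parametric variant: no nonparametric
  priors, no reference batch, no longitudinal or GAM extensions.
* Small batches (KPUM hosts 11 participants) make their location/scale
  estimates noisy; EB shrinkage mitigates but cannot eliminate this, and with
  only two features the priors themselves are estimated from two points.
* Brown–Forsythe p-values in the far tail (the p < 0.001 regime used for the
  original-stage site test) inherit the approximation error noted above.
* No confidence intervals on AUC (DeLong) — differences between near-ceiling
  AUCs are reported without inferential error bars.
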