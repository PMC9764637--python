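# Methods

## Problem

Early-stage invasive breast cancer is graded by pathologists along three
Nottingham axes (tubule formation, nuclear pleomorphism, mitotic activity),
and treatment decisions lean on that grade plus clinical covariates. This
package implements a risk pipeline in which the grading axes are replaced by
quantitative features computed from labeled tissue maps (cell point sets and
region polygons in µm coordinates) and combined with clinical covariates in
a censored-data support vector regression (SVRc), yielding a 0–100
recurrence-risk score dichotomised at a threshold chosen to maximise
sensitivity + specificity at a six-year horizon.

The cohort this style of model was developed on is private. The package
therefore ships a synthetic-cohort generator with known ground truth; every
claim the test suite makes is a claim about recovery of that ground truth,
not about real tissue.

## Synthetic cohort

Each patient carries a latent aggressiveness `a ∈ [0,1]`, drawn with a
mildly U-shaped Beta(0.6, 0.6) marginal (indolent and aggressive tumours
both common, the middle ground rarer). A Gaussian copula couples `a` with
tumour size (rank correlation ≈ 0.42), nodal burden (≈ 0.42), grade (≈ 0.55)
and ER status (≈ −0.25); clinical marginals are matched to a published
early-stage cohort (~87 % ER+, ~75 % T1, ~69 % node-negative, grade mix
≈ 19/42/40 %, median age 60). Stage is derived AJCC-style from size and
nodal categories.

Survival is Weibull (shape 1.2, baseline scale 780 months) with log hazard

    η = effect_size · [ (a − 0.5) + 0.40·(LN − E[LN]) + 0.005·(age − 60) ]

where LN is the ordinal nodal code (0, micro, 1–3, >3 → 0–3). `effect_size`
scales the whole predictor, so `effect_size = 0` is a global null — no
covariate, latent or clinical, carries signal. Censoring is administrative
at 144 months plus uniform dropout for 35 % of patients; at the defaults
(n = 2000, effect_size = 1.5) the observed event fraction is ≈ 14 %.

The relative weights were fixed once, at design time, by simulating (a) the
event fraction against the 14 % target and (b) the oracle concordance of the
true η (≈ 0.77 at effect_size 1.5) with the constraint that the
aggressiveness term — the morphology signal — dominates the predictor. A
draft with a heavier nodal weight produced models that scored well while
ignoring morphology, contradicting the premise of an image-based grade.

Tissue maps realise the morphology: 9–13 epithelial glands as smooth
star-shaped (hence simple) polygons; a fraction `tubule_fraction`
(decreasing in `a`) keeps an enclosed lumen; lumen-free growth becomes a
large sheet with propensity increasing in `a`; peri-epithelial lymphocyte
density falls with `a` (placement decays exponentially, 45 µm scale, from
the epithelium); mitoses cluster around a hotspot with rate rising in `a`;
epithelial nuclear areas are log-normal with dispersion rising in `a`.
Multiplicative log-normal noise (`noise_sd`, default 0.3) decouples each
patient's rates from `a` imperfectly, and Poisson sampling adds counting
noise.

What the generator does **not** emulate: pixel-level stain appearance,
segmentation error (cell labels are exact), spatial heterogeneity beyond a
single 2 mm field, competing risks, or informative censoring. Passing
recovery tests therefore demonstrates that the pipeline's statistics are
implemented correctly and can recover a known morphology–outcome link; they
say nothing about segmentation robustness on real slides.

## Morphometric features

All operators are deterministic, unit-aware (µm in, per-mm² or dimensionless
out) and invariant under rigid motions (the skeleton-based branching index
only approximately, since it is raster-based).

* **TIL density** — lymphocytes within a 50 µm band outside the epithelium,
  per mm² of band area (band = buffer minus epithelium, clipped to the
  field). Density rather than raw count removes field-size dependence.
* **Nuclear pleomorphism** — (mean of the top 1 % of epithelial nuclear
  areas − overall mean) / overall mean; scale-free, ≥ 0.
* **Mitotic hotspot** — the maximum number of mitoses in any circle whose
  area equals ten 0.2 mm² high-power fields (r ≈ 798 µm). Computed exactly:
  an optimal fixed-radius circle can be anchored on one point or on two
  boundary points, so candidates are all points plus the two circles through
  each pair closer than one diameter. A 25 µm grid search brackets it in
  tests (grid ≤ exact ≤ grid with radius inflated by half the grid
  diagonal).
* **Tubule branching** — glands are rasterized (2.5 µm/px), thinned with
  Lee's skeletonization, spur-pruned (10 µm) to remove blunt-end artifacts,
  and scored as branch-pixel clusters (≥ 3 skeleton neighbours) per mm of
  skeleton length, pooled over structures as Σbranches / Σlength.
* **Sheet fraction** — epithelial area in lumen-free structures ≥ 40 000 µm².
* **Intact-tubule fraction** — epithelial area in structures enclosing a
  lumen.

Degenerate inputs fail loudly: no epithelium, < 10 epithelial nuclei, or a
zero-length skeleton raise a `FeatureError` naming the feature; zero-area or
invalid polygons are rejected when the map is constructed.

## Feature curation

A univariate Harrell-C screen against the censored outcome retains features
whose C-index falls outside (0.4, 0.6) — discriminative in either
orientation. The published description of this screen prints a band that
cannot be a two-sided exclusion; symmetric bounds about 0.5 are used and are
configurable. The age–size composite defaults to `size × (60 / age)`
(a 2 cm tumour at 30 counts like 4 cm at 60); the formula is a documented
default and any callable can replace it.

## Censored support vector regression

With residual `r_i = (w·x_i + b) − y_i` on standardized features and time in
months as the target,

    min  ½‖w‖² + Σ_i [ C_i⁺ max(0, r_i − ε_i⁺) + C_i⁻ max(0, −r_i − ε_i⁻) ]

where each patient's (C, ε) pairs come from the event set or the censored
set. Censoring is handled economically: predicting *later* than a censored
follow-up is cheap (the true event time genuinely is later), predicting
*earlier* is penalised like an ordinary miss. With every patient uncensored
and shared (C, ε) this is exactly classical ε-SVR, which is the oracle
equivalence the tests exploit.

Solver: slacks are eliminated, leaving a (d+1)-dimensional convex
piecewise-quadratic objective minimised by L-BFGS over a Huber-smoothed
hinge with decreasing smoothing (10⁻¹ → 10⁻⁶ of the outcome scale),
followed by an exact active-set KKT polish that solves for the kink
multipliers and is accepted only when it verifiably lowers the true
objective and respects the multiplier boxes. A `fast` mode (single smoothing
stage) is used inside cross-validation; the final fit always runs `exact`.
Against a generic SLSQP solve of the full primal QP the polished solution
agrees to < 10⁻⁶ in predictions; against libsvm it agrees to ~4·10⁻⁶, with
our solution attaining the lower primal objective.

The raw output is a survival-time surrogate (higher = later). Risk is
100·(max_train − raw)/(max_train − min_train), clipped to [0, 100] — the
training range defines the scale, so out-of-range validation predictions
saturate. The threshold scans observed training scores for the maximum of
sensitivity + specificity at the horizon (ties → lowest threshold) and is
reported half-up-rounded (57.77 → 58). A `log_time` switch regresses
log1p(months) instead; months remain the default because the linear kernel
on standardized features makes the scale benign, and the risk score is a
min-max rescaling of the raw output either way.

Hyperparameters (four C's on log₁₀ scale in [−3, 3], four ε's in [0, 24]
months) are tuned by particle swarm (20 particles × 50 iterations,
ω = 0.729, c₁ = c₂ = 1.49445, velocities clamped to half the box) maximising
mean 5-fold event-stratified cross-validated Harrell C. The censored
over-prediction penalty is clamped to ≤ the event over-prediction penalty
when decoding a particle, encoding the censoring economics as a soft
constraint. All randomness is seeded; the same seed reproduces the same
hyperparameters bit-for-bit.

## Survival statistics

Harrell's C (score ties ½, pairs tied on event time not comparable),
Kaplan–Meier with Greenwood CIs, the two-group log-rank test, and a
univariate Cox fit (Efron ties, Newton convergence tightened to 10⁻⁹ so the
estimate matches an external reference fit to < 10⁻⁴) are provided behind
one module; lifelines does the heavy lifting and brute-force enumeration,
hand product-limit arithmetic, permutation calibration and a frozen
R `survival::coxph` fit serve as independent oracles in the tests.

At the six-year horizon a patient is *positive* if an event occurred by 72
months and *negative* if followed event-free to 72 months; patients
censored earlier are excluded and counted. The published 2×2 counts for
this kind of model do not reproduce the printed sensitivity/specificity, so
the exclusion rule — the simplest standard choice — is implemented and
documented, with an unadjusted mode (early-censored counted negative)
available for comparison.

## Study pipeline

The cohort splits 3:1, stratified on (event, grade, ER) with automatic
coarsening (and a warning) when strata are thinner than 2. Three variants
are fitted — clinical-only {age, age–size composite, stage, nodal code},
image-only (the six features), and the combined model — each tuned and
fitted on training only; the threshold comes from training; validation
never touches fitting (a permutation test in the suite verifies the
training-side results are bit-identical when validation outcomes are
shuffled). Receptor status and pathologist grade are available to callers
but excluded from the default variants, mirroring the modelling choice the
pipeline reproduces. Grade redistribution cross-tabulates pathologist grade
against the model's risk strata with half-up percentage rounding. A
rule-table comparator (editable CSV shipped with the package; first match
wins, default low) approximates the Adjuvant!-derived binary clinical-risk
categorisation — grade in, age out. An externally supplied 0–100 score
(e.g. a gene-expression recurrence score) can be appended as one more
covariate and the chosen variant refitted end-to-end on the sub-cohort
where the score exists.

## Problem sizes and numerical choices

The acceptance script runs the full study at n = 2000 (1500/500 split) with
the full PSO budget; the recovery test in the suite uses n = 800 at
effect_size 1.5, and the null-calibration test n = 2000 at effect_size 0 —
sizes chosen to keep the whole suite comfortably reproducible on one CPU
while leaving Monte-Carlo noise well inside the asserted margins. Ties in
threshold selection break toward the lower cut; half-up rounding is used
for all reported integers; standardization uses training means/sds with
zero-sd features mapped to unit scale; the risk scale degenerates (and the
fit refuses) if training predictions are constant.

## Known limitations

* The six features are a compact stand-in for a production catalogue of
  hundreds; the nuisance-feature block emulates only the *screening*
  problem, not correlated redundant features.
* The branching index depends on raster resolution and is only
  approximately rotation-invariant; blob-like glands yield small, noisy
  branch counts (the elongated-structure tests reflect where the statistic
  is actually informative).
* The exact hotspot search is O(m³) in the mitosis count; fields with many
  thousands of mitoses would need the grid approximation instead.
* Cox and log-rank assume proportional hazards and independent censoring,
  which the generator satisfies by construction; real cohorts need those
  assumptions checked.
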