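# Methods

## Scope and pipeline

`gmunit` implements the derivation of an anchored interval scale for
gross motor task difficulty in four stages:

1. **Component rating schema** (`task_schema`). Tasks are rated on three
   ordinal components: body position (1–12, supine through airborne),
   movement (1–22, no movement through hopping on one foot) and support
   (1–5, full proximal and head support through no support). Validation
   is strict — out-of-range codes are rejected, never clamped — because
   the rating ranges define the construct's full extent and silent
   clamping would corrupt measures. Ratings are stored as plain
   integers; category label text is metadata only, since the regression
   consumes numeric codes. Item names are free text and never used as
   keys (published spellings of the same item vary).
2. **Specification equation** (`spec_equation`). Forward stepwise OLS of
   observed item difficulty on the three components, with Pearson
   screening and VIF collinearity diagnosis.
3. **Anchoring** (`gm_scale`). The predicted-difficulty metric is fixed
   to 0 GM units at lying supine bringing hands to midline and 100 GM
   units at walking with hands free.
4. **Synthetic data** (`rasch_sim`). The observed difficulties the
   regression consumes come, in the original derivation, from an
   external Rasch partial-credit-model calibration of 537 clinical
   assessments that is not redistributable. The package therefore
   generates its own: either directly, as specification-equation
   predictions plus Gaussian noise, or structurally, by simulating PCM
   response matrices and recalibrating them.

## Regression procedure

The stepwise rule is pure forward entry: at each step the remaining
candidate giving the largest adjusted-R² increase is tried and admitted
iff its partial-F p-value (equivalently the t-test of the added
coefficient) is below `entry_alpha` (default 0.05); there is no removal
step. p-values use the t distribution on n − k − 1 degrees of freedom;
RMSE is the root mean squared residual on the same degrees of freedom.
VIF_j = 1/(1 − R²_j) from regressing predictor j on the others with
intercept, flagged at ≥ 10. Flagged collinearity is reported, never
acted on automatically; an opt-in `drop_collinear` mode removes, per
flagged pair, the predictor with the weaker zero-order correlation to
the outcome — removal involves judgment, so the default is
non-destructive.

Ordinal ratings enter as numeric integer predictors. Every fit report
carries the standard caveat that per-step coefficients cannot be
interpreted on an interval scale; this is a known limitation of the
modelling convention, not of the implementation.

The reference equation is kept at its printed two-decimal coefficients
(6.76, 1.23, 1.21, 4.93). Carrying more precision would be spurious: the
published reference table is only consistent with the printed values.

## Anchoring and rounding

With anchor predictions d_lo < d_hi and anchor values (0, 100), the
constants are offset = −d_lo and scale = 100/(d_hi − d_lo), and
GM = (difficulty + offset) × scale. Three numerical conventions matter,
all inferred from exhaustive agreement with the published reference
table and applied consistently:

* predicted difficulties are rounded to two decimals before the
  transform;
* the anchor constants are themselves rounded to two decimals
  (offset −14.13, scale 2.09) by default. The exact ratio
  100/47.75 ≈ 2.0942 changes the integer GM measure of five non-anchor
  tasks (e.g. 84 → 85, 89 → 90) and is available via
  `rounding_dp=None` for theoretical work;
* GM units are reported as nearest integers, ties away from zero (no
  reference row sits on a .5 boundary, so the tie rule is a convention,
  not an empirical inference).

Rounded constants make the transform slightly asymmetric: 100 GM maps
back to 61.97, not the 61.88 the anchors were derived from. The
`to_gm`/`from_gm` round trip itself is exact to floating-point
precision. The scale is affine, hence order-preserving and interval
(differences in GM units are proportional to difficulty differences),
and extends beyond both anchors.

## Partial credit model and calibration

The PCM is the adjacent-category Rasch model: for an item with
categories 0..m and step difficulties b_j = δ + τ_j (thresholds τ
centred to sum to zero),

    P(X = k | θ) ∝ exp( Σ_{j≤k} (θ − b_j) ),  empty sum = 0.

Items default to four categories, matching the 0–3 clinical scoring of
the instrument being emulated.

Calibration is joint (unconditional) maximum likelihood: alternating
Newton–Raphson updates of all step parameters (one small solve per item)
and all person abilities (scalar updates), items recentred to mean-zero
difficulty each iteration, convergence when the largest parameter change
falls below 1e-6 (cap 200 iterations, Newton steps damped to ±1, all
parameters boxed at ±10 logits). Standard errors come from the inverse
Hessian of each item's step parameters at the solution. Missing
responses are skipped in all likelihood sums (ignorable missingness).
Preconditions are enforced by filtering: items observed in fewer than
two categories are excluded as inestimable (with a warning); observed
category schemes with gaps are collapsed onto consecutive integers;
persons with all-minimum or all-maximum patterns are dropped. Person
ability estimation with fixed items returns a labelled ±∞ boundary
result for extreme patterns rather than a number posing as an MLE.

JMLE is inconsistent — estimating person parameters jointly inflates the
spread of item estimates by roughly I/(I−1), a factor of two in the
two-item dichotomous case. The calibrator therefore applies Wright's
(I−1)/I shrinkage to the centred estimates by default
(`bias_correction=False` disables it). Measured recovery under the
package's study conditions: two dichotomous items at δ = ∓1 and n =
4000 recover to within 0.03 logits; 66 four-category items × 500 persons
over 20 seeds give a mean absolute difficulty error of ≈ 0.06 logits.
Conditional or marginal ML, weighted likelihood ability estimation, and
fit statistics (infit/outfit) are out of scope.

The metric of the external difficulty estimates the original regression
used is not fully specified (their plotted range suggests roughly
14–73); `rescale_logits` maps calibrated logits onto any interval target
band, and anchoring makes the choice immaterial up to the affine
transform.

## Synthetic-data conditions

The generator's defaults are the study conditions the package is tested
under:

* **Difficulty vectors**: predictions of the reference equation over the
  66 bundled rating triples plus i.i.d. Gaussian noise with SD 6.09
  difficulty units — the residual RMSE of the reference fit — so the
  synthetic signal-to-noise ratio matches the reported real-data fit.
  Under these conditions the mean adjusted R² across 200 replicate
  stepwise refits is ≈ 0.87 and the mean predicted-vs-observed Pearson
  r ≈ 0.93, computed by `scripts/acceptance.py` and the test suite.
* **Response matrices**: 537 persons by default (the external
  calibration's sample size), abilities N(0, 1.5²) logits, item
  difficulties spread over ±3 logits with thresholds (−0.5, 0, 0.5).

What the generator does *not* emulate: real rater disagreement in
component scoring, multidimensionality or local dependence among tasks,
person misfit, and the clinical sampling structure of the original
calibration (children with cerebral palsy across severity levels).
Passing tests therefore show the pipeline's statistical machinery is
correct and well-calibrated under the stated model, not that the
construct theory holds in new clinical data.

Gaussian noise makes no allowance for the ordinal floor/ceiling of real
item difficulties; at SD 6.09 over a ~59-unit range this is negligible.

## Determinism and degenerate inputs

Every stochastic operation takes one explicit integer seed (NumPy
`default_rng`); no global state. Degenerate inputs fail loudly:
constant difficulty vectors yield an intercept-only model with a
warning, constant vectors are rejected by `pearson_r` and
`rescale_logits`, exactly collinear predictors report infinite VIF,
inverted anchors raise. Stepwise ties on adjusted-R² gain are broken by
candidate order (body position, movement, support), which only matters
in exactly symmetric synthetic designs.

## Problem sizes

The bundled table is 66 items. Noisy-refit summaries use 200 replicates;
calibration recovery checks use 500 persons × 66 items over 20 seeds —
sizes at which the Monte-Carlo error of every reported summary is an
order of magnitude below the tolerance it is compared at.
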