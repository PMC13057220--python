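# Methods

This package re-creates, at desk scale and on fully synthetic data, an
imaging-based multi-organ biological-age analysis: an uncertainty-aware
convolutional regressor maps each organ image to a Gaussian over
chronological age, the predicted age gaps (PAGs) are de-biased by median
regression, subjects are stratified into aging groups by an organ-specific
threshold, and the PAGs are related to disease and mortality with
left-truncated survival models.  Because the cohort is generated, every
stage can be validated by recovering parameters the generator knows.

## Synthetic cohort

**Demographics.** Chronological age (CA) at imaging is drawn from a normal
distribution with mean 64.23 y and SD 7.8 y truncated to [44, 83] y, the age
window of large population imaging studies; 53% of subjects are female; BMI
is normal(27, 4.5) kg/m² clipped to a physiological range.  The
administrative censoring age is `CA + U(0, 10)` y, approximating a
2014-to-2024 observation window.

**Organ age gaps.** Each subject carries a latent true age gap per organ
over nine organ systems (brain, heart, left/right kidney, liver, pancreas,
spleen, left/right fundus).  Gaps follow a factor model

    PAG_o = sd_o * (s_o * Z + g_o * W_pair(o)) + e_o,

with a shared systemic factor `Z`, one factor per bilateral pair
(kidneys, fundus), and independent residuals scaled so the marginal SD is
`sd_o` (default 2.5 y, a typical corrected-PAG spread).  The implied
correlation between organs o and p is `s_o s_p + g_o g_p [same pair]`.
Default loadings target the reported cross-organ pattern: kidney pair
r = 0.43, fundus pair r = 0.74, liver-to-abdominal-organ correlations of
roughly 0.22 to 0.28, heart–liver about 0.16, and a weakly coupled brain.
The configuration validates `s² + g² <= 1` per organ, which guarantees a
positive-semidefinite structure by construction.

**Outcomes.** Each outcome (death, Alzheimer's disease, type 2 diabetes,
chronic kidney disease, myocardial infarction) has a constant-rate
proportional hazard acting beyond an onset age (default 40 y):

    age_at_event = onset + Exp(rate),  rate = b0 * exp(beta * PAG_source),

so the true log hazard ratio per PAG year is known exactly.  Events after
the retrieval age (or after an earlier death) are unobserved; a diagnosis
before imaging marks existing pathology, one between imaging and retrieval
future pathology.  Subjects who are ever diagnosed receive a
`disease_acceleration` shift (default +3 y; +2 y for myocardial infarction)
added to the true age gap of the affected organ(s) *after* the hazard is
sampled and *before* images are rendered, so disease groups are separable
only through imaging — the same causal direction the analysis assumes.
The magnitude is a configurable default, not a claimed ground truth.

**Phantoms.** Each organ image is an ellipsoidal "organ" on a 32³ grid
(fundus: a 64² three-channel slice, exercising the 2D path) containing a
dark inner cavity whose radius

    r = r0 + slope_b * (CA + PAG_organ) + jitter

encodes the organ's biological age (defaults r0 = 2 voxels,
slope_b = 0.08 voxels/y — an image-level stand-in for structures that
enlarge with age, such as ventricles).  The cavity wall is anti-aliased
with a sigmoid profile of softness 0.6 voxels so the radius is encoded with
sub-voxel precision.  A per-image texture blur level drawn from
{0.5, 1.0, 1.5} both smooths the image and scales the radius jitter SD
(0.12 voxels × blur ≈ 0.9 to 2.8 y of label noise), making the predictive
uncertainty learnable from visible texture.  A uniform per-axis translation
of up to 1.5 voxels acts as nuisance, and white intensity noise
(SD 0.05) is added.  What the phantoms do **not** emulate: anatomy, MR
physics, multi-contrast acquisitions, scanner effects, or segmentation
errors (masks are exact by construction).  Passing tests therefore
demonstrate that the estimation machinery recovers a known image-encoded
aging signal — not that the models would perform comparably on clinical
images.

## Age regression

The regressor is a deliberately small residual CNN, written in NumPy with
hand-derived backpropagation and trained with Adam: three blocks of
(3×3×3 convolution → instance normalization) + (1×1 projection skip),
ReLU, and 2× average pooling, with 8/16/32 channels, global average
pooling and a two-unit head predicting the mean age `mu(x)` and
`log sigma(x)`.  Fundus images use the same blocks in 2D.  Parameters
minimize the heteroscedastic Gaussian negative log-likelihood

    L = (1/N) Σ_i [ (y_i − mu(x_i))² / (2 sigma(x_i)²) + log sigma(x_i) ],

which lets the network down-weight images whose labels it can only resolve
coarsely (high blur) while reporting that uncertainty.  Ages are
standardized internally; predicted `log sigma` is clamped to [−2, 3]
log-years at inference for stability.  Training runs on the healthy
subjects only (no organ-relevant diagnosis before imaging), split 80/20
with a fixed seed; inference covers the full cohort.  Desk-scale defaults
are 20 epochs, batch 16, Adam step 3·10⁻³, chosen so one organ trains on a
single CPU in a few minutes at n = 500; all are configurable.  Gradient
correctness is verified against central differences per layer.

## Bias correction

Regression toward the cohort mean makes raw predicted ages too old for the
young and too young for the old.  Rather than regressing the gap on CA
alone — which would also strip variance carried by sex or disease status —
the *median* of the raw PAG is modelled on CA plus the covariates whose
influence must survive correction (sex, existing pathology, future
pathology):

    Median(PAG_i | X_i) = β0 + β1ᵀ X_i,

and only the CA coefficient is removed, anchored at the cohort median age
A_ref:

    pred_corr = pred − β1_age (CA − A_ref).

Median (τ = 0.5) regression is solved as an exact linear program
(HiGHS via scipy), which is deterministic, robust to outlying predictions,
and resolves ties at the canonical vertex solution; statsmodels' QuantReg
serves as an independent cross-check in the tests.  The model is fitted on
the full inference cohort because the pathology covariates cannot be
estimated from healthy subjects alone, and per organ, since organs differ
in how much correction they need.  By construction the correction is
affine in CA, so any contrast between groups sharing the same CA values is
numerically unchanged.

## Stratification and group statistics

The corrected PAG is the corrected predicted age minus CA.  Per organ, the
threshold θ is the sample SD (n−1 denominator) of corrected PAGs over the
full inference cohort; subjects are decelerated (PAG < −θ, code 0), typical
(|PAG| ≤ θ, code 1; the boundary is typical) or accelerated (PAG > θ,
code 2).  Cross-organ structure is summarized by the Pearson matrix over
complete cases with Bonferroni control over the 36 organ pairs
(per-test p < 0.05/36 = 1.39·10⁻³); disease contrasts use Welch's
unequal-variance t-test with the comparison family passed in explicitly
(11 tests ⇒ p < 4.55·10⁻³).  PAG distributions are summarized with a
Gaussian KDE (Scott's rule bandwidth by default) and a mean ± 1.96 SD
reference band.

## Survival analysis

Age is the time scale: a subject enters the risk set at the imaging age
(delayed entry) and exits at the earliest of target diagnosis, death from
another cause (censored), or data retrieval.  Prevalent cases (diagnosed
before imaging) are excluded.  When mortality itself is the outcome, every
observed death is an event.  Kaplan–Meier curves and Cox
proportional-hazards fits use lifelines with `entry_col` for left
truncation and Efron tie handling; Wald 95% CIs and p-values are reported,
and nested models are compared with the likelihood-ratio test
(χ² = 2 Δloglik).  The aging group enters as a single ordinal covariate
(0/1/2), reading the reported HR as risk per one-step group increase;
continuous PAGs give risk per year.  Test oracles are independent of
lifelines: a hand-enumerated product-limit computation on a staggered-entry
fixture, and a staggered-entry toy whose partial likelihood
`l(b) = b − log(e^b + 1) − log(1 + e^{2b})` is solved by root-finding.

### Recovery experiment design

The hazard-ratio recovery experiment must measure a known log-HR of
0.14/y to within ±0.03 on the HR scale at n = 5000.  With the default
outcome configuration (onset 40 y, baseline rates of a few per mille),
left truncation at the imaging age leaves only ~350 incident events, and
the HR sampling SD (~0.017) exceeds that band.  The recovery condition
therefore uses a late-onset (60 y), high-incidence (0.15/y baseline)
outcome and a wider PAG spread (SD 4 y), yielding ~1000 events and an HR
sampling SD of ~0.012 — a pre-registered power calculation, not a fit to
observed results.  Null calibration (log-HR 0) checks 95% Wald CI coverage
over 100 replicates at n = 2000.

## Explainability

Grad-CAM for the regression output: channel weights are the spatial means
of ∂mu/∂A at a chosen residual block (the last by default; the target is
the age output, not the uncertainty), the weighted activation sum is
rectified, upsampled to the input grid (trilinear in 3D, nearest for the
2D fundus path) and min-max scaled to [0, 1]; an all-zero map (vanished
gradients) is flagged rather than rescaled.  Because the generator knows
where the age signal lives, localization is scored as the fraction of
top-decile activation voxels inside the dilated dark-cavity region; a
uniform map scores at the region's volume fraction, so the ratio of score
to volume fraction measures enrichment over chance.

## Numerical and reproducibility choices

- All randomness flows from explicit integer seeds; the pipeline derives
  per-stage seeds from one root seed via `SeedSequence`, and reruns with
  the same configuration are bit-identical for CSV/JSON outputs.
- Network arithmetic is float32; gradient accumulation sums in float64
  where cheap.  The LP and Cox solvers are deterministic.
- Degenerate inputs fail loudly and specifically: empty masks are QC
  failures, non-finite intensities data errors, rank-deficient bias
  designs name the collinear columns, all-equal PAGs make θ invalid, and
  Cox separation surfaces as a flagged non-convergence.
- QC of segmentation volumes is formalized as a robust z-score
  (|v − median| > k · 1.4826 · MAD, default k = 5); with MAD = 0 any
  deviation from the median is flagged, and an infinite k flags nothing.
- Crop margin defaults to 4 voxels per side; boxes are clipped at the grid
  edge and never discard mask voxels.  Min-max intensity normalization is
  per image; resampling is linear for intensities and nearest for masks.

## Problem sizes

Experiments are sized for a single CPU: the full-chain experiment uses 500
phantoms at 32³ with 20 training epochs; coefficient recovery uses
n = 2000; hazard-ratio recovery n = 5000; stratification calibration
n = 10⁴; the pipeline's default desk configuration trains three organs at
n = 150 for 8 epochs.  Population-scale regimes (tens of thousands of subjects,
hundreds of epochs) are configuration presets away but are not exercised
by the tests.

## Known limitations

- The predicted sigma is trained and reported but not used by any
  downstream statistic, mirroring its role in the analysis this package
  re-creates.
- The phantom aging signal is a single monotone geometric feature; real
  organ aging is diffuse and multi-factorial, so absolute MAE/r values here
  say nothing about clinical performance.
- The exponential (constant-rate) hazard was chosen over Gompertz for
  closed-form sampling; Cox estimation is baseline-agnostic, so recovery
  results transfer, but absolute incidence curves are not demographic.
- At the default desk scale (n = 150) the survival stage frequently has
  too few events for stable fits; it records the degeneracy instead of a
  hazard ratio.  Survival validation happens in the dedicated n ≥ 2000
  experiments.
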