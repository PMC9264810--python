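# Methods

`sersdisc` implements a chemometric workflow for discriminating
prostate-cancer patients from healthy controls using surface-enhanced
Raman (SERS) spectra of blood plasma and serum, together with a
synthetic cohort generator that emulates the structure of such spectra
so the entire workflow can be exercised and validated without access to
clinical data.

## The classification problem

Each observation is one sample's SERS spectrum: intensities on a
wavenumber grid (350–2200 cm⁻¹ at 1 cm⁻¹ spacing after alignment),
labeled *control* or *patient* and tagged with the specimen type
(*plasma* or *serum*). Cohorts are small (tens of samples) while spectra
are high-dimensional (1851 channels), so classification goes through
dimensionality reduction first, and all performance claims rest on
leave-one-out cross-validation (LOOCV). The patient class is the
positive class throughout, so sensitivity is the detection rate among
patients and specificity the correct-rejection rate among controls.

## Preprocessing

1. **Alignment** — linear interpolation onto the common uniform grid.
   Linear is the minimal-assumption choice at 1 cm⁻¹ sampling of
   2 cm⁻¹-resolution instrument data; it is exact for locally affine
   intensity profiles.
2. **Standard normal variate (SNV)** — each spectrum is shifted to zero
   mean and scaled to unit standard deviation, removing per-spectrum
   multiplicative scatter and additive offset. The sample standard
   deviation (denominator n−1) is used; the population convention
   differs by a vanishing factor at p = 1851 and is available as a
   switch. SNV feeds the multivariate analysis.
3. **Area normalization** — division by the trapezoidal integral over
   350–2200 cm⁻¹; used for figure-style mean spectra (unit area), not
   for classification.
4. **Baseline correction (optional, default off)** — asymmetric least
   squares: a second-difference-penalized smoother (penalty weight
   `lam`, default 1e5) with asymmetric weights (`p_asym`, default 0.01,
   on points above the current baseline), reweighted 10 times. Constants
   and slow ramps lie in the smoother's null space; narrow Raman bands
   survive. Off by default because input spectra are assumed already
   background-corrected by the acquisition software; the operation is
   provided for spectra that are not.
5. **Band restriction** — closed intervals, endpoints inclusive. Named
   presets: `full` (350–2200), `amide` (1200–1700, the protein-band
   window), `conclusions` (825–1050 ∪ 1506–1750, the two windows found
   most informative).

The pipeline order is resample → (baseline) → SNV → restrict; each step
appends a parameter record to the dataset's provenance list.

## Multivariate models

All chemometric fits are implemented from first principles in this
package and are deterministic given the input matrix; scikit-learn
appears only as an independent cross-check in the test suite.

**PCA** is computed by SVD of the column-centered matrix (numerically
preferable to an eigendecomposition of the covariance). Explained
variance ratios are σ²ₖ/Σσ²ᵢ. Component signs follow a fixed convention
(largest-magnitude loading entry positive). Two components are the
default everywhere — the robust small-sample choice — overridable in
config.

**LDA** (two-class Fisher discriminant) on the projected scores:
direction **d** = (S_w + λI)⁻¹(μ₊ − μ₋) with S_w the pooled within-class
scatter; λ defaults to 1e−8·tr(S_w)/d, just enough to survive degenerate
cross-validation folds. The threshold is the equal-posterior point of
the two projected class-conditional Gaussians with shared pooled
variance and empirical priors. Ties on the boundary go to the
larger-prior class, and to the negative (control) class at equal priors.
With a singleton training class (possible in small LOOCV folds) the
scatter contribution of that class is zero and the ridge keeps the solve
well-posed; in 1-D with equal priors the rule degenerates to the
two-means midpoint.

**PLS-DA** is PLS1 (NIPALS) regression of the centered {0, 1} class
indicator on centered X, two components by default: per component,
weight w ∝ Xᵀy, score t = Xw, loadings p = Xᵀt/tᵀt and q = yᵀt/tᵀt,
rank-one deflation of X and y. The regression vector is
B = W(PᵀW)⁻¹q. Classification cuts the predicted indicator at 0.5 (the
coding midpoint), ties to control; the ±1 coding differs only by an
affine map. **VIP scores** use the Wold formula
VIP_j = √(p·Σₐ SSYₐ(w_ja/‖wₐ‖)² / Σₐ SSYₐ) with SSYₐ the y-variance
explained by component a; squared scores average to one, and VIP > 1 is
the conventional importance cut.

**Linear SVM** solves the exact soft-margin dual
(0 ≤ α ≤ C, Σαᵢyᵢ = 0) by sequential minimal optimization with
maximal-violating-pair selection, KKT tolerance 1e−8, iteration cap
100 000. C defaults to 1. The intercept is averaged over free support
vectors. `pca_svm` applies it to 2-D PCA scores; `svm_raw` to the raw
spectra.

## Validation

**LOOCV** refits the *entire* chain — projection and discriminant — on
the n−1 retained samples of every fold before predicting the held-out
one, so no column mean, scatter matrix or PLS weight ever sees the
held-out row. This is enforced by construction and asserted by a test
that plants an extreme outlier and verifies the fold models that hold it
out are bit-for-bit those fit on the clean data. A config switch
(`cv.refit_projection: false`) reproduces the laxer
fit-projection-once-then-cross-validate variant for sensitivity
analysis; the mode is stamped into every report.

Confusion counts (patient positive) produce accuracy, precision,
sensitivity and specificity as exact rationals; rounding (half-up, one
decimal) happens only at presentation. Ratios with zero denominator are
reported as explicitly unavailable, never as 0.

The **train-test gap diagnostic** reports mean training-fold accuracy
against LOOCV accuracy across component counts: with 2 components the
two are close; with many components the training accuracy rises while
LOOCV does not follow — the package's overfitting check for
small-cohort chemometrics.

## Univariate analysis

At every wavenumber a two-sided two-sample t-test compares patient and
control intensities — Welch by default (unequal variances and unequal
cohort sizes), Student's pooled variant available. Columns with zero
variance in both groups get p = 1 and a diagnostic flag. The
Benjamini–Hochberg step-up rule at FDR 5% controls the expected false
discovery proportion across the grid. Per-wavenumber AUROC uses the
Mann–Whitney rank identity with midranks for ties. Significant
contiguous runs shorter than 3 grid nodes are discarded as single-node
artifacts before bands are reported. Mean-spectrum summaries mark local
maxima with prominence ≥ 2% of the spectrum's dynamic range; peaks of
class-wise and grouped means can differ slightly and all are reported.

## The synthetic cohort generator

Each synthetic spectrum is a sum of Lorentzian lines (HWHM 8 cm⁻¹ —
natural for Raman bands and wide enough that the closest listed band
pairs still resolve), plus a slowly varying degree-3 Chebyshev baseline,
all multiplied by a per-spectrum lognormal gain, with white detector
noise added per channel:

    x_i(w) = e^{N(0,s)} · [ Σ_k a_ik L_k(w; c_k + δ_i) + b_i(w) ] + ε_i(w)

with per-band amplitudes a_ik = A_k · f_k^{[i is patient]} ·
e^{N(0,cv)}, a shared per-spectrum wavenumber jitter δ_i ~ N(0, 1 cm⁻¹),
and ε ~ N(0, 0.02) (2% of the strongest band amplitude). The baseline is
`baseline_amp` (0.2) times a *fixed* characteristic Chebyshev shape with
per-spectrum coefficient perturbations of sd 0.05: background-corrected
spectra share a residual background shape, and only its small
sample-to-sample variation — not the shape itself — should compete with
the class signal. All randomness derives from the single cohort seed via
`numpy.random.SeedSequence.spawn`, one child stream per noise source in
a fixed order, so a seed determines the dataset bit-for-bit.

The **plasma preset** has 20 bands (390–1662 cm⁻¹) with the strongest at
642, 1136 and 1662 cm⁻¹; bands at 1256, 1336, 1508, 1617 and 1662 cm⁻¹
are more intense in controls (f = 0.77) and 1010 and 1209 cm⁻¹ in
patients (f = 1.3); 14 controls vs 27 patients. The **serum preset**
(14 vs 29) moves the band positions to their serum values, makes 498,
642, 815, 893, 1010, 1137, 1210, 1368 and 1412 cm⁻¹ patient-up and 728,
1331, 1447, 1511, 1582 and 1660 cm⁻¹ control-up, and adds a band at
1099 cm⁻¹ present only in patient spectra (a multiplicative effect
cannot express exact absence, so patient-only bands carry a flag;
reported band lists are internally inconsistent about whether this band
is patient-only or control-up, and the patient-only reading is
followed). Effect magnitudes 1.3/0.77 put the default PCA-LDA pipeline
in the ≥ 90% LOOCV accuracy regime at default noise, mirroring the
published operating point without claiming to reproduce it. A `null`
variant forces every f to 1 and drops patient-only bands, giving the
exact ground truth for FDR and null-accuracy experiments;
`scale_class_effects` scales every log-effect for effect-size sweeps.

**What the generator does not emulate:** real SERS enhancement physics,
substrate heterogeneity, analyte-competition artifacts, correlated
biochemical co-variation between bands, cosmic-ray spikes, or
instrument drift. Passing tests therefore demonstrate that the
*statistical machinery* behaves correctly on data with the documented
structure — not that the published clinical accuracies would replicate,
which would require the original spectra.

## Numerical choices and degenerate inputs

- PCA rank tolerance 1e−10 relative to the leading singular value;
  requesting components beyond the numerical rank raises a rank error.
- NIPALS tolerance 1e−10, cap 500 iterations (the univariate-y inner
  loop converges in one pass; the cap covers the general contract).
- SNV refuses constant spectra, area normalization refuses non-positive
  areas; both name the offending sample.
- Zero-variance test columns get p = 1 (flagged) rather than NaN; a
  zero-variance column with distinct group means is treated as the
  separation limit (p = 0).
- Metrics are exact `Fraction`s; percentage rendering is decimal
  half-up at one decimal place.
- Provenance records carry no timestamps, so identical (input digest,
  config, seed) runs produce byte-identical outputs.

## Problem sizes used in the validation suite

The suite validates statistical behaviour at the study's own scale:
cohorts of 41/43 spectra × 1851 channels; FDR control over 200 null
replicates of 500 channels; planted-effect recovery and the overfitting
diagnostic over 25 generator seeds each; oracle-equivalence checks on
random 12×8 and 20×100 matrices. The "moderate effect" regime of the
overfitting diagnostic scales the preset log-effects by 0.4 and doubles
the additive noise — chosen once so that two components neither saturate
nor fail, which is the regime in which the diagnostic is informative.

## Known limitations

- Only two-class problems; no multi-class extension.
- Only the linear SVM kernel; no hyperparameter search (C fixed at 1).
- BH assumes the usual positive-dependence conditions; spectra columns
  are strongly locally correlated, which BH tolerates but does not
  exploit.
- The generator's band-amplitude variability is independent across
  bands; real biofluid spectra co-vary biochemically.
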