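# Methods

This note records the models the package implements, the defaults it
chooses where the underlying protocol leaves a decision open, what the
synthetic generator does and does not emulate, and the numerical choices
that make results reproducible.

## Imaging models

**Saturation-recovery T1.** The forward model is the ideal two-parameter
saturation recovery, `S(TI) = S0·(1 − exp(−TI/T1))`, fitted per voxel by
bounded nonlinear least squares (trust-region reflective, analytic
Jacobian). Turbo-FLASH readouts perturb this ideal curve slightly; no
readout-correction term is applied, so the package estimates an *apparent*
saturation-recovery T1. Defaults: initial T1 = 1000 ms, initial S0 = the
voxel's maximum signal, bounds T1 ∈ [10, 10000] ms, parameter tolerance
1e-10, at most 200 iterations. Voxels whose peak signal is below 5% of the
volume's 99th-percentile signal are not fitted (air/background); voxels
that fail to converge or land within 0.1% of a T1 bound are marked invalid
— a flat (non-recovering) signal pins T1 against a bound and is therefore
rejected rather than reported.

**ADC.** Mono-exponential decay `S(b) = S0·exp(−b·D)` over the acquired
b-values (default: all seven, 0–1000 s/mm²; a subset is a config option
because scanner implementations differ on this point). The estimator is
linear least squares on log-signal weighted by the squared signal, which
makes the log-domain fit first-order equivalent to nonlinear least squares
in the signal domain; the package carries a direct nonlinear fitter purely
as a cross-check, and the two agree to well under 1% at SNR ≥ 30. Voxels
with any nonpositive signal at a fitted b-value are masked, not clipped —
clipping before a log transform biases D upward. Noise-driven negative
estimates are masked rather than zeroed. Output unit is 10⁻⁶ mm²/s.

**DCE conversion and iAUC60.** Dynamic signal is converted to gadolinium
concentration through the spoiled gradient-echo steady-state equation with
per-voxel M0 calibrated from the mean of the pre-injection baseline frames
(default 10) and the voxel's baseline T1. The inversion for
`E1 = exp(−TR/T1)` is a closed-form monotone rational expression, so the
conversion is exact to floating point; frames whose signal exceeds the SPGR
ceiling (E1 outside (0, 1]) invalidate the voxel. Relaxivity defaults to
r1 = 5.0 L·mmol⁻¹·s⁻¹, a literature value for gadobutrol at 1.5 T, and is
configurable since it is a property of agent and field strength, not of
the data. T2* attenuation is neglected (TE = 0.81 ms). The linearised
"signal change ∝ concentration" approximation holds to 2% only below about
0.05 mM at these sequence settings; the package therefore always uses the
exact inversion.

iAUC60 is the trapezoidal integral of C(t) over exactly 60 s from bolus
arrival, the final partial sampling interval handled by linear
interpolation. "60 s after injection" is not self-defining on sampled
data, so arrival is operationalised as the first frame at which the
baseline-subtracted concentration exceeds max(3× baseline SD, 1e-6 mM) for
two consecutive frames, detected once on the mean ROI curve and applied to
all voxels (per-voxel detection and a fixed frame index are options). At
1.75 s sampling the trapezoid is within 0.1% of a 1 ms reference integral
for realistic gamma-variate curves; the arrival quantisation (at most one
frame) contributes up to ~1.5% for curves with substantial late
enhancement, visible in end-to-end comparisons against fine-grid truth.

## ROI handling

ROIs are drawn on the anatomical grid and moved to functional grids by
nearest-neighbour resampling under a corner-aligned shared-frame
assumption (an optional rigid offset stands in for manual landmark
realignment, which cannot be automated from a protocol description).
Erosion is one pixel, in-plane only, with a 3×3 4-connected cross — the
minimal reading of "eroded in-plane by one pixel"; a square element would
also remove diagonal neighbours. Summaries (median, 25th/75th percentiles,
type-7 linear-interpolation convention) are computed on the eroded mask to
suppress partial-volume edge voxels; tumour volume is voxel count × voxel
volume on the *uneroded* outline, since the outline, not the eroded core,
is the tumour. Whether reported volumes precede or follow erosion is
genuinely ambiguous in the source protocol; this choice is fixed here and
flagged.

## Hypoxia score

Scores are computed in ΔCt (log2) space:
`HS = median_g[−(Ct_g − mean(Ct_controls))]` over the 24 signature genes,
with the arithmetic mean of control Ct equal to the log of the
geometric-mean control expression. A linear-space variant (2^HS) is a
flag; the two orderings agree (monotone transform) but the values differ,
and ΔCt space is the qPCR convention. Undetermined wells default to
imputation at cycle 40 (configurable exclusion); samples missing a control
gene are skipped with a warning; a sample needs at least half the
signature measured for a defined score. Gene identities are configuration
(a panel file) — the shipped `HYP01…HYP24`/`CTRL1–2` panel is a synthetic
placeholder for testing, not the assay's gene list.

## Cohort statistics

Visit comparisons use the Wilcoxon signed-rank test on per-patient
medians, zero differences dropped (classic convention; Pratt handling is a
flag), exact null distribution up to n = 25 when tie-free, tie-corrected
normal approximation otherwise. Group comparisons (CAIX± stratification)
use Mann–Whitney U, exact up to combined n = 20. Pearson correlations get
two-sided p-values from `t = r·√((n−2)/(1−r²))` on n−2 df. All tests are
two-sided and intentionally uncorrected for multiplicity — the layer
reproduces an exploratory feasibility analysis, and a correction would
change its meaning. At the study's sample sizes the exact discrete tests
have attainable size ≈ 0.042 (n = 12 signed-rank) and ≈ 0.041 (6 v 6 U
test) at nominal 0.05, which the acceptance suite verifies by simulation.

## Synthetic data

Phantoms are nested ellipsoids on an otherwise empty grid, each
compartment carrying a true T1, ADC, signal amplitude and a gamma-variate
enhancement curve `C(t) = A·(τ/αβ)^α·e^(α−τ/β)` (peak A at τ = αβ). A
gamma variate is the simplest family with a realistic wash-in/wash-out
shape; since the pipeline's only dynamic readout is a 60 s integral, no
tracer-kinetic (AIF-convolved) model is needed. Acquisition tags default
to the trial protocol: TI = {37, 100, 250, 1000, 2500, 3900} ms,
b = {0, 50, 100, 150, 200, 500, 1000} s/mm², 150 dynamics at 1.75 s, flip
angles 12°/16°, dynamic TE/TR 0.81/2.63 ms. Noise is Gaussian or Rician
(magnitude of signal plus complex Gaussian); everything is bit-reproducible
under a fixed seed, with the visit index salting only the noise stream.

Cohorts are drawn at summary level from a Gaussian copula: latent
standard-normal patient vectors with a target correlation matrix over
(T1, ADC, iAUC60, CD31, Ki67, HIF, HS), mapped affinely to physiologic
means and SDs — affine marginals preserve the target Pearson correlations
exactly in expectation. The default target matrix embeds the three strong
associations the study design is built around (iAUC60–HS −0.64, ADC–HS
+0.63, ADC–Ki67 −0.66) exactly; a matrix with only those cells and zeros
elsewhere is not positive semi-definite, so the unspecified cross-cells
among those four variables are filled with Markov-tree path products
(iAUC60—HS—ADC—Ki67), the minimal completion that restores positive
definiteness (min eigenvalue 0.25). Visit effects are multiplicative and
deterministic per patient: T1 ×0.85 at visit 2 and ×0.95 at visit 3, ADC
×0.80 at visit 3 — a *reduction*, following the study's Results section;
its Discussion states the opposite direction for ADC, and the flag to flip
the multiplier above 1 exists for exactly that reason. By default
round(0.25·n) patients lack visit 3 (mirroring 9-of-12 completion) and the
top half of patients by latent HS are CAIX-positive (CAIX is a hypoxia
marker). Ct tables place signature genes at
`Ct_g = mean(control Ct) − (HS + offset_g) + noise` with per-gene offsets
symmetric about zero, so at zero cycle noise the computed score equals the
latent HS exactly.

What the generator does **not** emulate: anatomy (tumours are ellipsoids
in air, with no surrounding tissue), EPI distortion, motion, B1
inhomogeneity, partial-volume mixing at compartment boundaries, inter-rater
outlining variability, or non-Gaussian marginals in the cohort copula.
Passing tests therefore demonstrate correctness of the estimators and
statistics under the stated forward models and noise — not robustness to
acquisition artefacts that only real data contain.

## Problem sizes and runtimes

Default full-size phantoms are 64×64×20 at roughly the limb field of view;
tests and the acceptance script use 16×16×6 to 48×48×8 grids and cohorts
of 12 patients (image level) or 10⁴ patients (summary level), sizes at
which the whole suite and the acceptance script each complete in a few
minutes on one CPU. Monte-Carlo checks use 500 voxels per compartment for
noisy T1 recovery, 300 replicates for the ADC estimator comparison and 10⁴
replicates for the rank-test null calibration.

## Known limitations

* The T1 model omits the turbo-FLASH readout correction; estimates on real
  turbo-FLASH data would carry a sequence-dependent bias that cancels in
  within-patient comparisons but not in absolute values.
* Bolus arrival quantisation to the 1.75 s frame grid biases iAUC60 by up
  to ~1.5% for late-washout curves; it is common-mode across patients by
  construction and so does not perturb cohort correlations.
* Exact rank tests assume tie-free data; tied data fall back to the
  corrected normal approximation even at small n.
* The nearest-neighbour ROI transfer assumes co-registered frames; there is
  no registration or distortion correction.
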