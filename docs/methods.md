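# Methods

This note documents the models, conventions and design choices behind
`fgscontrast`, in the spirit of a package methods appendix: what is
computed, under which assumptions, and where the genuinely open choices
were made.

## Pipeline overview

Two cameras image the same tissue slice; pathology (H&E) provides the
ground-truth tumor mask in the reference modality's frame. The pipeline:

1. fits a similarity transform from user-picked control points and
   resamples modality B into modality A's frame;
2. computes whole-slice TBR and aCNR per modality from the tumor and
   background ROIs;
3. extracts annotated lines perpendicular to the tumor border, collapses
   each to a 1-D profile, and computes per-position TBR/aCNR, the AUC of
   aCNR over tumor positions, and the aCNR = 1 crossing with its distance
   to the pathology border;
4. computes pixel-level agreement (r², Bland–Altman, tumor/background
   overlap) on min–max-normalized paired intensities;
5. aggregates everything into a median (IQR) comparison table with paired
   Wilcoxon signed-rank p-values.

Everything is deterministic given the input files and configuration.

## Registration

The transform is a similarity (isotropic scale, rotation, translation) with
reflections disallowed — two camera views of the same physical slice cannot
be mirrored. The estimate is the closed-form least-squares (Umeyama) fit,
delegated to scikit-image's estimator behind a (row, col) coordinate
convention: 0-based, pixel centers at integer coordinates, transforms
mapping moving → fixed. Modality B is always resampled into modality A's
frame so that masks and line annotations live in a single reference frame.

Resampling uses bilinear interpolation by default (nearest is available);
out-of-frame pixels get a NaN sentinel and are excluded from every
downstream statistic, so registration cannot bias ROI means. A fitted
transform within 1e-9 px of the identity is treated as the identity:
resampling at that magnitude is numerically meaningless and would only
NaN-fill a one-pixel border. Note that bilinear resampling mildly
attenuates per-pixel noise in the moving image (adjacent-pixel averaging);
this is a property of any interpolating registration, and it is visible in
synthetic studies as a slightly higher aCNR for the registered modality.

## ROI statistics and slice metrics

ROI standard deviations are population SDs (divisor *n*): ROIs hold
thousands of pixels, the difference from the sample convention is
negligible, and the choice keeps hand-computed test oracles exact. The
detectability rule is strict: a well is detectable iff SNR > 9.5 dB, and
`snr_db` returns a flagged non-value (`None`) rather than a number when the
signal mean does not exceed the control mean. Background subtraction clips
at zero, since negative fluorescence is unphysical and residual negatives
would shift downstream min–max scaling.

## Line analysis

* **Widening/collapse.** Lines are widened to `width = 11` pixels and
  collapsed with a Gaussian-weighted mean across the width. The collapse
  sigma defaults to `width/6 ≈ 1.83 px` so the ±3σ kernel support spans the
  full width; it is configurable, since only a "Gaussian mean" is specified
  by the study design this mirrors.
* **Sampling.** Along-line samples are at 1-pixel steps with bilinear
  interpolation (exact on locally affine intensity fields); labels come
  from nearest-neighbor lookups of the pathology mask on the centerline,
  and the border position is the midpoint between the last tumor and first
  background sample. Lines must cross the border exactly once; other
  crossing counts are an error naming the count.
* **Per-line means.** The mean TBR and mean aCNR of a line average over
  *all* positions, tumor and background alike (the convention is
  configurable in principle; the restriction to tumor-only is not used).
* **AUC.** The trapezoidal integral of the aCNR profile over tumor
  positions uses a pixel-unit abscissa, so a constant aCNR of c over k
  tumor positions gives c·(k−1). Magnitudes of order 1–30 at typical line
  lengths are therefore expected.
* **Crossing rule.** With noise the aCNR profile can cross 1 many times.
  The detector takes the LAST down-crossing (>1 to ≤1, linearly
  interpolated) of the tumor-connected above-threshold run: transitions
  inside the tumor qualify, and when the run straddles the border the
  crossing is where the run ends, even a few samples into the background.
  Isolated super-threshold noise spikes deeper in the background never
  define the border. An entirely sub-threshold profile yields an absent
  crossing, which is a valid outcome that feeds the positive/negative
  crossing-agreement statistics.
* **Localization accuracy.** On synthetic step-contrast lines the crossing
  localizes the border to within one pixel pitch (median). The error is not
  monotone in contrast: at high contrast a bounded sub-pixel interpolation
  bias (≤ half a sample spacing) dominates, while in the noise-dominated
  regime near tumor aCNR ≈ 1 the error grows monotonically as contrast
  falls — the property tests probe the latter branch.

## Pixel agreement

Paired pixels are min–max-normalized per modality over in-frame pixels;
masks must be disjoint, and pixels that are sentinel in either modality are
dropped. r² is the OLS coefficient of determination of B ~ A (numerically
symmetric in the two roles). Bland–Altman differences are oriented B − A by
default (configurable, recorded in the result), with sample-SD (ddof = 1)
limits of agreement `bias ± 2σ`, the standard Bland–Altman convention — the
one place where a sample SD is used instead of the population SD of ROI
statistics. The tumor/background overlap uses an inclusive comparison at
the background maximum and, being a rank statistic, is invariant under any
strictly increasing intensity transform.

## Phantom tools

* **FWHM** is measured between half-maximum crossings located by linear
  interpolation. The above-half-max region must be a single connected run —
  multimodal profiles are an error rather than a guess — and the profile
  must fall below half max on both sides (the failing side is named).
* **Sensitivity** applies the SNR rule with a monotone cut: the reported
  detection limit is the smallest concentration that is detectable with
  every larger concentration also detectable, so a single noisy outlier
  cannot fake a limit. Suspected specular reflections are handled by
  excluding their pixels from the ROI (a quantitative stand-in for visual
  screening, which is not algorithmic).
* **Spectral correction** fits the wavelength-form Planck law with two free
  parameters (temperature, scale; gray emissivity assumed) to a calibrated
  lamp spectrum, initialized from Wien's displacement law. Fits whose
  relative RMS residual exceeds 5% are rejected as non-Planck input. The
  correction curve is the fitted black body divided by the recorded lamp
  spectrum; applied multiplicatively it undoes the instrument's spectral
  response up to a constant.

## Synthetic data: what it emulates, and what it does not

The slice generator produces a piecewise-constant elliptical-tumor scene
per modality, blurred by a modality-specific Gaussian PSF (stronger blur
standing in for the shorter wavelength's scattering), plus additive
Gaussian sensor noise; modality B optionally receives a smooth additive
autofluorescent background (Gaussian-filtered white noise with a 15 px
correlation length, scaled to a chosen amplitude) and is finally warped by
a known similarity misalignment, so the true registration transform is
exactly its inverse. Intensities are floating point end to end;
quantization to integer TIFF is an explicit optional step, keeping analytic
oracles exact.

Default intensities put the noiseless modality-A slice at TBR 1.43 with
whole-slice aCNR ≈ 0.6, and modality B at TBR 1.25 with aCNR ≈ 0.86 — the
scale of published penile-carcinoma medians for NIR/SWIR-role systems; the
autofluorescence amplitude (default 0; 2500 a.u. in the `hnscc_like_spec`
variant) reproduces the failure mode where background emission drowns the
modality-B contrast (TBR → 1, aCNR → 0). The default misalignment (scale
1.02, rotation 0.03 rad, translation (3.5, −2.5) px) is a small,
realistic inter-camera offset. Tube phantoms default to a 0.6/1.2 mm
inner/outer diameter lumen at 0.05 mm/px, area-sampled so the unblurred
profile's FWHM equals the lumen diameter exactly.

Not emulated: optical light transport (no Monte-Carlo scattering), camera
sensor models (dark current, fixed-pattern noise), 3-D tissue volumes, and
the true spatial statistics of tissue autofluorescence — the smooth-field
model is a stand-in, not a claim about tissue. Passing tests therefore
demonstrate the *estimators*' correctness and calibration on known ground
truth, not the clinical performance of any imaging system.

## Statistics

Reporting is always nonparametric — median, IQR (linear-interpolation
quartiles, the convention IQRs depend on), and the paired two-sided
Wilcoxon signed-rank test — because contrast metrics of this kind are not
normally distributed in practice; no normality pre-test is run. Zero
differences are dropped per the Wilcoxon convention; the exact null
distribution is used for n ≤ 25 and the normal approximation with
continuity correction beyond; fewer than 5 usable pairs (or all-zero
differences) yield a flagged undefined p-value rather than a number. The
0.05 significance level is reported but never used to filter output rows.
Intensity rows in the comparison table carry no p-value: raw camera units
are not comparable across systems.

## Problem sizes

The validation suite uses problem sizes chosen to make the statistical
checks sharp while staying quick: 200 seeded slices (160² px, ≥ 10⁴ pixels
per class) for Monte-Carlo parameter recovery, 500 synthetic lines for
border localization, and 2000 null simulations (n = 20) for Wilcoxon
type-I calibration. The whole suite runs in well under a minute on one CPU.

## Known limitations

* The crossing detector operates on the raw (collapsed) aCNR profile; no
  additional 1-D smoothing is applied before thresholding.
* Whole-slice background is taken as the complement of the tumor mask when
  no explicit background mask is supplied; images containing non-tissue
  area need an explicit background mask.
* The Planck fit assumes gray emissivity; strongly structured lamp spectra
  are rejected rather than modeled.
* Registration quality is limited by the user-supplied control points; no
  automatic feature matching is attempted.
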