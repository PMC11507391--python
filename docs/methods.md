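# Methods

## The estimation problem

The acid value AV (mg KOH per g oil) of an oil sample is measured
chemically by titration, `AV = 56.1·C·V/m`, where C (mol/L) and V (mL) are
the concentration and consumed volume of the KOH titrant and m (g) the oil
mass; 56.1 g/mol is the molar mass of KOH.  The package's purpose is to
predict AV without chemistry, from short-wave-infrared hyperspectral
images of the oil, by calibrating linear latent-variable models on a
cohort with known titration values.

The workflow is the standard chemometric escalation: reflectance
calibration and ROI-mean spectra → per-spectrum pretreatment →
Kennard–Stone partitioning → models on the full 512-band spectrum → models
on a few selected characteristic wavelengths → models on those wavelengths
fused with image-texture features.

## Pipeline components and their defaults

**Reflectance calibration.** `R = (raw − dark)/(white − dark)` per pixel
and band, clipped to [0, 1.05]; white/dark references are averaged over
their frame stacks first.  A band where white ≤ dark is a hard error that
names the band.

**ROI extraction.** The oil region is segmented by thresholding the mean
image over a wavelength window (Otsu's method unless a manual threshold is
given) and keeping the largest connected component.  The ROI-mean spectrum
is the per-band arithmetic mean over masked pixels; replicate scans are
averaged elementwise.

**Pretreatments.** All are per-spectrum (nothing is learned from the
calibration set) and preserve the 512-column axis: Savitzky–Golay with
window 11 and polynomial order 2 (a common NIR default; exposed as
parameters), derivatives scaled per nm, edges handled by polynomial fit so
no columns are lost; SNV with the n−1 standard deviation; min–max to
[0, 1]; "Baseline" implemented as subtraction of the per-spectrum
least-squares straight line in wavelength (the term is ambiguous in the
applied literature; linear detrend is the choice here, and a constant
offset is a special case of it).

**Kennard–Stone split.** Seeded with the globally most distant pair
(Euclidean), then greedy maximin additions; ties break to the lowest row
index, so the split is deterministic.  |calibration| = ceil(0.6·n)
reproduces the conventional 3:2 division (92/61 at n = 153).  The split is
computed once per cohort, on the spectra preprocessed the way the
selection-tier models see them (second derivative by default), and shared
by every model so all tiers compare on identical sample sets.

**Outlier screening.** Mahalanobis distance in the PCA score space
covering 95 % of variance, flagged beyond the chi-square(1−α, k) radius
with α = 0.01.  This is a generic spectral screen; it is available and
tested but not applied by default to synthetic cohorts, which are
generated clean.

**SPA.** Chains are grown from every candidate start column by repeatedly
taking the column with the largest norm after projection onto the
orthogonal complement of the chain span (computed by incremental
deflation; exact orthogonality is verified against a Gram–Schmidt oracle
in the tests).  Chains are built on the larger part of an inner
Kennard–Stone 70/30 split of the calibration set and every (start, length)
chain is scored by the RMSE of an intercepted multiple linear regression
on the held-out 30 %; the outer prediction set is never touched.  The
returned chain is the validation-RMSE minimiser.  A one-standard-error
parsimony rule was evaluated and rejected: with ~46 validation samples the
SE slack is large enough to collapse the subset to one or two wavelengths,
which cannot combine the two acid-coupled bands and measurably degrades
both recovery and prediction.

**CARS.** Per Monte-Carlo run i (default N = 50): fit a PLS model (≤ 10
components) on a random 80 % of calibration samples restricted to the
surviving variables; rank variables by |coefficient|; enforce the
exponentially decreasing retention ratio r_i = a·e^(−k·i) with a, k solved
from r_1 = 1 and r_N = 2/p (forced removal), then draw that many weighted
samples with replacement (adaptive reweighted sampling), the unique draws
surviving; record the 5-fold RMSECV of the survivors.  The surviving set
with minimum RMSECV wins.  Because each run resamples from the current
set, the variable-count trace is non-increasing by construction.

**GLCM texture.** Images at the selected wavelengths are quantised by
linear binning of the masked intensity range into 64 gray levels
(affine-invariant); co-occurrences are counted at offset d = 1 in the four
standard directions, symmetrised and normalised.  Counting is mask-aware —
both pixels of a pair must lie inside the ROI — and the ROI is eroded by
3 px first, because segmentation slop at the dish rim otherwise leaks
near-zero background pixels into the gray-level range and destroys the
features.  The four statistics f1, f2 (both in (0, 1]), f3 (entropy,
natural log — the base only rescales it) and f4 (correlation, defined as 0
when a marginal variance vanishes so constant ROIs stay finite) are
computed per direction; the feature row is wavelength-major, then
direction, then f1..f4 (64 values for 4 wavelengths).  All four directions
are fused rather than direction-averaged; averaging is available.

**PCR / PLSR.** Both mean-center X and y.  PCR takes the SVD of centered
X, A = F·Pᵀ + E with orthonormal loadings P, and regresses y on the first
f score vectors.  PLSR is NIPALS PLS1; the coefficient path for nested
component counts is computed in one pass, which the cross-validation and
CARS loops reuse.  Components are chosen by 5-fold cross-validated RMSE
with a one-standard-error rule toward smaller f (f_max = 12).  At full
rank both models reproduce ordinary least squares; NIPALS coefficients are
cross-checked against an independent SIMPLS implementation and against
scikit-learn in the tests.

**Fusion and scaling.** Fused matrices concatenate the selected-wavelength
spectral block (first) with the texture block.  Because derivative spectra
and texture features differ by orders of magnitude, fused models autoscale
columns; additionally each column is divided by the square root of its
block width (block scaling), so the handful of spectral columns and the
64+ texture columns contribute equal total variance — without this the
texture block swamps the spectral information.  Spectral-only models are
mean-centered only.

**Metrics.** Rc²/Rp² are squared Pearson correlations between measured and
predicted AV (the convention in this literature, where "R" is the
measured-vs-predicted correlation); a coefficient-of-determination mode is
available.  RMSEC/RMSEP are root mean square errors in mg/g.  Improvements
between models are reported in both conventions found in applied papers —
relative change (new−old)/old·100 and absolute percentage points
(new−old)·100 — rounded to two decimals; R²/RMSE are reported to four.

## The synthetic cohort

The generator emulates the study conditions: 153 samples, 512 bands on
870–1720 nm, AV drawn from Beta(2, 5) scaled to [0.32, 1.59] mg/g (mean
≈ 0.70 — most oils fresh, a skewed tail of rancid ones).  Per sample,

    absorbance(λ) = baseline(λ) + Σ_b (a_b + g_b·AV + ε_b) · exp(−(λ−c_b)²/2w_b²)
    reflectance(λ) = gain(λ) · 10^(−absorbance(λ)) + noise

with bands at 1115/1330/1520/1590 nm (widths 18/12/10/15 nm), AV coupling
g = 0.16 and 0.06 absorbance/(mg/g) on the 1330 nm (C–H bend) and 1520 nm
(O–H) bands only, per-band amplitude jitter ε ~ N(0, 0.012) (sample-to-
sample composition noise), a random smooth baseline, a random interferent
band at 1210 nm, and a multiplicative smooth scatter curve (sd 0.01,
correlation length 200 nm).  The 10^(−A) link is a Beer–Lambert-style
surrogate giving bounded, peak-shaped reflectance, not a radiative-
transfer claim.  Pixel noise is 0.001 reflectance units, inflated up to
40× over the outer 25 bands per edge to mimic InGaAs detector roll-off;
cohort mean-spectra carry pixel noise divided by √(ROI pixel count),
exactly what ROI averaging delivers.

Imaging scenes are 80×80 px with a centred oil disk (radius 0.35·min
side) on a near-black background.  Oil pixels carry the sample spectrum
times (1 + 0.10·field), where the texture field is smoothed white noise
normalised to zero mean/unit variance over the disk; its smoothing length
is 2.5/(1 + 2·texture_coupling·AV) px, so texture roughness increases
with AV when the coupling is on and the GLCM features carry an AV readout
that is statistically independent of the spectral channel.  Cubes are
regenerated lazily from per-sample seeds (per-band seeded noise makes a
band-subset cube exactly a slice of the full cube); storing 153 full
cubes would cost ~1 GB.

**What the generator does and does not emulate.** It reproduces the
statistical structure the analysis assumes — band positions, AV coupling,
scatter-type nuisance that derivatives remove, noisy detector edges,
AV-coupled texture — but not instrument line-spread, stray light, real oil
chemistry beyond band positions, or the dish-cropping geometry of a real
stage.  Passing tests therefore demonstrate that the pipeline recovers
known structure under realistic noise, not that any particular accuracy
will be achieved on real oils.

**Calibration of the defaults.** The noise levels were fixed once so that
the synthetic cohort reproduces the qualitative regime of the motivating
study: full-spectrum second-derivative models reach Rp² ≈ 0.80–0.85, a
handful of selected wavelengths matches or slightly beats the full
spectrum (the amplitude jitter is a common floor that extra wavelengths
cannot average away, while the noisy edges penalise the 512-band models),
and fusion lifts the median Rp² above 0.90 because the texture channel is
an independent AV readout.  The full-versus-selected gap is a small-margin
effect and can invert on individual seeds; the fused-over-both ordering is
robust.  Problem sizes used by the test-suite recovery checks: 10 cohorts
of 153 samples for the three-tier medians, 20 cohorts for planted-band
recovery (five narrow informative bands; a selector "hits" a band when it
places a wavelength within ±15 nm of its centre).

## Known limitations

- SPA's projection criterion is variance-driven and will chase
  high-variance noisy columns (e.g. detector edges); the validation-RMSE
  scoring compensates but does not eliminate this.
- The PLS implementation is univariate-y only (PLS1), which is all this
  workflow needs.
- ENVI support covers BSQ/BIL/BIP with float32/float64/uint16 and
  nm wavelengths — the common instrument export — not vendor-proprietary
  extensions.
- R² as squared Pearson correlation is blind to calibration bias (a
  predictor 2·y + 1 scores R² = 1); the coefficient-of-determination mode
  exists for that reason.
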