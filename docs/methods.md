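# Methods

This note documents the models implemented in `cyclechrome`, the defaults
chosen where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Spectral computations

All spectral quantities live on a fixed grid, 400–700 nm at 1 nm (301
samples).  Photon catches are rectangular sums on that grid; at 1 nm
resolution the difference from trapezoidal integration is far below every
perceptual threshold the pipeline applies.  Catches are left in arbitrary
linear units by default: the receptor-noise distance uses log catch ratios
and redness uses the LW/MW ratio, both invariant to common scaling.  An
optional normalization (`catch_set(..., normalize="illuminant")`) rescales
so a perfect reflector scores 1.0 per channel, for users who prefer
bounded values; no downstream statistic changes.

The bundled standard curves are generated from closed-form models by
`scripts/make_standard_curves.py` (provenance recorded in each CSV
header):

* **CIE 1931 XYZ 2°** — the multi-lobe piecewise-Gaussian fit of Wyman,
  Sloan & Shirley (2013), accurate to ~1% of peak; the fit's small
  negative lobes are clamped at zero because sensitivities are
  non-negative by contract.
* **LMS cone sensitivities** — *synthetic* stand-ins built from the
  Govardovskii et al. (2000) A1 visual-pigment nomogram at corneal peaks
  566/541/441 nm, normalized to unit maximum.  They reproduce the peak
  positions and bandwidths of measured human cone fundamentals but omit
  lens and macular-pigment filtering; any application that needs
  colorimetric-grade fundamentals should substitute measured tables via
  the two-column CSV interface.
* **D65** — PCHIP interpolation of the standard 10 nm relative-power
  tabulation (normalized to 100 at 560 nm).

Only D65 is bundled; other illuminants are accepted as input spectra.  No
chromatic-adaptation (von Kries) transform is applied anywhere.

## Camera model and image pipeline

The response of each camera channel to a grey standard of reflectance r is
modeled as `response = a·r^b + c`, a monotone power law with offset.  This
family nests a purely linear sensor (b = 1) and gamma encoding
(b ≈ 1/2.2), and on simulated and typical camera data reaches the R² >
0.999 regime expected of this calibration; a fit below that is flagged,
not rejected.  Fitting is per-channel nonlinear least squares
(scipy `curve_fit`) with b bounded to [0.05, 20].  Inversion clips raw
responses to the calibrated span with a logged count, so an isolated
specular pixel cannot poison a batch.

Grey-card standardization multiplies each channel by
0.18 / (card-region channel mean); it is exactly idempotent and makes the
card read 18% to floating precision.  Patch geometry uses 0-based pixel
indices, origin top-left, half-open rectangles; patch dimensions are
rounded half-away-from-zero to whole pixels (sub-pixel patches are not
supported, and the one-pixel ambiguity this leaves is far below the noise
of any real measurement).  Patch color is the mean of the two patch means,
not a pixel-pooled mean — the distinction only matters for unequal patch
sizes, which the geometry rules out.  RAW decoding and pupil detection are
out of scope: the pipeline ingests demosaiced 16-bit TIFF plus a CSV
sidecar of pupil and grey-card coordinates.

## Camera → cone mapping

Both sides of the training set (camera catches, target LMS or XYZ catches)
are computed from the same reflectance spectra under the same illuminant;
the map is an ordinary least-squares polynomial per target channel.  The
default basis is degree 2 in the three camera channels with all cross
terms and an intercept (10 terms); on smooth natural-like spectra this
reproduces the R² ≥ 0.999 conversion regime, and the degree is a
configuration knob for cameras or spectra that need more.  Negative
predicted catches are clamped to 10⁻⁹ of the channel's training mean with
a logged count, because a log-ratio downstream cannot absorb a zero.  The
LAB transform is the standard CIE 1976 two-branch formula with the D65 2°
white point, matching the training illuminant.

## Perceptibility models

The receptor-noise distance is implemented for a trichromat with log
(bright-light) receptor signals.  Channel noise ω can be supplied two
ways:

* `weber_direct` (default): the printed Weber triplet — 0.08:0.02:0.02
  SW:MW:LW, with 0.09:0.02:0.02 as a second reported variant — is used
  verbatim.
* `abundance_scaled`: ω_i = ω_ref·√(abundance_ref/abundance_i) with the
  most abundant channel as reference, which is how the receptor-noise
  framework propagates relative cone proportions.  The three printed cone
  proportion settings (standard 1:0.5:0.03125 SW:MW:LW, plus the reported
  human minimum 1:1:0.03125 and maximum 1:0.06:0.03125) only change
  results in this mode, so end-to-end runs report every setting side by
  side.

The SW:MW:LW ordering of those printed triplets (short-wave most abundant)
is implemented exactly as printed even though it is physiologically
surprising; any other ordering can be supplied through `NoiseModel`.
Thresholds: ΔS ≥ 1 JND is discriminable; a LAB single-axis difference
> 2.2 is noticeable.  Cycle contrasts are taken against the adjusted
day-14 color; on modeled data the reference comes from the fitted Fourier
curve (raw-observation and interpolated references are available for
external tables).  Dichromat/tetrachromat formulas and luminance-channel
JNDs are not implemented.

## Cycle-day standardization

Raw days (whole days only; photography is daily) map onto the adjusted
28-day cycle with menses onset → 1, LH surge → 14, final cycle day → 28,
advancing by 13/(lh−1) adjusted days per raw day before the surge and
14/(length−lh) after.  A closed form and the day-by-day recursion are both
implemented and agree to 10⁻¹²; full precision is kept internally and the
conventional 2-decimal rounding is applied only at presentation.
Conception risk is linear interpolation over a user-supplied integer-day
table; the package bundles **no** actuarial values — the
`placeholder_risk_table` is a smooth synthetic curve peaking near adjusted
day 12.5, for tests and demonstrations only.  Cycles without a detected LH
surge cannot be standardized and are excluded with a logged reason.

## Mixed-effects Fourier regression

The phase convention is θ = 2π(adjusted_day − 1)/28, so menses onset is
phase 0.  Any affine phase choice is equivalent up to a rotation of each
harmonic coefficient pair — the likelihood-ratio test and the effect size
are unaffected — but the convention is fixed so reported coefficients are
reproducible.  The default model uses the first two harmonic pairs; higher
orders are accepted by configuration.  Estimation is maximum likelihood
(not REML) via statsmodels MixedLM so likelihood-ratio tests of fixed
terms are valid; the optimizer tries lbfgs, then bfgs, cg and powell,
accepting the first converged fit with a finite log-likelihood.  Random
intercepts: participant, plus cycle-within-participant whenever any
participant contributes more than one cycle (with one cycle each the
component is unidentifiable against the participant intercept and is
reported as 0).  Boundary variance components are reported, not treated as
errors.  The cycle test always has 2×orders degrees of freedom regardless
of covariates (e.g. conception risk).  Residuals are assumed independent
given the intercepts; autocorrelated-residual models are out of scope.

## Synthetic data

The generator emulates the design of the motivating study: 22 naturally
cycling participants, one cycle each of 26–34 days, the LH surge 14 days
before the final cycle day (±1 day of jitter), weekday-only photography
averaging ~13 usable photos (±4).  The redness outcome (LW/MW) has
intercept 1.85, default Fourier coefficients (−0.007, 0.009, 0.004,
−0.002) — effect size ≈ 0.0087, i.e. ≈ 0.5% of the mean ratio — with
participant/cycle/residual SDs 0.06/0.02/0.03.  These values were chosen
so the simulated study reproduces the reported regime: a clearly
significant 4-df cycle test of moderate size, a LAB redness amplitude well
below 2.2 and a maximum day-14 receptor-noise contrast below 1 JND.
Luminance defaults carry a much weaker signal (effect size 0.08 against
residual SD 1.2), so its cycle test is typically non-significant.  Cone
triples are back-constructed so LW/MW reproduces the redness outcome
exactly (MW per participant ≈ 1, SW = 0.95·MW); LAB redness is a
deterministic log map of the ratio scaled so its amplitude is
sub-threshold.

Training spectra are logistic squashes of random smooth functions
(2–3 broad Gaussians of width 80–200 nm plus an optional wide sigmoid
edge), mimicking the low-dimensional smoothness of natural reflectance
collections; an optional skin bias adds the rising long-wavelength edge of
blood-perfused skin.  Synthetic cameras have Gaussian R/G/B bands near
605/535/465 nm and a power-law response with exponent ≈ 1/2.2.  Face
images are uniform skin fields with Gaussian pixel noise, an 18% grey
rectangle and pupil markers — sufficient to validate the geometry and
calibration chain, but deliberately not photorealistic: no shading,
specularity, texture, pose variation or demosaicing artifacts.  Passing
tests therefore demonstrate the correctness of the computations, not
robustness to real-photography nuisances.

Every generator is a pure function of its seed; seeded end-to-end runs
write byte-identical summaries.

## Validation choices and problem sizes

The test suite validates each operation against an independent oracle
(brute-force summation, hand-evaluated formulas, dense-grid SDs,
forward-simulation inverses) and checks the statistical machinery by
simulation: the 4-df cycle test's type-I error over 1000 null replicates
(simulated with 40 participants × ~20 photos, a size at which the
chi-square reference distribution is accurate; at the 22×13 study size the
small-sample ML test is mildly anticonservative, a known property of
likelihood-ratio tests with few clusters), and 95%-interval coverage of
the Fourier coefficients over 200 replicates at the 22×13 study size.
The cone-mapping calibration check trains on 500 synthetic spectra.

## Limitations

* The bundled LMS curves are nomogram approximations (see above).
* The external-dataset reader infers cycle boundaries from decreases in
  adjusted day when identifier columns are absent — a documented heuristic
  that treats each detected cycle as its own participant.
* Exact reproduction of a published mixed-model χ² can be
  software-sensitive in the second decimal (optimizer, convergence
  tolerances); the likelihood-ratio machinery here is validated by
  simulation rather than against any single software's output.
* Conception-risk values must be supplied by the user; the bundled table
  is synthetic.
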