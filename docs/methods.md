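# Methods

This note documents the models, parameters and numerical choices behind
`hypoxmap`, in the spirit of the methods documentation of mature scientific
packages: what is computed, under which assumptions, with which defaults,
and what the synthetic validation does and does not demonstrate.

## The measurement being modelled

A widefield mesoscale imaging rig alternates four LEDs frame by frame —
blue (475 nm) exciting a GCaMP calcium indicator, and green (535 nm),
amber (590 nm) and red (620 nm) providing reflectance — with the camera at
80 Hz, i.e. 20 Hz per color over a ~10×10 mm, 192×192 px field of view.
A 40-minute acquisition holds 10 min normoxia, 10 min hypoxia (12, 10 or
8 % inspired O2, or a pure-normoxia control) and 20 min normoxia. The
analysis chain is: co-registration → hemodynamic correction of the
fluorescence → Beer-Lambert hemodynamic signals → ∆F/F normalisation →
(GSR for maps only) → ROI time courses → statistics.

## Hemoglobin spectroscopy

Per pixel, `beer_lambert_invert` solves the linear system
−log(R_λ(t)/R_λ(0)) = D_λ(ε_HbO,λ·∆HbO + ε_HbR,λ·∆HbR) over the three
reflectance channels by ordinary least squares (pseudoinverse of the 3×2
design matrix). Choices:

- **Extinction table.** ε values are taken from the standard tabulated
  hemoglobin absorption spectra (Prahl compilation) evaluated at the LED
  center wavelengths, shipped as package defaults; each LED is treated as
  monochromatic. Differential pathlength factors default to
  D = 0.057/0.070/0.45 cm at 535/590/620 nm (longer where absorption is
  weaker) and are configurable. Forward simulation and inversion share one
  `OpticalModel`, so round-trip validation and all derived quantities
  (notably sO2, a ratio) are insensitive to the absolute calibration of
  the table. The model reports its condition number and refuses
  ill-conditioned spectra.
- **Baseline.** R_λ(0) is the per-pixel temporal mean over the first
  normoxia epoch (default minutes 0–10). A mean is robust to frame noise
  and matches the "∆ from baseline" semantics of the outputs.
- **Baselines and sO2.** HbO₀ = 60 µM, HbR₀ = 40 µM, so baseline
  sO2 = 60 % exactly; sO2 is a fraction internally and percent in
  summaries. Frames where HbT₀+∆HbT ≤ 0 are set missing. ∆HbT is defined
  as ∆HbO+∆HbR, so conservation holds to machine precision.
- **Outliers and masking.** Whole-brain statistics exclude the midline
  sinus stripe and a 5 px eroded brain margin. Trace values beyond
  3 standard deviations of the full-trace mean are excluded (single pass);
  the exclusion is applied to whole-brain mean traces, where the statistic
  is used — a per-pixel option exists but is not the default. It can be
  disabled (`outlier_exclusion=False`) when quantifying constructed traces
  whose genuine transient would be clipped as an "outlier".
- **Epoch metrics.** Plateau = mean over minutes 14.5–19.5, baseline =
  mean over 4.5–9.5, dip = minimum in a configurable window after hypoxia
  onset (default minutes 10–11, i.e. a 60 s window — the width is a
  package choice), overshoot = maximum in minutes 20–21. Group summaries
  report mean ± SEM (sd/√n over subjects).

## Hemodynamic correction and ∆F/F

`hemodynamic_correction` regresses each pixel's fluorescence trace on its
own three reflectance traces plus an intercept and keeps the residual
(plus the pixel mean). Regressors are standardised per pixel and the
system is solved with a batched minimum-norm pseudoinverse: the three
channels are driven by only two hemoglobin species and are therefore
nearly collinear, which a naive normal-equations solve handles badly;
the minimum-norm solution leaves the residual — the quantity of interest —
unchanged and degrades gracefully to an intercept-only fit for constant
regressors. Reflectance is resampled to the fluorescence timestamps by
linear interpolation. The fit window defaults to the whole acquisition; a
config option restricts fitting to normoxia epochs to avoid absorbing
hypoxia-driven covariance.

`compute_dff` uses 4th-order Butterworth filters applied forward-backward
(zero phase): F0 = low-pass < 0.3 Hz, ∆F/F = band-pass 0.3–3 Hz divided by
F0. Pixels whose F0 touches zero are masked. The band upper corner is
capped at 0.45·fps for low-rate test signals. `windowed_std` uses sample
(n−1) normalisation, centered windows, truncated (not padded) edges;
10 frames = 500 ms at 20 Hz.

## Registration

Within an acquisition every frame is registered to the first frame; across
weeks each session is registered to the subject's first acquisition. The
estimate is a 2-D affine optimised on the mean-squares metric (SimpleITK
gradient descent, linear interpolation), initialised by subpixel phase
cross-correlation; frames are resampled once through the composed
transform (bilinear; nearest-neighbour for label images). If a frame's
fitted transform fails to reduce its MSE the identity is kept with a
warning, so registration never degrades a frame. An optional smooth
displacement-field refinement (diffeomorphic demons, smoothing σ = 2 px,
30 iterations by default) handles non-rigid residuals; it is off by
default for speed and its parameters are exposed rather than asserted.

## Connectivity and statistics

Seeds are 3 px-radius lattice disks (29 pixels) at integer-rounded region
centroids, intersected with the brain mask; 8 seeds give 28 unique pairs
(12 within-macrocluster, 16 between). Pearson correlations are computed on
band-passed ∆F/F and on ∆HbO without further detrending; Fisher z uses
|r| clipped at 1−10⁻¹² so degenerate perfect correlations stay finite.
Analysis windows (hypoxia 12.5–17.5 min, normoxia 2.5–7.5 min) are
configurable; minute-based windows convert to half-open frame intervals by
flooring start·60·fps. Windows with fewer than 30 frames are rejected as
unstable. Global signal regression (per-pixel OLS on the in-mask frame
mean) is applied only when producing seed-pixel correlation maps; all
quantitative statistics run on un-regressed data. Manual gas-switch
transition periods are excluded from epoch windows by a configurable
margin (default 30 s).

The statistics module is self-contained where exactness matters:

- **Wilcoxon signed-rank**: exact for n ≤ 25 via dynamic programming over
  (doubled, tie-averaged) signed ranks — equivalent to enumerating all 2ⁿ
  sign assignments; tie-corrected normal approximation with continuity
  correction above. Exactness matters because 8-subject cohorts sit where
  the approximation is badly calibrated, and uniform-sign contrasts bottom
  out at the attainable two-sided floor 2/2⁸ = 0.0078125.
- **Benjamini–Hochberg**: the step-up formula q₍ᵢ₎ = min_{j≥i} m·p₍ⱼ₎/j.
- **Friedman**: tie-safe average-rank form referred to χ²(k−1); identical
  blocks return statistic 0, p = 1.
- **KS normality gate** (sample mean/sd estimated — the Lilliefors caveat
  is accepted deliberately, and the gate is conservative: n < 4 routes to
  the nonparametric branch), paired t and Kruskal–Wallis wrap scipy.
- Two-sided tests throughout.

With fewer than 5 subjects hypothesis tests are skipped (estimates still
reported). The longitudinal normoxia screen runs Friedman per seed pair
across ≥ 3 matched weeks with BH over the 28 pairs, then per-week
Kruskal–Wallis versus week 1 for significant pairs.

## The synthetic-data generator

The generator forward-simulates the full chain so each stage has a
recoverable target:

- **Calcium.** 8 regional ∆F/F traces as band-limited (0.3–3 Hz)
  Gaussian processes with an exchangeable two-cluster correlation
  structure: within-cluster r = 0.8, between-cluster r = 0.5 in normoxia
  dropping to 0.1 during hypoxia (the generator's default study
  condition), fluctuation sd 5 %. Independent filtered sources are
  standardised and whitened within each epoch and mixed with the Cholesky
  factor of that epoch's target matrix, so epoch-wise empirical
  correlations match the targets essentially exactly (band-limited noise
  would otherwise decorrelate too slowly for short epochs). Non-PSD
  targets fail loudly, naming the offending pair.
- **Hemodynamics.** A global epoch-driven piecewise-exponential ramp —
  HbR saturating fast (τ = 20 s) to a plateau, HbO dipping (unit-peak
  gamma-like transient) then rising slowly (τ = 150 s at 8 %), and on
  return to normoxia an exponential recovery (τ = 60 s) with an HbO
  overshoot / HbR undershoot transient — plus a local neurovascular
  component: calcium convolved with a unit-area gamma kernel (delay 1.5 s,
  FWHM 2 s; amplitude 20 µM HbO per unit ∆F/F, HbR:HbO ratio −0.4, values
  conventional for rodent widefield). Ramp amplitudes per oxygen level
  (HbR plateau 10.9/13.4/21 µM and HbO 7.8/20/28 µM at 12/10/8 %) follow
  the graded severity of the challenge; the pure-normoxia control is
  identically zero.
- **Optics and sensor.** Reflectance channels follow the Beer-Lambert
  forward model over smooth vessel-like texture fields; the fluorescence
  channel is F0·(1+∆F/F) attenuated using the mean of the excitation
  (475 nm) and emission (515 nm) extinction coefficients — the photon
  path crosses the tissue at both wavelengths, which is exactly the
  physics the regression correction targets. Frames are interleaved
  blue→green→amber→red at 4× the channel rate; all four frames of a cycle
  sample the signals at the cycle time (zero-order hold). Additive
  Gaussian sensor noise defaults to 50 counts on a 10 000-count baseline
  (~0.5 %, sCMOS-like); negative intensities are clipped at zero with a
  logged count. Optional rigid motion is a smoothed random walk applied
  per camera frame. The "GFP analog" used to validate the hemodynamic
  correction sets the neural fluorescence term to zero while keeping full
  hemodynamic contamination, and is rendered noise-free so the residual
  isolates what the regression can and cannot remove.
- **Fixtures.** Stacks are written as float32 multi-page TIFF with a YAML
  sidecar (color order, rates, timeline) and CSV ground-truth tables.
  Float32 (rather than integer counts) keeps the write→read round trip
  lossless and preserves the noiseless-inversion precision that the
  validation relies on; real uint16 data reads through the same path.

**What the synthetic validation shows — and does not.** Passing tests
demonstrate that the implementation inverts its own forward model to
stated tolerances, recovers injected motion and connectivity parameters,
and that the statistics are exact/calibrated. The generator omits vessel
anatomy, photon-level light transport, spatially varying pathlengths,
behaviour/pupil covariates and indicator nonlinearities, so agreement here
does not certify accuracy of absolute in-vivo concentrations; in-vivo
numbers also depend on recordings that are not publicly released, and are
treated as property-based targets rather than values to reproduce.

## Problem sizes and determinism

Tests and the acceptance script run desk-scale configurations chosen as
the package's own validation sizes: 16–96 px frames, 2–6 minute
acquisitions with the 1:1:2 epoch split for image-level stages, and
full-length (40 min) trace-level simulations where the analysis windows
(minutes 12.5–17.5 / 2.5–7.5 / 14.5–19.5) must exist. Every stochastic
component draws from `numpy.random.default_rng` seeded from the scenario
or run configuration, so identical configurations reproduce bit-identical
stacks and CSV checksums.

## Known limitations

- The 3-channel system is near-collinear (two chromophores); per-channel
  gain drift that is not common-mode biases ∆HbO/∆HbR (though not sO2's
  invariance to common gain).
- The diffeomorphic refinement is a generic demons field; its parameters
  are exposed, not tuned to any particular tissue deformation model.
- The KS normality gate with estimated parameters is conservative; it
  routes borderline cohorts to the nonparametric branch.
- Blood-flow (speckle) measurements, graph metrics and ICA-style network
  discovery are out of scope.
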