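# Methods

## The detection pipeline

Per camera sequence the pipeline is:

1. **Scene model.** The background is a pixel-wise weighted average of a
   window of frames (default 50). The default weights rise linearly from
   the earliest to the latest frame of the window, so the model leans
   toward the most recent illumination; a `uniform` scheme (plain mean) is
   available. The window is leading by default — appropriate when
   acquisition starts before flies arrive — with a rolling mode
   (`rolling_backgrounds`) for scenes whose illumination drifts throughout.
   Numerically the weighted sum is anchored at the window's first frame
   (`f0 + Σ wᵢ(fᵢ − f0)`), so a perfectly static scene yields an exactly
   zero residual rather than ~1e−14 float residue; this matters because
   the later 8-bit conversion stretches whatever range the difference
   image has.
2. **Difference imaging.** Per frame, the absolute difference from the
   scene model. Absolute-valued so that objects darker or lighter than the
   background both survive; flies on pale trap cardboard are dark, but the
   sign-free form is robust to local texture.
3. **8-bit conversion.** The difference image's [min, max] is rescaled
   linearly onto [0, 255] with half-up rounding; a constant image maps to
   zero. Conversion of the difference image is the default; a
   `convert_source="raw"` toggle instead converts the raw frames before
   subtraction, since the original macro's order of operations admits both
   readings.
4. **Thresholding.** Otsu's criterion (maximising between-class variance)
   on the 8-bit image by default — deterministic and parameter-free — with
   a fixed-threshold override. Foreground is `image >= t`. A constant
   image has no two-class split: it returns an empty mask flagged
   `degenerate`, never an exception (a frame with no motion thus counts
   zero flies).
5. **Blobbing.** One binary opening then one closing with a 3×3 square
   element (radius 1). The opening deletes sub-element specks, the closing
   bridges 1-px gaps so a single fly does not split into several
   particles. The element is the smallest nontrivial choice and matches
   common particle-analysis practice.
6. **Particle analysis.** 8-connected component labelling, intersected
   with an optional rectangular region of interest, with an inclusive area
   gate of 150–950 px by default — the empirical size range of a fly at
   this imaging geometry. Each accepted component becomes a detection
   record (centroid, area, half-open bounding box, 0-based origin
   top-left). No identity tracking is attempted: a fly sitting through k
   frames is counted k times, exactly as per-image counting does.

## The simulator

`generate_image_sequence` emulates one camera watching one trap surface:

- **Background:** a fixed smooth random field (Gaussian-filtered white
  noise, σ = 25 px, amplitude ±12 around level 200) — bright, textured,
  static. It exercises background subtraction nontrivially without
  photorealism.
- **Flies:** filled dark ellipses (intensity −120 against the local
  background), aspect ratio uniform in [1, 2.5], random orientation. The
  rasterised pixel count is tuned by bisection on the axis scale to hit a
  requested target area within ±2 px. Target areas are sampled from the
  interior of the configured area range (margin 25 px by default) so the
  *segmented* area — after rasterisation and the 3×3 open/close — still
  falls inside the detection gate; blobs are placed with a minimum
  separation so two flies never merge into one particle. Flies are
  stationary for their lifetime.
- **Dynamics:** an independent per-frame birth–death chain. Each present
  fly departs with probability `departure_rate`; at most one new fly
  arrives per frame with probability `arrival_rate`. The stationary mean
  occupancy is arrival/departure, so treatment-dependent mean sighting
  rates are set by the rate ratio. Defaults (0.05/0.05, mean one fly) suit
  a moderately attractive surface; the qualitative ordering between
  treatments — lure-only busiest on internal panels, insecticide
  intermediate, control near zero — is configured per surface by the
  caller, since per-frame occupancy distributions are not measurable from
  capture counts alone.
- **Acquisition defaults:** 640×480 8-bit frames, 6 s cadence. A warmup
  period with no arrivals (default 50 frames, equal to the background
  window) precedes the dynamics, mirroring acquisition that starts before
  flies are released; it guarantees the leading-window scene model is
  fly-free, which the exact-recovery property relies on.
- **Noise and drift:** i.i.d. Gaussian pixel noise (`noise_sd`) and a
  global linear illumination ramp (`drift_amplitude` over the whole
  sequence), both zero by default. Frames are rounded and clipped to
  uint8, so with zero noise and drift each frame is an exact function of
  the ground truth.

What the simulator does **not** model: fly morphology (wings, legs),
walking or flight blur, shadows, specular highlights, weather, or 3-D trap
geometry. Passing tests on synthetic data therefore demonstrate the
pipeline's correctness (segmentation, gating, counting, statistics), not
its accuracy on real imagery — on real sequences, validation against
manual counts (the `validation` module) remains necessary.

`generate_capture_table` draws per-replicate trapped and in-tub counts
from a negative binomial (gamma–Poisson mixture) with per-treatment means
and a common dispersion (default 5): replicate-level capture counts are
strongly overdispersed relative to Poisson, with in-tub variance far above
its mean. Totals are trapped + in-tub by construction, and the Poisson
limit is recovered as dispersion → ∞.

## Statistics

- **Transform:** counts are analysed as ln(x + 1). The +1 offset admits
  zeros (in-tub counts of 0 occur) and is the variant under which the
  treatment comparisons on the bundled dataset are internally consistent;
  F statistics are invariant to the logarithm's base.
- **Summaries:** sample SDs use the n−1 denominator; report output is
  rounded to one decimal, with unrounded values retained.
- **One-way ANOVA:** explicit between/within decomposition; F with
  (1, n₁+n₂−2) df equals the squared pooled two-sample t (asserted to
  1e−10 in tests). Zero residual variance yields an infinite F flag, not
  an exception.
- **Two-way ANOVA:** ordinary least squares with full interaction via
  statsmodels. Sequential (Type I) sums of squares on balanced designs,
  where they conserve total SS exactly; a Type II flag handles unbalanced
  data such as missing camera-days, and achieved degrees of freedom are
  reported rather than forced to the nominal design.
- **Fisher LSD:** LSD = t(1−α/2, residual df)·√(2·MSE/n), pairs flagged
  when |mean difference| > LSD, deliberately unadjusted for multiplicity
  (the LSD convention). For two groups this reproduces the unadjusted
  pooled t-test decision.
- **KS normality:** D = sup|ECDF − Φ((x−μ̂)/σ̂)| with the p-value from the
  asymptotic Kolmogorov distribution, no small-sample or
  estimated-parameter correction. The reference mean and SD default to
  sample estimates but can be passed explicitly (the analytic
  quantile-sample identity D = 0.5/n only holds for the generating
  parameters).
- α = 0.05 throughout, except correlation-significance statements at
  0.001; p-values are reported, never optimised.

## Problem sizes and tolerances

Test and acceptance runs use 500-frame sequences at the full 640×480
geometry for end-to-end recovery (noiseless: exact; noise SD 4: ≥ 95%
frame agreement), 200 random 32×32 masks for the labelling oracle,
10,000-step occupancy chains against a numerically iterated
transition-matrix oracle (3 SE band with an autocorrelation-corrected
standard error), and 1,000 simulated null capture tables for the type-I
error of the treatment ANOVA (2 Monte-Carlo SE band around α). Oracle
equivalences are exact or at 1e−8…1e−12 as stated in the tests.

## Known limitations

- Otsu thresholding assumes a bimodal difference histogram; frames with
  many flies of varying contrast can shift the threshold. The fixed
  threshold override exists for such scenes.
- The per-frame counter does not deduplicate multiple sightings of one
  individual across frames; sighting counts and capture counts are
  therefore different observables and are analysed separately.
- The rolling background mode recomputes a full window per frame (O(window)
  per frame); for long drifting sequences an incremental update would be
  preferable.
- The simulator's blobs never touch; real trap surfaces show clustered
  flies, which the area gate would merge or reject. Counting accuracy
  under clustering is not claimed.
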