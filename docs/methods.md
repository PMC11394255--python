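# Methods

## The clock-sweep statistic

The cue reduces a lesion to a one-dimensional angular brightness profile.
Angles follow the clock-face convention: 0 at 12 o'clock (image-up),
increasing clockwise, so π/2 is 3 o'clock. For each of `n_angles`
(default 360) uniformly spaced angles, the arm from the lesion centroid to
the margin radius is sampled at uniformly spaced points (endpoints
included; per-arm sample count `max(32, ceil(margin_radius))`) with
bilinear interpolation, and m(θ) is the mean of those samples. "Brightness
on a clock arm as a function of angle" admits several readings (margin
pixel only, arm mean, arm integral); the arm mean is used because it is
the simplest angle-indexed brightness functional, and the choice is
validated on synthetic ground truth only — no reference image with a
known printed value is available for a desk check.

The summary is Δ/mean with Δ = max m − min m and mean the arithmetic mean
of m over the uniform angle grid. The denominator is deliberately the
*profile* mean rather than the whole-lesion mean so the statistic is a
function of the profile alone; `sweep_statistic(..., mean_intensity=...)`
accepts the whole-lesion mean for the alternative convention. The
statistic is invariant under global intensity scaling and under image
rotation (exactly for multiples of the angular step).

Hand angles: darkest = argmin m, brightest = argmax m, ties broken toward
the smallest angle (closest to noon going clockwise) for determinism. The
max-variation hand is the argmax of the magnitude of the circular central
difference of m after a circular moving-average smoothing (odd window,
default 5 samples) that keeps the hand from locking onto single-pixel
noise. "Variation" is not defined more precisely by the cue's published
description; the smoothed derivative is this package's reading.

## Segmentation

The lesion is taken darker than the surrounding skin (typical pigmented
lesion contrast). Grayscale conversion uses Rec. 601 luminance. The
threshold is Otsu's criterion with one refinement: when the histogram has
an empty gap between the lesion and background modes, every split inside
the gap maximises the between-class variance equally, and the plateau's
*midpoint* is used. (The plateau's left edge — what a bin-by-bin argmax
returns — can sit one histogram bin inside the darker mode and shave off
the brightest lesion sector; the midpoint is threshold-stable for both
noisy and noise-free images.) The largest 4-connected below-threshold
component is kept, holes filled, and the centroid is the binary (not
intensity-weighted) centroid.

The margin radius at each angle is the *last* crossing out of the mask
along the ray (robust to concave borders), traced at 0.5 px steps. A ray
point counts as inside only when its full bilinear footprint (up to four
surrounding pixels) is in the mask. This places the margin at most ~1 px
inside the outermost mask pixel and guarantees that interpolated arm
sampling up to the margin never mixes in background intensity — on a
uniform-interior lesion the measured profile is exactly flat, and the
margin still tracks a harmonic boundary within 1.5 px RMS.

## Synthetic lesions

The generator draws a margin r(θ) = R₀(1 + Σ aₖ cos(kθ + φₖ)) and fills
the interior with L₀(1 + A sin(θ + φ)) plus optional clipped Gaussian
noise; the background is constant. Because the interior has no radial
dependence, the along-arm mean equals the angular modulation analytically
and Δ/mean = 2A exactly, with the brightest angle at π/2 − φ. A
radial-taper option would break this closed form and is deliberately
absent. Defaults — 512×512 image, R₀ = 150 px, lesion level 90,
background 200, one k = 2 harmonic of amplitude 0.1 (a roughly elliptical
lesion), noise_sd 0 — are chosen as a mid-size dermoscopy crop whose
ground truth is exact; noise is opt-in because the generator's purpose is
analytic truth, not photorealism. The generator does not emulate hairs,
air bubbles, pigment networks, colour, or uneven illumination, so passing
recovery tests demonstrate correctness of the measurement chain, not
field performance on real dermoscopy.

End-to-end, the measured statistic recovers 2A to about −0.9% relative
(systematically small): samples within a few pixels of the centroid mix
intensities across clock angles under bilinear interpolation, slightly
shrinking the measured amplitude. This sits well inside the 2% band the
recovery tests assert for A ∈ [0.05, 0.4].

## Reader simulation

Readers follow the equal-variance Gaussian signal-detection model:
evidence x ~ N(0,1) for nevi, N(d′,1) for melanomas, response "melanoma"
iff x > c. The two conditions share truth labels per image and differ
only in d′; evidence draws are independent between conditions (the model
does not attempt to capture within-reader decision correlation across
conditions, anchoring on the machine output, or reader learning).
Defaults mirror the benchmark design: 10 readers, 38 melanomas, 40 nevi,
d′ = 0.94 without and 1.41 with the cue, criterion c = 0.3 — the
operating point implied by the benchmark's mean sensitivity (≈74%) and
specificity (≈61%) at d′ = 0.94. Parameter recovery holds within
Monte-Carlo error (delta-method SE) at 10⁴ images per reader.

## Scoring and report parity

Sensitivity and specificity are percentages with melanoma positive;
d′ = z(H) − z(F) with rates 0 or 1 replaced by 1/(2n) or 1 − 1/(2n).
The printed-report generator rounds per-reader percentages to 1 decimal
and, by default, derives d′ **from those rounded percentages** rather
than the raw count rates (`dprime_from="counts"` switches). This is how
the benchmark's printed table was evidently assembled — every one of its
30 d′ cells reproduces to 2 decimals from the rounded percentages, while
count-level rates disagree in 4 cells — and it keeps each printed row
self-consistent with what it displays. The Mean row averages the rounded
per-reader cells in exact decimal arithmetic with half-up rounding
(0.465 → 0.47; float banker's rounding would give 0.46).

The benchmark's summary table contains one internally inconsistent cell:
reader 6's sensitivity increase is printed as 2.5 although its own
columns give 84.2 − 81.6 = 2.6. The slip propagates to the printed mean
increase (7.87 vs the consistent 7.88) and splits the printed statistics
across sources: the reported mean matches the increase column while the
reported SD (6.79) and two-sided p (0.0051) match the with/without
columns. `analyze_reader_table` therefore computes every paired test both
ways (`from_columns` and `from_increase_column`) and asserts nothing
about intent. Matched-sample t-tests default to two-sided; the one-sided
option (alternative: the cue improves the metric) reproduces the halved
p-values (0.0026, 0.029) that appear alongside the two-sided ones in the
benchmark's reporting.

Count reconstruction: with the constraint that melanomas and nevi total
78 images, an exhaustive search shows (38, 40) is the *unique* split for
which every printed percentage is an integer count ratio to 1 decimal
(they are also the minimal per-class denominators; the benchmark's prose
says 39 + 39, a discrepancy that is documented, not resolved — the
printed percentages themselves demand 38/40). The reconstructed
count-level table assigns decisions to image ids deterministically; only
the per-reader marginals are identified by the printed summary.

## Numerical and design notes

- Degenerate inputs: uniform images raise a segmentation error naming the
  problem; a zero-mean profile raises on the undefined statistic;
  identical paired vectors raise a degenerate-test error; extreme rates
  without a class size raise rather than silently correcting.
- The pipeline writes JSON at full precision and applies printed-table
  rounding only to the human-facing report CSV; a run manifest (config,
  versions, seed, input SHA-256s) makes every run reproducible.
- Problem sizes in the acceptance script — 512² images, 10⁴ images per
  simulated reader — are the package's standard demonstration sizes:
  large enough that Monte-Carlo and interpolation error sit well inside
  the asserted bands, small enough to run in seconds.

## Known limitations

- The cue is validated on synthetic lesions only; the original dermoscopy
  image set is not publicly deposited, and the one published example
  overlay value (0.29) cannot be checked without its source image.
- Otsu segmentation assumes a single darker lesion on a lighter
  background; multi-lesion images, hair, and strong vignetting are out of
  scope.
- The ensemble ("Eclass") risk score shown on overlays is consumed as an
  input number only; the 13-algorithm ensemble that produces it is prior
  work and is not reimplemented here.
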