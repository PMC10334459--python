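# Methods

`mgcekit` digitizes the eight exercises of the Myasthenia Gravis Core
Examination (MG-CE) as administered over a telehealth video link. This
note records the models behind each metric, the tunable parameters and
their defaults, what the synthetic generators do and do not emulate, and
the numerical choices made where the design was genuinely open.

## Coordinate and landmark conventions

All image coordinates have the origin at the top-left with y increasing
downward, so "elevation" of a lid, arm, or hip means *decreasing* y; the
sign conventions below are chosen so clinically meaningful directions
(arm falling, lid drooping) read negative/decreasing. Face landmarks use
the 68-point schema with **1-based** indices (mouth corners are points 49
and 55; eye hexagons 37–42 and 43–48); body landmarks use the 33-point
pose schema with **0-based** indices (shoulders 11/12, elbows 13/14,
hips 23/24). The index tables in `mgcekit.landmarks` are the single
source of truth, and `face_point`/`face_slice` do the 1-based conversion.
Pretrained detectors are deliberately outside the package: any adapter
that emits frames in these schemas can feed the pipeline, and the core
never imports a detector.

Frames whose detector confidence falls below a floor (default **0.5**)
are flagged through a quality mask and excluded from fits, but never
dropped from a series — dropout patterns are themselves diagnostic.

## Eye segmentation at video-call resolution

An eye in a standard video call occupies roughly **40×20 px**. Classical
iris detectors (circular Hough, Daugman's integro-differential operator)
need far more resolution and controlled illumination, so the package
refines a detector-supplied eye ROI with a local hybrid:

1. grayscale (standard luma weights) and a 1st–99th percentile contrast
   stretch;
2. two-class intensity clustering — Otsu threshold by default, 1-D
   k-means behind a config switch — isolates the dark iris+pupil blob;
   the largest dark connected component wins, ties broken by proximity
   to the patch center, and components smaller than **6 px²** mean the
   eye is closed;
3. the pupil center is the darkness-weighted centroid of that component,
   and the vertical iris borders are its extreme columns. At this
   resolution the pupil proper is rarely separable from the iris, so the
   blob centroid *is* the reported pupil center;
4. lids are found per column from the smoothed vertical intensity
   gradient (Gaussian σ = 0.7 px): scanning downward, the upper lid is
   the strongest dark-to-light transition above the iris top (skin below
   the lash line is darker than the sclera). When no such edge exceeds
   **0.05 intensity/px** the lid is resting on the iris and the blob's
   own top edge is used. Symmetric logic finds the lower lid. Gradient
   peaks are refined to sub-pixel accuracy by parabolic interpolation,
   and each lid is fitted by a quadratic with one round of 2·MAD outlier
   rejection.

Failures return a quality flag (`closed`, `low_contrast`) instead of a
guessed geometry, and `validate_segmentation` re-checks lid ordering,
component spill, and contrast post hoc.

The three per-frame openness measures are the lid-to-lid distance at the
pupil column, the opening area between the fitted lid curves over the
iris span (trapezoid rule), and the upper-lid-to-pupil distance.

## Ptosis and alignment metrics

The ptosis exercise (60 s sustained upgaze) is summarized by an ordinary
least-squares line through each measure's unmasked samples: the slope,
the percent decay evaluated from the fitted endpoints
(100·(fit(t₀)−fit(t₁))/fit(t₀)), and a two-sided t-test on the slope at
α = 0.05 as the significance criterion (no particular test is canonical
here; the slope t-test is the natural choice for an OLS summary). An
exponential relaxation fit (time constant to 1−1/e of the asymptote) is
exposed but marked exploratory — it is not part of the standardized exam.

Ocular alignment uses the barycentric coordinate of each eye's innermost
iris border between the eye corners, b ∈ [0, 1], clamped; corner spans
below 4 px are rejected. Misalignment is |Δb| referenced to the median of
the first **2 s** (the exercise's own baseline; no published rule
exists). The summary reports the maximum, the OLS drift slope, and a
steadiness verdict (max < 0.1 by default).

## Motor metrics

Arm elevation is the angle of the shoulder→elbow segment against the
**image horizontal** (not the shoulder line, so torso tilt does not alias
into drift), computed as −atan2(Δy, |Δx|) in degrees. Drift onset is the
first time the smoothed angle stays below **−5°** for **≥ 1 s**
continuously; both values are configurable because the clinical notion
of "drift" has no numeric definition — the default is small enough to
catch early drift and robust to landmark jitter. Detection therefore
reports the *threshold-crossing* time; for a gradual drift of slope m
this exceeds the true onset by 5°/|m|, which the tests account for.

Series smoothing is Savitzky–Golay (order 4, 1 s window), chosen for its
defining property of passing polynomials up to the filter order through
unchanged; any filter with that property is conformant. Sit-to-stand
velocity alone uses an order-1 (moving-average) smooth over 0.3 s,
because a quartic fit rings at the plateau corners and overshoots the
true peak slope.

Sit-to-stand: the rise interval runs from where smoothed mean hip height
leaves the band within 10% (of the total rise) of the seated plateau to
where it enters the same band around the standing plateau; plateaus are
medians over the first/last second. Peak speed and acceleration come
from finite differences of the smoothed height; lateral sway is the RMS
of hip x about its mean during the rise. A pixel calibration from an
object of known size (e.g. the seat, scale = cm/px) converts to cm/s.

## Facial metrics

Mouth features per frame: corner distance ‖p₄₉−p₅₅‖; mouth angle of the
49→55 segment against the image horizontal (signed; a tongue pushed into
one cheek tilts it one way, the other cheek the other way); vertical
inner-lip opening; and the upper-lip-to-nose distance normalized twice —
by the inter-ocular landmark distance (zoom invariance) and by its own
baseline-window mean (default 2 s), so a resting face reads ≈ 1. Upper
lip center and nose base default to points 52 and 34 and are
configurable, since no standard nominates them. Lip curvature is the
inverse radius of the Kåsa least-squares circle through the five outer
upper- (or lower-) lip points. The seal flag fires when the inner-lip
gap falls below 20% of the baseline gap (with a 0.5 px floor so a closed
resting mouth counts as sealed).

Cheek illumination is the mean blue-channel value inside the cheek
quadrilateral (jaw points 3–15–13–5, halved at the vertical through its
centroid for per-side signals). It is illumination- and skin-tone-
sensitive by construction and is treated as corroborating evidence only.

Deformation events are excursions of a feature beyond z·(1.4826·MAD) of
its pre-exercise baseline (z = 4), sustained ≥ 0.3 s, with events closer
than 0.3 s merged; amplitude is the median in-event deviation. A
zero-variance baseline falls back to "any nonzero deviation", so clean
synthetic steps are detected and a flat signal yields no events. Events
on masked (low-confidence) spans are suppressed, since occlusion by
fingers or beards is known to confuse landmark detectors.

The tongue-side switch is the transition between the longest pair of
sustained (≥ 1 s), suprathreshold, opposite-sign runs of the mouth angle
relative to its resting orientation; the threshold is max(1°, 3× the
frame-to-frame noise estimated robustly from first differences), so
jitter alone cannot produce a switch.

## Voice metrics

The waveform (PCM WAV, ≥ 8 kHz) is rectified and RMS-resampled to a
**1000 Hz** magnitude series, then block-averaged with **block = 60**
into a **16.67 Hz ≈ 17 Hz** envelope. The intermediate rate is explicit
config: the breathing-band analysis (5–25 Hz) needs a series whose
Nyquist exceeds 25 Hz, and the block-60 average is only meaningful on
such a series.

Speech segments are runs of the envelope above noise_k × median
(noise_k = 3; on counting audio roughly half the track is silence, so
the median sits at the noise floor). The threshold is capped at 90% of
the envelope maximum so a continuously voiced track still yields one
segment — the cap binds only on degenerate near-constant envelopes. Gaps
under 0.15 s are bridged and fragments under 0.05 s dropped, avoiding a
spray of sub-syllable gaps. For a counting-to-50 exercise the **50
longest** segments are retained (ties → earlier start), re-sorted by
time.

Features, all restricted to speech where noted:

* **Integrated loudness** (LUFS): ITU-R BS.1770-4 / EBU R128 —
  K-weighting as two biquads bilinear-transformed from the analog
  prototypes (reproducing the standard's tabulated 48 kHz coefficients
  exactly and matching the response at any rate), 400 ms blocks at 75%
  overlap, −70 LUFS absolute gate then −10 LU relative gate. Mono
  channel weight 1.0. Digital silence returns NaN with a flag.
* **Pitch**: per-segment normalized autocorrelation with parabolic lag
  refinement, search range 50–400 Hz (spanning typical adult male
  85–155 Hz and female 165–255 Hz voices), voicing threshold 0.5;
  median and IQR over segments.
* **Breathing-band energy**: L2 norm of the FFT coefficients of the
  1000 Hz magnitude series with 5 ≤ f ≤ 25 Hz. Linear in amplitude.
* **Teager–Kaiser energy**: ψ(n) = x(n)² − x(n−1)x(n+1), mean over
  speech samples; equals A²sin²(ω) for a sinusoid.
* **Spectral entropy**: per 0.05 s rectangular-window frame, the Shannon
  entropy of the normalized power spectrum divided by log(#bins) —
  0 for a pure tone, →1 for white noise; silent frames are excluded
  from the mean. "Entropy spikes" are peaks with prominence ≥ 0.1.
* **Single-breath features**: duration from first segment start to last
  segment end (the duration, not the count reached, is the robust
  severity indicator when diction speed varies); energy integral
  Σx²·Δt over speech (uncalibrated airflow proxy); voiced fraction.

## Grading

Each item maps onto {0 normal, 1 mild, 2 moderate, 3 severe} using the
published boundaries, with printed intervals inclusive. Uncovered integer
seams take the milder grade: arm drift at exactly 120 s → 0, dysarthria
onset at exactly 50 → 0, diplopia at exactly 61 s → 0, and sub-second
diplopia onsets in (0, 1) → 2 while onset 0 ("immediate") → 3. Numeric
rules are total and monotone (worse input never lowers severity), which
the tests verify by enumeration.

Purely visual categories (cheek-puff "transverse pucker", sit-to-stand
"need to use hands", the ptosis lid-vs-pupil category) are accepted as
clinician annotations; automated features attach as supporting evidence.
A helper maps a measured lid-to-pupil distance to the ptosis category
with |d| ≤ 1 px meaning "at the pupil" (configurable; no published
pixel tolerance exists).

## Synthetic fixtures

The generators produce the study conditions every metric is tested
under, with analytic ground truth and full determinism under a fixed
seed:

* **Eye scenes** — 40×20 px patches: an anti-aliased iris disc (4×
  supersampling) inside an opening bounded by parabolic lid occluders,
  over skin; Gaussian pixel noise σ = 0.05 on a [0, 1] intensity scale
  for the accuracy batches; randomized geometry and photometry within
  anatomically plausible ranges. Ptosis sequences descend the upper lid
  linearly by a stated fraction (15% over 60 s for the headline case).
* **Body streams** — a fixed 33-point template with kinematic overrides:
  arm-hold rotates the elbows about the shoulders (drift onset + angular
  slope, −2°/s default); sit-to-stand moves the hips through a
  smoothstep (peak speed 1.5·Δy/T) with sinusoidal sway (RMS a/√2);
  Gaussian landmark jitter.
* **Face streams** — a bilaterally symmetric 68-point template with a
  cheek-puff lip raise and/or a tongue-push mouth rotation injected.
* **Counting audio** — sine bursts (default 140 Hz, 0.5 s on / 0.5 s
  off) with 20 ms raised-cosine edges over Gaussian noise at a stated
  SNR (20 dB default), 16 kHz.

What they do **not** emulate: real eyelash/eyebrow texture, specular
corneal highlights, head pose change, rolling-shutter or compression
artifacts, formant structure and coarticulated speech, room acoustics.
Passing tests therefore demonstrate correctness of the measurement
chain under the stated geometry/noise regime, not detector-level
robustness on patient video — the detectors themselves are outside the
package boundary.

## Problem sizes and reproduction

The accuracy batches use 50 eye scenes; decay/onset recovery suites use
50–100 seeded replicates; counting audio uses 50 bursts (~51 s at
16 kHz). `scripts/acceptance.py --seed N --out results.json` recomputes
the three headline figures (mean pupil error, mean lid-to-pupil distance
error, fitted percent ptosis decay) from scratch; all randomness derives
from the given seed.

## Known limitations

* The "pupil center" is the iris+pupil blob centroid; partial lid
  occlusion biases it toward the visible portion (this is the dominant
  term in the ~1–1.5 px batch error).
* The cheek illumination signal is not robust to lighting; it is
  deliberately secondary.
* Depth-based cheek-bulge reconstruction is out of scope (at telehealth
  noise levels the depth signal is not usable).
* Dysarthria classification is out of scope; the dysarthria-onset count
  used for grading is an annotation input.
* Session exercise windows come from the config, not auto-detection.
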