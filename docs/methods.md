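# Methods

This note documents the models, conventions and numerical choices behind
`fiberkit`, in the order the pipeline runs, and what the synthetic-slide
validation does and does not demonstrate.

## Conventions

Coordinates are 0-based `(row, col)`; pixel centers sit at integer
coordinates; geometry stays in pixel units until measurement applies the
micrometer scale (default 0.26 μm/px). Channel 0 carries the first analog
(CldU, "red"), channel 1 the second (IdU, "green"); class masks use
0 = background, 1 = analog1, 2 = analog2. The channel order is
configurable for protocols that reverse the pulses. All randomness flows
through explicit integer seeds and `numpy.random.default_rng`; ties are
broken in lexicographic `(row, col)` order so runs are bit-reproducible.

## Synthetic slides

The generator emulates spread-DNA images at the level the pipeline
consumes: sparse bright curvilinear strokes of ~3 px half-width on a dark
noisy background. Fibers are heading-random-walk polylines (step 4 px,
turn bounded at 3°/step by default — spread fibers are stretched and
nearly straight), carrying 1–3 consecutive single-analog segments. The
default population mixes segment counts at roughly 9% single / 78% double /
13% triple and draws IdU/CldU ratios log-normally around a median of 1.2,
matching the composition of a typical annotated training corpus; specific
experiments override these (the validation slides use two-segment fibers
with ratio exactly 1, see below).

Rendering computes the exact disc-swept stroke of each sub-polyline
(per-pixel point-to-segment distance, no sampling approximation), so the
class mask, instance map and polyline arc lengths are exact ground truth.
Within a fiber, analog1 discs are stamped before analog2 discs: ambiguous
transition pixels therefore resolve to the *second* analog, the same rule
human annotators follow for yellow-ish transition pixels. Across fibers,
intensities max-composite and masks take the later-drawn fiber.
Acquisition effects apply to intensities only, in the order Gaussian PSF
blur (σ = 1 px), additive Gaussian noise (σ = 4 on a 0–255 scale), and a
multiplicative illumination ramp (±10% across the field, random
direction). These defaults are free parameters — the noise statistics of
any particular microscope are not being fitted — chosen so the threshold
backend neither trivially saturates nor fails.

What the synthetic model deliberately omits: non-Gaussian PSFs, camera
gain/offset structure, autofluorescent debris, stain granularity along a
fiber, and fiber density correlations. Passing the validation therefore
shows the geometry, disentanglement, measurement and statistics are
correct; it does not certify segmentation quality on real microscope data,
which depends on the backend plugged in.

## Preprocessing

Images are resampled bilinearly to 0.26 μm/px. Per channel, values are
scaled to [0, 1] (by dtype maximum for integer data, by the data maximum
for floats), background is a median filter (kernel 31) applied to an
8×-downsampled proxy and upsampled back — at full scale the effective
kernel (~250 px) is two orders of magnitude wider than a fiber, so strokes
do not contaminate the model — and subtracted with clarity α (default 1).
Contrast is stretched so the `100 − α` percentile, estimated on a stride-4
subsample, maps to 255 (α = 1 ⇒ p99; α = 0 ⇒ maximum, i.e. no subtraction
and gentlest clipping). When the chosen percentile is 0 — over 99% of a
channel is clean background, common on sparse or heavily cut slides — the
stretch falls back to the channel maximum rather than zeroing the channel.

## Segmentation

A backend is any callable mapping a `(2, h, w)` patch to a `(3, h, w)`
probability simplex. The shipped threshold backend smooths each channel
(σ = 1), thresholds (Otsu per channel by default, fixed values
configurable), and forms softmax probabilities over
`[threshold, ch1, ch2] / temperature` (temperature 8): the argmax is
exactly "foreground where a channel exceeds threshold, class of the
dominant channel". Tiled inference covers the image with 1024-px tiles at
10% overlap and blends overlaps with an isotropic Gaussian weight centered
per tile (σ = 0.125·tile, floored at 1e-6 so weights stay positive);
smaller images are reflect-padded up to one tile. TTA averages over the
8-element dihedral group for square inputs and flips + 180° for non-square
ones (quarter turns would change the raster shape). Ensembles average
member probability maps pixel-wise. All three operations preserve the
probability simplex exactly.

## Junction disentanglement

Each connected component of the mask is thinned to a 1-px centerline
(standard morphological thinning, no tip pruning); skeleton pixels inherit
the mask label, and fiber width is estimated as twice the median distance
transform over skeleton pixels. Branch points are skeleton pixels whose
occupied 8-neighborhood splits into ≥ 3 directional groups around the
ring, evaluated as a 256-entry neighborhood truth table (a compiled bank
of hit-and-miss templates), plus the pixels of any filled 2×2 skeleton
block — thinning leaves such blocks precisely where strokes cross at
steep angles, and their pixels individually look like corners to the ring
test. Branch pixels cluster into junctions by single-linkage at 10 px;
junction centers whose erasure discs would overlap (closer than twice the
erase radius) are then consolidated, because they are physically one
intersection region and matching their arms separately pairs same-side
arms.

A disc of radius 1.5× the fiber width is erased around each junction;
remaining components become branches (fragments under 5 px are dropped,
and residual spurs are resolved by taking the longest endpoint-to-endpoint
path). Endpoint directions are chords over the last 15 skeleton pixels;
endpoint *color* is the majority label of the 5 pixels nearest the cut —
after erasure only a few true-label pixels may separate the endpoint from
the transition, and a longer window misreads the color at crossings that
sit near a transition.

Matching minimizes `w_d·dist/maxdist + w_a·(π − |Δθ|)/π + w_c·[labels
differ]` with `maxdist` = 3× fiber width. The defaults are
`w = (0.2, 0.6, 0.2)`: collinearity must dominate because the geometry is
stacked against proximity — genuine continuations sit a full erased-disc
diameter apart (≈ `maxdist`), while the arms on one side of an acute
crossing are much closer, so a heavily weighted distance term
systematically selects the wrong pairing below ~80°. A branch is never
paired with itself. Two endpoints pair directly; three take the cheapest
pair and tie the leftover tip to the junction center with its own label;
four evaluate the three perfect matchings; five or more (rare, dense
tangles) match greedily by ascending cost with a warning. Reconnection
paths are straight lines labeled with the second analog when the joined
ends disagree — consistent with the annotation rule that ambiguity goes to
the second analog — otherwise the shared label. Fibers are the connected
components of the pairing graph; components that are single-label or
shorter than 15 px are discarded, and final cleaning keeps bicolor fibers
with 2–3 segments whose pixels stay ≥ 1 px from the image border.

## Measurement

Segments are maximal constant-label runs along the fiber path; runs under
4 px are merged into their longer neighbor (label flicker where the
skeleton grazes a transition), and background-labeled stretches from
reconnections join the following run. Run boundaries sit halfway between
the last pixel of one run and the first of the next.

Lengths are integrated along a moving-average-smoothed centerline (window
7, ends padded by linear extrapolation). The raw 8-connected step metric
(1 per axial step, √2 per diagonal) overestimates oblique digital lines by
up to ~8% — the classic chessboard digitization bias — while the smoothed
path is exact on axial and diagonal lines and within ~0.2% at intermediate
angles; the step metric remains in use for the 15-px cleaning rule, where
the convention, not sub-pixel accuracy, matters.

Two stroke-geometry corrections are applied by the pipeline (both default
to off in the bare `measure` function):

* **Transition de-bias.** Because ambiguous transition pixels belong to
  the second analog, the observed run boundary sits one stroke radius
  (3 px by default) inside the first analog's true track; each transition
  transfers that much length back from the second-analog run to the
  first-analog run. Verified on straight-fiber calibrations at multiple
  orientations.
* **Tip correction.** Thinning tips can recede into or overshoot past the
  stroke's rounded end cap by a few pixels depending on orientation and
  curvature. When a tip sits exactly at the curve's end, the mask reaches
  one cap radius ahead of it; the measured deviation from that expectation
  (walked along the tip direction) is applied as a signed correction,
  clamped to +1 cap radius and −½ cap radius — the negative side is only
  half-trusted because cap erosion from thresholding dim stroke ends is
  indistinguishable from overshoot.

The ratio is total analog2 length over total analog1 length for every
bicolor fiber. Classification follows the structure catalogue: 2 segments
⇒ ongoing fork; green–red–green ⇒ divergent (bidirectional) origin;
red–green–red ⇒ convergent forks; anything else is invalid.

Error filtering is a pluggable scorer mapping a fiber record to an error
probability; records above the threshold (default 0.5) are marked invalid,
and lowering the threshold rejects strictly more. The shipped rule scorer
is a smooth logistic over the extracted features crossing 0.5 at
tortuosity 1.5 (smoothed length over endpoint chord), mean curvature
0.3 rad/px (turning rate of 5-px chords — single-pixel headings are
45°-quantized and would misread gentle curves), or a configurable
intensity floor; closed loops score 1. It replaces a trained
false-positive classifier with a transparent rule; any scorer with the
same signature can be swapped in.

## Evaluation

Detections are compared as pixel sets (centerlines dilated by the 3 px
annotation stroke radius, so predictions are commensurate with hand-traced
strokes; raw-mask comparison is available). Greedy matching descends over
IoU, accepting a pair when both ids are unused and IoU strictly exceeds
0.5; precision, recall and F1 follow. Mask quality uses multiclass Dice
over foreground classes present in either mask. Grader agreement is
mutual: a fiber pair is common when ≥ 50% (inclusive) of each skeleton's
pixels lie within 5 px of the other — mutuality keeps the relation
symmetric; the "sufficient fraction" is a free parameter set to 0.5.

## In-silico experiments

Fiber shortening removes a chosen fraction of an analog's length from the
*terminal* end of its segment (the end away from the color transition,
preserving the bicolor structure; interior segments of 3-segment fibers
have no free end and are skipped with a warning). The removed stroke
(dilated +2 px to cover the blur halo) is inpainted per channel with
values sampled i.i.d. from an annulus 2–6 px outside the fiber stroke,
excluding other fibers; exactly the kept stroke (including its natural
rounded cap) is protected — a wider guard would leave a stub of original
paint past the cut. For starting ratio α and cut fractions (C_r, C_g) the
measured ratio should follow α·(1−C_g)/(1−C_r); the cut-grid experiment
re-analyses the slide at every grid point and reports medians both over
all matched fibers and over the common set detected at every level, which
removes detection-dropout bias. Degradation applies per-channel Gaussian
blur or seeded additive noise (clipped to the dtype range).

## Statistics

Cliff's δ is computed by sorted search (O(n log n)), identical to full
pair enumeration. Bootstrap CIs are percentile intervals over B = 1000
(default) independent resamples of both conditions — percentile rather
than BCa, and independent rather than paired resampling, because the
conditions are independent fiber populations. A condition differs
significantly from the reference when its 95% interval excludes zero; the
reference, unless given, is the condition whose median sits at the
midpoint of all condition medians (lower-middle on even counts), and its
median normalizes all condition medians. Two graders disagree on a
condition when exactly one flags significance. Mann–Whitney U is two-sided,
exact for untied samples of ≤ 20, tie-corrected normal approximation
otherwise (via scipy). Structure-type counts compare by Pearson χ² on the
2×k table (k−1 df); a zero expected cell raises an error advising category
merging. Ratio tests use valid two-segment fibers by default; three-segment
structures enter the type counts.

## Validation protocols and problem sizes

The standard validation slide holds 200 two-segment fibers of 80–160 px
(20–40 μm) built with ratio exactly 1 on a 1280² raster (~10% stroke
coverage, a well-populated field); the blur series uses a 1600² raster
with 26 px minimum spacing so 200 fibers remain individually resolvable at
σ = 12. The exact-recovery slide (50 fibers, 768², no noise, no blur, no
crossings) uses the same ratio-1 construction: its 40–80 px tracks keep
the ±1–2 px quantization floor of any integer-raster centerline comfortably
below the 5% accuracy check, which shorter minority tracks of extreme-ratio
fibers would not. The crossing benchmark renders two straight bicolor
fibers crossing at 45–90° with the intersection at 35% of each arc (clear
of the mid-fiber transition), with mild blur and noise. The bootstrap
calibration draws both conditions from the same log-normal ratio
distribution (n = 200/condition, 200 replicates, B = 500).

## Known limitations

* The threshold backend is a reference implementation: adequate for
  synthetic slides and clean well-separated real images, not a substitute
  for a trained segmentation model on difficult data; the backend contract
  exists precisely so one can be plugged in.
* Single-color fibers are deliberately out of scope (discarded by
  cleaning), as is decoding proprietary acquisition formats.
* Junctions with ≥ 5 arms fall back to greedy matching; extremely dense
  tangles can still merge or drop fibers.
* The stroke-geometry corrections assume the 3 px annotation stroke
  convention; masks produced under a very different stroke width need the
  `stroke_radius_px` configuration updated.
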