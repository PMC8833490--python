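# Methods

## Problem setting

A single animal is observed by two fixed, opposing cameras. An upstream
frame-level posture detector (out of scope here) supplies, for every frame
sampled at `fps` (default 5), at most one record: posture class ∈ {lying,
sitting, standing}, confidence ∈ [0, 1], and a bounding box in normalized
center format (cx, cy, w, h as fractions of image width/height). Frames
with no detection are kept as explicit gap records. All downstream
quantities are computed from these streams alone; no image data is used.

## Activity statistic

Movement is quantified as the Euclidean displacement of the box center
between consecutive frames, `m_{f,f+1} = √(Δx² + Δy²)`, in raw normalized
units. No aspect-ratio correction is applied even though a 16:9 frame
makes one normalized x-unit physically longer than one y-unit: the
classification thresholds below were calibrated in the same uncorrected
space, and rescaling would invalidate them.

The per-window statistic is the trailing mean norm: at each step time `t`
(step 1 s), pairs whose two frames both fall in `(t − 5 s, t]` contribute,
and the sum of the `F − 1` pair values is divided by `F`, the number of
frames in the window (a full 25-frame window at 5 fps divides by 25). This
frame-count normalization is deliberate — it is the convention the
published thresholds were derived under — and slightly shrinks the mean
relative to a conventional pair-count mean (factor 24/25 for full
windows). `ActivityConfig.mean_over_pairs` switches to the conventional
mean for users who prefer it; the thresholds are not recalibrated when it
is on.

Activity levels: mean norm ≥ 0.0094 → *highly active*; ≥ 0.0054 →
*active*; otherwise *inactive*. The upper boundary is inclusive by
definition; making the lower boundary inclusive upward as well (exactly
0.0054 → active) is our convention, chosen so both boundaries behave
identically.

Gap handling is our convention (the operating assumption upstream is a
near-continuous detector): a pair spanning a gap is invalid, and a window
with fewer than `min_valid_fraction` (default 0.5) of its expected pairs
valid yields a no-data sample rather than a mean over a sliver of frames.
Windows are causal (emitted at the window end), so the pipeline could run
in real time with a 5 s latency.

## Posture smoothing, fusion, behavior

Each camera's posture stream is smoothed by a trailing 5 s mode filter on
the same 1 Hz emission grid as the activity windows. Ties are broken by
the larger summed confidence of the tied labels, then by the fixed order
lying < sitting < standing; the reported confidence is the maximum among
the winning label's votes. A single flipped frame inside an otherwise
constant window can never win the mode, which is the point of the filter.

Fusion operates per second after smoothing (smooth first, then fuse: the
per-camera mode must see each camera's own labels for the blind-spot case
to be resolvable). The fused mean norm is the maximum over cameras — the
camera seeing the larger displacement is the one seeing the movement. On
posture disagreement the higher-confidence label wins; confidence ties go
to the camera with the larger norm, then to the fixed label order. Cameras
are aligned by nearest timestamp within 0.5 s (integer-second snapping).
A second with only one camera reporting uses that camera; with none, the
fused sample is no-data. Fusion is commutative and idempotent, and with a
single camera the pipeline degrades to a pass-through.

The activity level is classified from the *fused* norm, then crossed with
the fused posture through the behavior decision tree. The default
ethogram has seven labels; the nine posture × activity combinations are
collapsed by mapping highly-active sitting/lying onto *active sitting* /
*active lying* (a fox cannot be locomoting while lying — a large box
displacement in those postures is body movement, not travel). The
`strict_nine` variant keeps all nine labels for users who want the
uncollapsed cross.

Posture changes are counted on the smoothed, fused 1 Hz series: a change
is two adjacent seconds with different non-missing labels, attributed to
the later second's bin; a no-data second between two postures suppresses
the count, since the transition cannot be located. Overview bins (default
30 min, aligned to the stream origin's clock grid) accumulate seconds per
posture, activity and behavior label plus the change count; per-family
seconds sum to the bin's covered seconds by construction.

## Detector evaluation

Matching is the classic greedy VOC contract: per image, predictions in
decreasing confidence order, each matched to the best-IoU unmatched
ground-truth box of the same class, TP iff IoU ≥ 0.5 (the boundary counts
as TP), each ground truth used at most once; unmatched ground truths —
including labeled images where the detector returned nothing — are FN.
Per-class AP is the 11-point interpolated form: the mean over recall grid
{0, 0.1, …, 1} of the maximum precision among PR points with recall ≥ r
(0 where none exists); mAP averages per-class APs over classes with at
least one ground-truth box. Overall precision/recall pool TP/FP/FN over
classes; a 0/0 ratio is reported as undefined, never as 0. Average IoU is
the mean over TP-matched pairs. Degenerate zero-area boxes score IoU 0
instead of raising, so a malformed prediction cannot abort an evaluation.
Recall grid comparisons use a 1e-9 slack so that exact-fraction recalls
(k/10) are never excluded by binary rounding.

Confidence ties are resolved by a stable sort (input order), documented so
results are reproducible. Detection speed is hardware-bound and not a
quantity this package computes.

## Synthetic scenes

The simulator generates the setting the pipeline targets: behavior states
follow a continuous-time Markov chain over the ethogram (exponential dwell
times, default means 20–60 s per state so that 5 s windows rarely straddle
transitions; uniform jumps to any other reachable state — restricting
`dwell_means` restricts the state space). Position is a reflected Gaussian
random walk inside an inset arena (margin 0.08 keeps boxes on screen),
with per-frame, per-axis step scale σ set by the state's activity level.

Calibration of the step scales is closed-form, done once: an isotropic
Gaussian step with per-axis σ has mean length σ·√(π/2), so a full
25-frame window's mean norm is σ·√(π/2)·24/25. The defaults σ =
(0.0005, 0.006, 0.012) therefore put noiseless window means at ≈ 0.0006,
0.0072 and 0.0144 — mid-band between the 0.0054/0.0094 thresholds for the
active regime and an order of magnitude clear of them for the other two.
The window-mean standard deviation (≈ 0.13 σ) leaves ≥ 2σ of margin to
each boundary, which is where the ≥ 95% band-compliance property comes
from; windows straddling a state transition mix regimes and are exempt.

Cameras render the truth independently: per frame a miss with probability
`miss_prob`, otherwise a detection with isotropic center jitter (clipped
to the unit square, so clipping never moves a center farther than the
jitter overshoot), a posture flip per the camera's flip table with
probability `flip_prob` (modeling the blind spot: the default camera 1
reports standing as lying), and a confidence drawn from a clipped Gaussian
— mean 0.90 for correct labels, 0.60 for flipped ones, reflecting that
partial views score lower. Box sizes are posture-typical constants with
5% multiplicative jitter; they only exercise the IoU/evaluation paths.
The default two-camera noise point (5% misses, jitter σ 0.002, 5%
standing→lying flips on camera 1) is the moderate-noise condition used
throughout the tests.

All randomness flows through one `numpy.random.SeedSequence`: truth and
each camera get spawned child streams, making fixtures byte-identical
across reruns and platforms.

### Expected labels and what recovery tests show

A windowed pipeline's output at second `t` summarizes `(t − 5, t]`, so
during the ~5 s around a state transition the "right" answer is genuinely
ambiguous. The fixture's *expected* labels are therefore defined by
applying the same trailing-window conventions to the noiseless truth
(mode of true postures, mean of true displacements); a noise-free run of
the pipeline reproduces them exactly, and a separate test checks agreement
with the instantaneous state away from transitions. Recovery accuracies
quoted by the acceptance script compare the noisy pipeline against these
expected labels. The blind-spot fusion check counts recovery over
*steady* standing seconds — seconds whose whole trailing window lies in a
standing bout — since window-straddling seconds are ambiguous at the
output resolution regardless of fusion.

The simulator emulates detector *output* statistics, not fox biology or
image formation: misses and flips are i.i.d. per frame (real detector
errors are burstier), jitter is isotropic and state-independent, the walk
has no goal-directed structure, and no multi-animal or occlusion-by-object
cases exist. Passing recovery tests demonstrates the correctness and noise
robustness of the downstream analytics under these assumptions — not
field performance of any particular detector.

## Problem sizes and numerical choices

Test and acceptance runs use 10 min to 2 h simulated bouts (the 2 h
moderate-noise bout: ~72 000 frames over two cameras, ~7 200 scored
seconds), 500-image evaluation sets, 1 000 random AP instances and 500
random IoU pairs — sizes chosen so the full suite runs in well under a
minute while keeping binomial noise on reported rates below a percentage
point. Window membership and grid joins use a 1e-9 epsilon on timestamps;
the AP recall grid uses the same slack (see above). The brute-force
cross-checks are independent code paths: AP via exact rational arithmetic
over enumerated PR points, IoU via an area-weighted 2000×2000 raster
(plain cell-center counting at that resolution has error up to ~1e-2 and
cannot support a 1e-3 comparison; area weighting is exact to float
rounding).

## Known limitations

Sleeping and awake motionless lying are indistinguishable by construction
(same posture × activity cell), as are behaviors that share a cell (e.g.
enrichment interaction vs. pacing within *highly active standing*). The
activity statistic sees only whole-body translation of the box center;
within-box movement (grooming, scratching) registers only insofar as it
moves the box. Timestamps are seconds-since-stream-start; mapping to wall
clock (and thus to clock-aligned half-hour bins) is the caller's
responsibility via the bin origin. Multi-animal scenes are out of scope:
the per-frame reducer keeps only the single best detection.
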