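# Methods

## Scope and model

The package assesses upper-limb exercise quality from 2D pose-landmark
streams.  A repetition (motion segment α) is represented by one to three
joint-angle trajectories; its quality is the DTW distance to a baseline of
mean normal trajectories, standardized by the normal sample's distance
statistics and mapped to a 0–100 score.  Only x/y landmark coordinates are
used: monocular depth is estimation, not measurement, and the interior
angle computed by the cosine rule is invariant to the image's y-down
convention, so no axis flip is applied.

### Joint angles

For a vertex landmark v and references p₁, p₂ the angle is
arccos(D/(M₁M₂))·180/π with D the dot product of the vertex-anchored
vectors and M₁, M₂ their magnitudes.  The cosine argument is clamped to
[−1, 1]: with collinear points, floating-point error can push it past ±1
and the clamp keeps the angle at exactly 0° or 180° instead of NaN.
Angles are unsigned interior angles in [0°, 180°]; no reflex angles are
distinguished.  Zero-magnitude vectors (a reference coinciding with the
vertex) raise a degenerate-geometry error naming the frame.

Angle definitions: shoulder = angle at the shoulder subtended by elbow
and hip; elbow = angle at the elbow subtended by shoulder and wrist;
wrist = angle at the wrist subtended by index finger and elbow.  The
33-point schema's per-hand index-finger point is used for the finger
reference.

### Smoothing

A centered moving average with window 5 (samples) is applied to the angle
trajectory (not the landmarks) before both segmentation and assessment.
At the boundaries the window shrinks to the available samples so the
output keeps the input's length and time grid — segment boundaries then
map 1:1 onto frames.  Window 1 disables smoothing (useful for ablation).

### Segmentation

Detection runs on the smoothed primary angle only; compensation angles
are sliced on the same frame ranges, never re-segmented.  The rest angle
is the median over the initial rest window.  Candidate repetitions are
extrema of |θ − rest| with a minimum prominence; for each, the start is
the first frame whose deviation exceeds the onset threshold after having
been within it, the trigger is the first frame after the extremum moving
back toward rest, and the end is the first frame after the trigger within
the return tolerance of the start angle — or, if the next repetition
begins before the angle returns, the reversal point (deviation minimum)
between the two extrema.  Segments shorter than a minimum duration are
discarded.  Detection is direction-agnostic (abduction raises the
monitored angle, elbow flexion shrinks it).

Defaults (all config-exposed calibration knobs, chosen for full
range-of-motion upper-limb exercise at webcam frame rates): rest window
0.5 s, onset threshold 10°, return tolerance 5°, minimum segment 0.3 s,
minimum peak prominence 15°.  The prominence gate is what keeps abnormal
tremor (≈3° at ≈6 Hz) from splitting a slow repetition into several.

### Baseline construction

Per joint: mean length l̄ = Σlᵢ/n over the normal segments; each
trajectory's elapsed times are rescaled by e′ = e·l̄/e_max; the rescaled
trajectories are resampled by linear interpolation on a uniform grid over
[0, l̄] and averaged pointwise.  The grid step defaults to the median
inter-sample interval of the contributing segments (≈1/60 s at 60 FPS),
so the mean trajectory has roughly frame resolution; it is exposed as a
parameter.  The grid is realized with `linspace` so that it ends exactly
at l̄.

μ and σ are the sample mean and sample SD (n − 1 denominator) of the
contributing segments' multi-DTW distances to the finished means,
computed in-sample by default.  In-sample statistics slightly understate
σ (the means were fitted to the same segments); `stats_segments` accepts
a held-out pool to quantify that optimism.  σ = 0 (e.g. identical inputs)
flags the baseline degenerate and Z-scores against it are refused.

### DTW configuration

The distance is classic dynamic-programming DTW with symmetric steps
(diagonal/vertical/horizontal), no slope constraint, and optionally a
Sakoe–Chiba band.  Defaults, all in `DtwConfig`:

- **dependent multivariate mode**: one alignment over vector-valued
  samples with per-step cost the Euclidean norm of the per-joint angle
  differences, all joints equally weighted (weights are exposed — the
  wrist's small range of motion makes equal weighting noise-sensitive,
  which is why single-angle features often win);
- **path-length normalization**: the accumulated cost is divided by the
  optimal warping-path length, so distances read as mean per-step angular
  error in degrees (order 1–2° for normal movement) rather than sums over
  ~60 frames.  Path length is recovered by backtracking with ties broken
  deterministically (diagonal, then vertical);
- the assessed segment is compared at its native sampling — DTW absorbs
  tempo, so slow-but-complete movements are not penalized (a known
  limitation of the scoring: slow, full-range abnormal movements can
  score 100).

Independent mode (mean of per-joint scalar DTWs) is available.  With one
joint both modes reduce bitwise to the scalar DTW.  The DP kernel is
numba-compiled when numba imports, with an identical pure-Python
fallback; tests verify the DP against an exhaustive enumeration of all
monotone warping paths on small instances.

### Scoring

Z = (d − μ)/σ; S = 100/max(Z, 1).  S is continuous at Z = 1, monotone
non-increasing, with range (0, 100]; it never reaches 0.

## Synthetic data

The simulator stands in for the study's private recordings and defines
the package's validation conditions.

- Repetition: raised-cosine pulse rest → peak → rest.  Normal: duration
  1.0 s ± 10% jitter, full range of motion (abduction 15°→165°, shoulder
  flexion 15°→160°, elbow flexion 170°→40°), peak jitter ±5%.  Abnormal
  (emulating a 5-kg resistance band): duration uniform in [2, 3] s, 70%
  of the normal range, plus a 3° tremor sinusoid at 6 Hz windowed by the
  pulse shape so it vanishes at rest.
- Sampling at 60 FPS with additive Gaussian angle noise (SD 0.5°),
  standing in for pose-estimation jitter.
- Clip: 3 s lead-in rest (the observer's countdown), 10 repetitions
  separated by 0.4 s rest plateaus, ~2 s trailing hold.
- Protocol: 12 participants × 3 exercises × 2 sides × (2 normal + 1
  abnormal) rounds of 10 repetitions → 216 clips, 2160 segments, 180 per
  participant.  Per-participant Gaussian offsets (SD 5°) on rest and peak
  angles provide between-subject variability so that the B/N subset split
  is a meaningful comparison.
- Non-primary joints sit near resting values (shoulder 20°, elbow 160°,
  wrist 160°) with a small excursion coupled to the primary movement
  (8–10% for shoulder/elbow, 5% for wrist) and half-amplitude tremor in
  the abnormal condition — enough structure for the multi-angle feature
  variants to be exercised, without claiming physiological realism.
- A `posture_lean_sd_deg` knob adds a per-clip baseline offset emulating
  the seated-posture variation that blurs shoulder-flexion scores; it
  defaults to 0.
- Landmark streams are produced by planar forward kinematics of a
  shoulder-anchored 3-link chain (upper arm 0.16, forearm 0.15, hand 0.07
  in normalized image units) written so that recomputing angles from the
  emitted 33-point frames recovers the generating trajectories to ≤1e−6°;
  unused landmarks hold a static plausible pose.

Durations, range-of-motion direction, tremor presence, and all protocol
counts follow the study design; the remaining shape constants are this
package's choices, fixed once and exposed as configuration.  What passing
tests show is therefore that the *pipeline* reproduces the protocol
bookkeeping and separates the simulated conditions — not that it would
achieve the same p-values or distance magnitudes on real video, which
depend on pose-estimator error structure, true inter-subject variability,
and camera placement.

## Evaluation pipeline

Per exercise, normal segments are split per participant half/half into
baseline subset B and test subset N (seeded, deterministic); abnormal
segments form subset A.  Sides are pooled.  For each of six feature
variants (triple, dual, single, shoulder-only, elbow-only, wrist-only)
the baseline is built from B only and distances computed for all
segments.  Subset pairs (N–B, N–A, B–A) are compared with the two-sided
independent-samples t-test (pooled variance by default — the common
statistical-package default the study's naming suggests — Welch behind a
flag) and the two-sided Mann–Whitney U-test with tie correction.  Raw
p-values are reported; no multiple-testing correction.  The report also
summarizes Z and score distributions per subset (in-sample μ/σ make
subset B's Z-scores mean 0, SD 1 — a sanity identity the tests assert)
and the closest-k abnormal analysis (k = 10): mean/SD of distance, Z, and
score of the abnormal segments nearest the baseline.

Problem sizes: the default validation dataset is the full 216-clip
protocol at 60 FPS (2160 segments); the test suite's module-level checks
use reduced plans (2 participants, 4 repetitions per round) where the
full grid is not the point.

## Numerical and degenerate-input choices

- Cosine argument clamped before arccos (no NaN on collinearity).
- Warping band too narrow to reach the corner → explicit parameter error.
- Empty sequences, empty segment lists, zero-length trajectories →
  parameter/data errors rather than silent propagation.
- σ ≤ 1e−12 is treated as zero (degenerate baseline, exit code 4 in the
  CLI).
- Backtracking tie-break (diagonal first) fixes the path length when
  multiple optimal paths exist, keeping path-normalized distances
  deterministic.
- All simulator draws flow through one `numpy.random.Generator`; the CLI
  derives per-stage substreams from the run seed via `SeedSequence`
  keyed by stage name, so stage outputs are independently reproducible.

## Known limitations

- DTW ignores speed and timing: slow but complete movements score as
  normal; smoothness/time-penalty features are deliberately out of scope.
- The simulator does not model pose-estimator failure modes (occlusion,
  identity swaps, out-of-frame limbs) beyond additive angle noise.
- Segmentation thresholds are calibration knobs; very small-range
  exercises would need different onset/prominence values.
- The single-angle baseline comparison assumes the camera was oriented as
  prescribed per exercise (front for abduction, side for flexions);
  perspective error is not corrected.
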