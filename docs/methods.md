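# Methods

## Problem setting

Given a 25-frame, 768×576 px, 8-bit phase-contrast sequence at 0.833 µm per
pixel, the tracker must (1) detect sperm-head centroids per frame, (2)
assign each detection to an existing track, a new track, or the clutter set
τ₀, and (3) report track-level quality against ground truth. State
estimation (Kalman/particle smoothing of the resulting tracks) and CASA
kinematic parameters are deliberately out of scope: the package isolates
the observation and data-association steps.

## Track geometry

Coordinates are raster: x = column, y = row, 0-based, origin top-left, y
down. All headings are measured in this frame consistently, so the
convention cancels from every comparison. A track with L points yields
L − 1 steps (dᵢ, θᵢ) with d the Euclidean displacement and θ from the
two-argument arctangent — the single-argument form loses the quadrant and
would make rotation normalization meaningless. Zero-displacement steps
carry θ = 0 by convention. Normalization subtracts the first *motile*
step's heading from every θ and wraps to (−π, π]; it is idempotent and
preserves displacements exactly. Interior missing slots are filled by
linear interpolation (a run of k misses becomes k + 1 equal sub-steps), the
same dummy-point rule used wherever a gapped track enters a distance.

The step-space distance between a growing track and an exemplar truncated
to t steps is the Euclidean norm over the 2t residuals, with angular
residuals wrapped to (−π, π]. Raw subtraction would charge ~2π for two
nearly identical headings straddling ±π; wrapping removes that artifact.
Displacements are in pixels and angles in radians, so one radian of heading
error weighs as much as one pixel of displacement error; at the typical
4 px step of a progressive cell this is a reasonable exchange rate, and it
keeps the distance free of extra tuning constants.

## Detection

Per frame: (1) foreground where intensity exceeds the local mean by
`sensitivity` local standard deviations (window 31 px, both moments from a
uniform filter); (2) morphological closing with a disk of radius r_SE = 5
to re-merge fragmented large components; (3) hole filling; (4) 8-connected
labeling and an area band filter [β_min, β_max] = [1, 25] px. Surviving
centroids are the observations. `sensitivity` defaults to 4.0, tuned on the
synthetic renderer: the head (≈120 counts over background) sits ~20 noise
standard deviations high, while a 4σ cut keeps the expected number of noise
pixels per 768×576 frame in the low tens; lower cuts let closing weld noise
pixels into head-sized blobs and false alarms explode. Sweeping β_max is
the intended way to trade detection probability against false alarms.

Detection scoring pairs detections with ground truth by minimum-total-cost
assignment, forbidding pairs farther than 5 px (the head major axis,
4.3 µm ≈ 5.2 px, rounded down). Per-frame detection probability is
true positives over ground-truth count, undefined (and excluded from
averages) for frames with no ground truth; sequence and dataset figures
are unweighted means of means.

## Association model

Exemplar tracks are normalized polar tracks from manually extracted (here:
simulated ground-truth) sequences, excluding the sequence under test
(leave-one-out). The N exemplars are the regions of a Softmax CPD with
fixed coefficients ζᵢ^q = −δ(i−q), so region weights reduce to a softmax of
negative truncated distances — no learning is involved. Computation is in
log space with the usual max-subtraction; exemplars shorter than the
required length are excluded before the softmax and receive weight exactly
zero.

Each comparable region (one with both a t-step prefix and a step t + 1)
scores every gated candidate with an isotropic bivariate Gaussian centred
on its step t + 1, variance max(λ·d_r, σ_floor) per axis, angular residual
wrapped. The broadening-with-step-length covariance encodes that fast
exemplar steps predict loosely and slow ones tightly; σ_floor = 0.25 px²
keeps immotile exemplar steps from producing a degenerate spike. λ defaults
to 0.25 px so that ±2σ around a typical 4 px step spans ≈ ±2 px, on the
order of per-step heading jitter; both are configurable. Per-region scores
are normalized over the m candidates (regions whose scores all underflow
contribute a uniform distribution), then mixed by the region weights, so
the output sums to one over the candidate set.

Candidates are observations strictly inside the circle of radius
(miss_count + 1)·v̄ around the last assigned point, converted to (d, θ)
relative to that point and rotated into the track's normalized frame so
they are commensurate with the exemplars. A candidate reached after k
misses spans k + 1 interpolated steps, so its per-step displacement
d/(k + 1) is what the exemplar's next step is compared against. v̄ is a
dataset property with no universal value; `max_step_displacement` derives
it from a ground-truth table (the benchmark uses 1.25× the observed
maximum single-frame displacement).

### Joint assignment and lifecycle

Per frame, one rectangular cost matrix covers all live tracks: −log
mixture probability for gated (track, observation) pairs, a forbidden
sentinel elsewhere, and one private miss column per track at
−log p_miss (p_miss = 0.05 by default). The Hungarian solution gives a
joint assignment in which no observation serves two tracks — the
single-scan analogue of picking each track's argmax candidate, made
consistent across tracks.

Tracks with fewer than two observed points have no step pattern to compare,
so their first transition is scored by a distance-only Gaussian with scale
v̄/2. This bootstrap score is deliberately *not* normalized over the
candidate set: its absolute value is what lets the joint solver arbitrate
between a young track and a confirmed track competing for the same
observation. (Normalizing it makes every young track's best candidate free,
which lets duplicate tracks steal observations from established ones and
measurably fragments the output.)

Lifecycle per frame: assigned tracks append the observation and reset the
miss counter; missed tracks append an explicit missing slot and increment
it; at d̄ consecutive misses the track terminates with trailing missing
slots trimmed. d̄ defaults to 5, the smallest threshold giving a 99%
chance of at least one look at a target when the per-frame detection
probability is 0.67 (the formula d̄ ≥ log(1−π)/log(1−p_d) is exposed as
`required_miss_threshold`). Every unassigned observation seeds a tentative
single-point track; tentative tracks that die before gaining a second
point go to τ₀, since a track must exist in at least two frames. The
output therefore always partitions the observation multiset into pairwise
disjoint tracks (each with ≥ 2 observed points, ≤ 1 per frame) plus τ₀ —
asserted by `validate_result` in every pipeline test.

The nearest-neighbour baseline shares gating, the joint solve, and the
entire lifecycle; only the cost changes (Euclidean distance from the last
point, miss cost equal to the current gate radius so any gated observation
beats a miss). Differences between the two trackers therefore isolate the
association cost. On clean, well-separated scenes their outputs coincide
exactly.

## Evaluation

Estimated and truth tracks are paired by Hungarian assignment on the mean
frame-aligned point distance over their temporal overlap (gaps
interpolated). Pairs are inadmissible with no overlap, endpoint distances
above 25 px (five allowed misses × 5 px per-step allowance), or mean
distance above 50 px; the mean distance is computed over the overlap only,
since behaviour outside a partial overlap is undefined. Accepted pairs are
the correct associations n_C; precision n_C/‖ω‖, recall n_C/‖G‖, and
F1 = 2RP/(R+P) = 2n_C/(‖ω‖+‖G‖) follow (F1 defined as 0 when P + R = 0).
RMSE per accepted pair is the root mean squared point distance over the
overlap, in Cartesian coordinates (the rejection rule likewise uses
Cartesian point distances, not the step-space distance).

## Synthetic data

The generator emulates the recording conditions rather than sperm
hydrodynamics. Progressive cells (default 50% of the population) keep a
persistent heading with Gaussian per-step noise (sd 0.15 rad), per-step
speed ~N(4, 1) px/frame truncated at zero (≈4 px/frame matches the average
movement scale the evaluation thresholds assume), and a sinusoidal lateral
beat (amplitude 1.5 px, 0.2 cycles/frame) standing in for flagellar
oscillation. Non-progressive cells (25%) take small steps (~N(1, 0.5)) with
turning uniform in ±π/2; immotile cells (25%) jitter sub-pixel (sd
0.05 px) about a fixed point. Boundaries are reflective; grid placement is
available for deliberately well-separated scenes. The renderer draws an
anti-aliased bright ellipse per head (5.2 × 3.5 px, the measured head size
in pixels), oriented along the instantaneous heading, plus a bright halo
annulus mimicking the phase-contrast artifact, on Gaussian background
(mean 40, sd 6); the detection-level corrupter bypasses imaging entirely,
keeping each true point with probability p_d, jittering it, and adding
Poisson clutter uniform over the arena.

What the generator does *not* emulate — cell-cell occlusion and collision,
focus drift, brightness gradients, debris with internal structure,
correlated misses — bounds what passing tests show: they demonstrate the
machinery is correct and that the exemplar prior helps under detection
dropouts and clutter, not that the specific scores transfer to clinical
recordings.

## Problem sizes and numerical choices

The bundled benchmark uses 10 cells × 25 frames × 10 replicate sequences
per detection-probability level, with the exemplar library drawn from the
other nine replicates (~90 exemplars, leave-one-out); these sizes keep a
full sweep around a minute on one core while leaving the method/baseline
ordering stable across seeds. Forbidden assignment pairs use a finite 10⁹
sentinel for solver safety, and sentinel pairs are stripped from solutions.
Probabilities are floored at 10⁻³⁰⁰ before taking logs; softmax and
per-region normalizations subtract maxima. Assignment ties are broken
deterministically by the solver's row order; tests assert only
total-cost optimality, never a particular tied solution. The whole pipeline
is deterministic given its inputs, and all generator randomness flows from
explicit integer seeds.

## Known limitations

Single-scan association: a wrong assignment is never revisited, unlike
multi-hypothesis deferred-decision trackers. The exemplar prior assumes the
reference population moves like the tracked one; a library from a different
preparation could mislead. The miss probability p_miss is a fixed constant
rather than derived from the measured detection probability. Segmentation
has no halo-specific suppression, so bright rings near merging cells can
produce false or merged detections — on real recordings the area filter and
the tracker's τ₀ routing absorb some, not all, of this.
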