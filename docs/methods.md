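# Methods

This note documents the models and procedures implemented in `gamekin`,
the parameter defaults and why they were chosen, what the synthetic-data
generator emulates, and the package's known limitations.

## Coordinate and unit conventions

Touch positions are stored in screen points with the origin at the
top-left corner, x rightward and y downward — the native convention of
touch events. Times are seconds from trial start; absolute timestamps in
input files are normalized on read. Physical outputs (mm, m) are obtained
through a `DeviceProfile`: the default 132 points/inch matches a
12.9-inch tablet's logical density, giving 0.1924 mm per point; it is
overridable for other hardware. Unit conversion is applied after all
geometric computation, never before.

Touch events arrive irregularly, so every kinematic analysis starts by
linearly resampling each trace onto a uniform grid (default 60 Hz, the
typical touch event rate). Output samples sit at exact multiples of the
sampling period inside the trace's time span.

## Reach deviation (drag-and-drop)

The straight path through the reach endpoints P₁, P₂ is represented as
the normalized implicit line αx + βy + δ = 0 (α² + β² = 1). Every sample
of the drag, from first touch to release inclusive, contributes a
perpendicular deviation; the path score is the root mean square of these
deviations in mm. Per-item completion time runs from touch-down on the
item to touch-up, not from trial start. Placement accuracy is a
point-in-polygon test of the drop point against the crate polygon
(boundary counts as inside).

## Track tracing and kernel change-point segmentation

The tracing analysis follows a segmentation-first design: the path
derivative dy/dx (central differences on the uniform grid; slopes where
|Δx| < 10⁻⁹ are clamped to ±10³, since the derivative is formally
unbounded) is segmented, and errors are measured per segment against the
ideal track.

**Cost and criterion.** A segment z_{a..b} is scored with the RBF kernel
cost c(z_{a..b}) = (b−a) − (1/(b−a)) Σ_{i,j} exp(−γ(zᵢ−zⱼ)²), which is
zero for constant segments and nonnegative by Cauchy–Schwarz on the
kernel Gram matrix. The segmentation criterion V(τ) sums this cost over
the K+1 segments induced by the breakpoints τ.

**Solvers.** `segment_fixed_k` minimizes V exactly for a known K by
dynamic programming over all admissible breakpoints (suffix recursion;
O(KT²) with O(1) segment costs from 2-D prefix sums of the Gram matrix).
Ties are broken toward the lexicographically smallest breakpoint vector,
making results deterministic. `segment_penalized` solves the
penalty-per-change formulation with PELT pruning, which is sound here
because the kernel cost never increases under splitting. Breakpoints use
the half-open convention: a breakpoint is the first index of the next
segment. The minimum segment length defaults to 5 samples (~80 ms at
60 Hz): shorter curvature segments are indistinguishable from noise.

**Bandwidth.** γ is not fixed a priori; the median heuristic
γ = 1 / median(squared pairwise differences) is computed on a
deterministic subsample of ≤ 1000 points. Constant signals have no
defined bandwidth and the caller must supply γ (the race analyzer falls
back to γ = 1 for the noiseless case).

**From segments to errors.** The default race track has 13 sections
meeting at 12 labeled curvature breakpoints; the sections have distinct,
bounded headings (no near-vertical tangents), so the derivative signal
changes distribution exactly at the bends. The path is low-pass filtered
(Savitzky–Golay, ~0.35 s window, order 2) before differentiation —
finger wobble is noise, not curvature — but distances are always
measured on the raw resampled samples. Detected segments are paired with
ideal sections by a monotone minimal-cost assignment: when the
segmentation is clean this is exactly the k-th-to-k-th pairing, and when
a split is spurious or missed it absorbs the defect locally instead of
shifting every later pairing (a strict order bijection propagates a
single off-by-one across the whole trace). Samples near a detected
boundary may belong to either adjacent section, so each sample's error
is its distance to the paired section or its immediate neighbors,
whichever is nearest. Per-segment and overall RMSE are reported in mm.

**Shortcut rule.** Cutting across the track is flagged when ≥ 25% of
samples lie beyond the corridor half-width (default 40 pt) from the
track, or when the traced path is shorter than 0.8 × the track length.
Both thresholds are configurable; the rule itself is a behavioral
criterion, not a fitted quantity.

## Coloring accuracy

Strokes are rasterized with a circular brush (default radius 6 pt) onto
a grid of 2×2-pt cells; stroke polylines are subdivided to half-cell
resolution first. The result is a *set* — retracing and stroke order
cannot change it. Cell centers are tested against the shape (circles
analytically via a high-resolution buffer, polygons by point-in-polygon
with the boundary counted inside). Reported measures: inside% and
outside% with the unique colored cells as denominator (they sum to 100
whenever anything was colored), and coverage% with the shape's own cell
count as denominator. Both denominators are reported because "% filled
inside" is ambiguous between them. Star shapes are stored as explicit
simple polygons, avoiding even-odd filling questions.

## Morse tapping

Press intervals are reconstructed from down/up events per pointer
(orphan events are dropped with a warning). A press is a dot iff its
duration ≤ `dot_max_s` (default 0.3 s, configurable; the boundary is
assigned to dot by convention). Within each half of the trial
(fingers switch at 90 s of the 180-s trial) the pointer with more
presses is the tapper; the other is the holding finger. Produced symbols
are matched greedily, in order, against the expected dot/dash stream of
the message — the game paces the player symbol by symbol, so
insertion/deletion alignment is unnecessary — and each mismatch is one
error. Characters whose full symbol sequence has been consumed count as
revealed. Tap and error rates are computed over tumbling 10-s windows
spanning the nominal trial duration. The holding finger contributes a
displacement count (one per inside→outside crossing of its circular
target) and its path length in mm. Overlong inter-symbol pauses are not
counted as errors; only press-duration mismatches are.

## Bimanual coordination

Each hand's samples are reduced to the unwrapped angle atan2(y−c_y,
x−c_x) around its circle (in screen coordinates positive angles advance
clockwise on screen). The oscillatory signal fed to the Hilbert
transform is sin(angle); the instantaneous phase is the unwrapped
argument of the analytic signal, and the angular velocity is the time
derivative of the unwrapped angle divided by 360 (rev/s). Mirrored modes
negate one hand's angle before comparison so ideal mirrored coordination
also reads 0° (in-phase) or 180° (antiphase).

Phase synchronization is summarized by the arithmetic mean, SD and
normal-theory 95% CI (mean ± 1.96·SD/√n over per-sample values) of the
absolute wrapped phase difference |Δφ| ∈ [0°, 180°]; folded statistics
keep the summary nonnegative and bounded. Speed synchronization
summarizes Δω = ω_right − ω_left the same way. 10% of samples are
trimmed from each end before statistics to suppress Hilbert end effects
(configurable). Travel distance per hand is the polyline length of the
raw trace in meters; its CV across attempts is reported when a hand has
multiple attempts.

## Cross-trial statistics

Pearson (on raw values) and Spearman (average-rank) correlations
quantify the speed–accuracy tradeoff (completion time vs error) and the
age trend (age vs error); the Pearson p-value comes from the standard t
transform and is reported, not used for gating. The time–error cloud is
also summarized by an exponential best fit y = a·exp(bx) via log-linear
least squares (requires y > 0), with the residual sum of squares on the
original scale. Dispersion summaries use the sample SD (n−1), a 1.96
normal CI multiplier (the per-sample n is in the thousands, where t ≈ z)
and CV = SD/mean, undefined when |mean| is below 10⁻¹².

## The simulator

The generator stands in for study participants and encodes the
structural relations the analyzers are designed to detect. What it
emulates:

* **Reaches** follow a minimum-jerk profile (the standard point-to-point
  human movement model) with zero-mean Gaussian perpendicular noise;
  drop points land in the crate with probability increasing in skill.
* **Speed–accuracy coupling**: a single `speed_factor` both shortens
  movement durations and scales up injected noise
  (σ_eff = noise_sd_mm · speed_factor / skill), so hurried trials are
  faster *and* sloppier.
* **Age → skill**: cohort ages map to skill linearly in log-age (a
  monotone stand-in, not a claimed developmental model); skill speeds
  movements up and scales noise down, producing the age trend.
* **Tracing wobble** is a mean-reverting (Ornstein–Uhlenbeck) lateral
  process with stationary SD `noise_sd_mm` and 0.25-s correlation time —
  band-limited like real finger corrections, not white.
* **Tapping** reproduces the expected Morse stream with per-symbol error
  probability decaying per 10-s window (practice effect), an exact
  forced-error override for recovery tests, a deliberate excursion
  model for the holding finger, and the 90-s finger switch.
* **Bimanual modes** place the two hands at 0°/180° initial offset with
  independent OU phase jitter per hand whose *difference* has the
  configured stationary SD; mirrored modes invert one rotation
  direction. Cohorts configure antiphase modes with 2.5× the jitter of
  in-phase modes, reflecting their well-known lower stability.

Defaults: 60 Hz sampling; skill 0.7; noise 2 mm; ω = 0.6 rev/s per hand;
phase jitter 10°; tap error probability 0.2 decaying ×0.85 per window;
game durations 60 s (reach attempt), 30 s (race), 120 s (coloring),
180 s with 90-s switch (tapping), 30 s per mode (bimanual). All
randomness derives from the config seed; identical configs produce
byte-identical serialized trials.

What it does **not** emulate: strategy changes within a trial, fatigue,
pauses and task abandonment, stylus pressure/tilt, device latency or
dropped touch events, or any claimed distribution of real participants'
scores. Passing recovery tests therefore shows the analyzers are correct
and well-calibrated on clean generative structure — not that real
children's data will be as well behaved.

## Numerical choices and degenerate inputs

* Duplicate timestamps are collapsed (last wins) before resampling;
  fewer than 2 distinct timestamps is an error.
* Coincident reach endpoints, < 2 polyline vertices, empty stroke sets,
  zero brush radius, constant signals for bandwidth/phase, nonpositive
  penalties and infeasible K all raise typed exceptions rather than
  returning silent defaults.
* The race analyzer falls back to the largest feasible K (with a
  recorded warning) when an attempt is too short for 13 segments.
* Wrapped phase differences live in (−180°, 180°]; the −180° boundary
  (within float tolerance) is mapped to +180°.
* Fixed-K ties break to the lexicographically smallest breakpoint
  vector; penalized ties to the smallest previous change index.

## Problem sizes

The test suite and the acceptance script run simulations sized for a
single CPU: segmentation signals of ~1000–1300 samples, 30-s bimanual
trials at 60 Hz (1801 samples per hand), 100-seed recovery loops for the
scalar pipelines and 8–10-seed loops for the segmentation pipeline.
These sizes put every sampling-distribution check within its stated
bounds while keeping the full suite under a minute.

## Known limitations

* **Derivative fragility.** dy/dx is unbounded for near-vertical motion;
  clamping keeps the kernel cost finite, but tracks approaching vertical
  tangents produce spike-dominated signals the segmentation handles
  poorly. The shipped track avoids vertical tangents by design.
* **Noise ceiling for tracing recovery.** With the default track and
  speeds, injected wobble up to ~2 mm SD is recovered within 20%; beyond
  that the derivative SNR collapses, segment boundaries drift, and the
  tracing RMSE is inflated (upward-biased but still monotone in the true
  noise, so ordinal comparisons survive).
* **2-D endpoint only.** Touch data measures the fingertip's contact
  point; no 3-D limb kinematics are inferred.
* **Angular-speed units.** Speeds are reported in rev/s as
  (dφ/dt)/360°. Published per-hand values of ~7 "revolutions per second"
  for this task class are implausibly fast for hand circling and likely
  reflect a different effective unit (e.g. rad/s); comparisons across
  studies should check units explicitly.
* **Greedy symbol alignment** assumes the game paces the player; data
  from a free-running tapping paradigm would need insertion/deletion
  alignment.
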