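# Methods

## Geometry and conventions

World coordinates are millimetres in a right-handed frame with z up and the
origin at the left arena's bottom corner nearest its monitor; image
coordinates are pixels, origin top-left, x right, y down.  Frames are
0-based at 30 Hz; epochs include both endpoints.  The two arenas
(609.6 × 304.8 × 304.8 mm, separated by 304.8 mm along x) each carry their
own world frame anchored by an L-shaped reference object; the frames are
unified by translating the right group's coordinates by the measured
offset (914.4, 0, 0) mm, implemented as t → t − R·offset on the right-group
camera extrinsics (idempotent).

## Camera model and pose

Cameras are pinhole with radial-only distortion (the default rig is
distortion-free, matching a linear lens).  Extrinsics are recovered from
≥ 4 non-collinear 3D–2D correspondences on the reference object: a DLT
initialization when ≥ 6 points are available (deterministic multi-start
otherwise), refined by Levenberg–Marquardt on reprojection error.  The
contract is defined by reprojection RMSE (< 1e-6 px noiseless), not by a
named PnP algorithm.  Two-view triangulation returns the midpoint of the
common perpendicular between the back-projected rays, which is the
least-squares point for two rays; multi-view triangulation triangulates
every unordered camera pair and averages the results without weighting or
outlier rejection.  This unweighted average is deliberately simple; its
accuracy is limited by the worst-conditioned pair (see Limitations).

## 2D tracking

Detector peaks become candidates when their confidence strictly exceeds
0.95, at most two per feature label per camera-frame.  K-means (k = 2,
seeded) clusters candidate positions; the uniqueness constraint (one animal
has at most one of each feature) is enforced by move-or-drop repair: a
duplicate farther from its cluster centroid moves to the other cluster if
that cluster lacks the label, else is dropped.  If the two clusters' union
has no duplicate labels and their centroids are within 120 px (≈ two face
widths), they are merged — a single visible animal should yield one
cluster, which plain k = 2 K-means cannot produce.  Outlier removal pools
the frame's within-cluster nearest-neighbor distances and drops members
whose nearest-neighbor distance exceeds the pool mean + 2 SD; clusters with
fewer than three members pass through (insufficient statistics).  The pool
uses nearest-neighbor rather than all pairwise distances: with an isolated
false positive in the cluster, the pairwise pool is inflated by the
outlier's own distances and the 2-SD rule never fires, whereas the
nearest-neighbor pool isolates it as intended.

Identity is established where it is unambiguous — the middle cameras each
see exactly one animal — by triangulating the per-camera feature centroids
to a 3D animal position (constrained to its arena box with a 50 mm
tolerance), interpolating gaps, projecting into the monitor-end cameras,
and labeling each end-camera cluster by optimal 2×2 assignment to the
projections (matches beyond 300 px are refused).  Frame-to-frame linking of
centroid tracks uses minimum-displacement optimal assignment with a 100 px
jump gate at 30 Hz and deterministic lower-index tie-breaks.  Gap
interpolation is linear, capped at 5 frames, and never extrapolates
leading/trailing gaps.

## Gaze model

The face-norm vector is the unit normal of the plane through the two eyes
and the central blaze, signed so the mean ear-tuft position has negative
projection (tufts lie behind the face).  The gaze cone is single-nappe with
half-angle θ = 10° — the containment inequality
cos θ − ⟨d, X−o⟩/‖X−o‖ ≤ 0 uses cos θ directly, so θ is the off-axis
half-angle; boundary equality counts as inside.  The cone apex is placed at
the centroid of the two eyes and the blaze (configurable); the defining
inequality leaves the apex position open, and this choice keeps the apex on
the facial plane between the eyes.

Head-gaze velocity is the five-point stencil
v(t) = [N(t+2) + N(t+1) − N(t−1) − N(t−2)] / 6 applied per component to the
raw norm series — no smoothing.  The threshold 0.05 applies to ‖v(t)‖ in
the natural per-frame units of unit vectors (no rescaling by the frame
interval); the first/last two frames are undefined and break epochs, as do
frames with invalid geometry.  Stable epochs are maximal sub-threshold runs
of at least 3 frames.

## Intersections

Cone–facial-triangle and cone–cone tests are numerical, as simple grid
scans: a barycentric grid (default 25², plus the vertices) on the
eyes+mouth triangle, and a regular 3D grid (default 40³) over the search
volume for cone–cone.  The default search volume is the axis-aligned
bounding box of both arenas inflated 10% — it includes the inter-arena gap,
where joint-gaze targets between the animals actually lie.  The joint-gaze
location is reported as the centroid of the grid points satisfying both
containment inequalities (the closest-approach midpoint of the two axes is
a cross-check in tests).  The cone–monitor intersection is analytic: the
conic of the cone quadric restricted to the monitor plane, classified as an
ellipse exactly when the plane cuts all forward generators (axis-to-normal
angle < 90° − θ) with a forward axis crossing, flagged `clipped` when the
ellipse exceeds the monitor rectangle.  Both the ellipse center and the
axis–plane point are available as "gaze centers"; the axis–plane point is
the default.

## Gaze states

Frame classification is hierarchical: a cone containing any sampled point
of the partner's facial triangle defines partner (or reciprocal, if
mutual) gaze regardless of incidental external cone–cone intersections;
joint gaze requires an external intersection with neither face hit.  Epoch
attribution follows the semantics of each state: joint and reciprocal
require both animals stationary, so overlap segments of the two epoch sets
may take any state (modal frame state, ties resolved by the hierarchy);
partner states require only the gazer's stability, so the non-overlapping
remainder of an animal's epochs is classified among {that animal's partner
state, none}.  Transition matrices count consecutive epoch states (missing
states break chains; self-transitions are the recurrent edges); reciprocal
epochs are excluded from transition analysis by default, reflecting their
rarity, and the χ² edge comparison is 2×2, two-sided, without continuity
correction.  Near/Intermediate/Far distance boundaries default to the
intersections of adjacent components of a tri-Gaussian mixture fitted to
the social-distance sample (terciles as fallback), with a config override.

## Mixture MLE and bimodality

EM over heterogeneous component families (Gaussian, Gamma, lognormal) with
exact weighted M-steps; the Gamma shape solves
log a − ψ(a) = log m − m_log by Brent's method to 1e-10.  The
log-likelihood is asserted non-decreasing at every iteration; convergence
is relative improvement < 1e-8, capped at 500 iterations.  Model selection
is by AIC with fewer-parameters tie-breaks.  Sarle's BC defaults to the
population form (skew² + 1)/kurtosis — for a uniform distribution skewness
is 0 and kurtosis 9/5, giving the 5/9 benchmark exactly — with the
finite-sample-corrected variant selectable; bimodality is flagged at
BC > (5/9)·1.05 (5% margin, configurable).

## Synthetic scenes

The generator emulates the acquisition setup, not its appearance: a rigid
6-landmark face template (eye spacing 20 mm, blaze 12 mm above the eye
midline, mouth 15 mm below, tufts 25 mm lateral and 8 mm behind the facial
plane — plausible marmoset scale), posed per frame so the scripted dyadic
gaze state holds by construction.  The dyadic state timeline comes from
animal A's script; B's script, when given, must match it segment-for-
segment and contributes B's motion profiles.  Partner gaze aims the gazer's
cone axis at the partner's face centroid (fixed-point iteration, since the
apex moves with orientation) while the partner faces its own monitor;
joint gaze aims both axes at a point on the gap floor between the arenas;
"none" points both animals at their own monitors, so the cones diverge.
Head reorientation at segment boundaries is abrupt, which the 5-frame
velocity stencil flags as non-stationary — epochs therefore sit strictly
inside segments and each segment contributes exactly its scripted frames of
its state.  Every generated frame is re-classified by the noiseless oracle
and the generator refuses unrealizable segments.

The default rig places the monitor-end cameras beyond the outer arena ends,
straddling the arena laterally (±250 mm) for a wide stereo baseline, and
the middle cameras near the gap end of each arena's open sides, angled back
so the other arena falls outside their frusta (verified numerically at
build time, as is ≥ 2-camera coverage of every arena vertex per group).
Intrinsics are fx = fy = 1000 px at 1920×1080 with zero distortion.
Rendering projects true landmarks per camera and corrupts them: Gaussian
pixel noise, Bernoulli dropout, Poisson false positives uniform in the
image with confidence U(0.5, 0.94) — below the 0.95 threshold most of the
time, so candidate selection is stress-tested but not overwhelmed; true
detections draw confidence from U(0.96, 0.999).

What the generator does **not** emulate: fur/appearance, geometric
occlusion (dropout is stochastic, not ray-cast), detector bias or
spatially correlated error, body posture beyond the head, and more than two
animals.  Passing tests therefore demonstrate the geometry, identity and
classification machinery — not detector performance on real video.

## Problem sizes and numerical choices

The end-to-end demonstrations use 150–240-frame scenes (five or six
scripted segments) — long enough for every state and several epochs per
animal, small enough for interactive runs.  The EM recovery suite uses
n = 10⁴ per fit over 20 seeds.  Tolerances: rotation orthonormality 1e-9;
noiseless reprojection/triangulation round trips 1e-6; probability row
sums 1e-12; Gamma M-step 1e-10.  Ties in K-means are controlled by the
seeded initialization; assignment ties resolve to lower indices via an
infinitesimal cost bias.

## Known limitations

- Frame-level gaze classification is sensitive to landmark noise: the
  face-normal's lever arm is ≈13 mm, so 3D landmark error σ translates to
  ≈ σ/13 rad of axis noise against an ≈11.5° tolerance (10° cone + ≈1.5°
  face subtense at ≈560 mm separation).  At 1 px detection noise the
  pipeline reconstructs landmarks to ≈1 mm and frame-state agreement
  exceeds 95%; at 2 px it degrades to ≈87%.  Epoch-level (modal) labels are
  considerably more robust.  Improving this would require weighting or
  pruning ill-conditioned camera pairs in the triangulation average, which
  the pipeline deliberately keeps as a plain unweighted mean.
- The unweighted all-pairs triangulation average lets the narrowest-
  baseline camera pair dominate the error budget; rig design (wide end-
  camera baselines) mitigates this.
- Identity transfer relies on the middle cameras' unambiguous single-animal
  views; with both middle views of a group lost for longer than the
  interpolation cap, end-camera clusters in that span stay unlabeled.
- The cone–cone grid test can miss intersection regions smaller than the
  grid pitch (default ≈40 mm at arena scale); the grid resolution is a
  config key.
- Mixture EM finds local optima; initialization is data-driven with seeded
  jitter, and parameter-recovery tests cover the regimes used, but
  pathological starts can converge to degenerate components.
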