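# Methods

`larvatrack` quantifies the locomotion of small bright animals (Drosophila
larvae, C. elegans) in dark-background recordings such as those produced by
FTIR-based imaging rigs.  This note describes the model behind each stage,
the parameters that matter, the numerical conventions, and what the
synthetic test bed does and does not establish about real recordings.

## Coordinate and precision conventions

Pixels are addressed as `x` = column, `y` = row, origin top-left, 0-based.
All landmark coordinates are integer or half-integer pixel positions; no
sub-pixel refinement is performed anywhere, so the smallest expressible
positional error is 1 px along an axis and √2 ≈ 1.41 px diagonally.  Frame
indices are 0-based internally and 1-based in all files written to disk.

## Segmentation

The background image is the per-pixel minimum intensity over time,
`B(r,c) = min_t I_t(r,c)`.  This is exact when every pixel is animal-free in
at least one frame, i.e. when each animal travels at least its own body
length during the recording.  Recordings that violate this (an animal
holding position while head-casting, very short clips) must be given an
explicit background — the CLI flag `--blank-background` supplies an
all-dark one — otherwise the stationary body is absorbed into `B` and
disappears from the foreground.  For long recordings `background_stride`
subsamples the frames used in the minimum; the result is an upper bound on
the true minimum background, which errs on the side of a slightly brighter
background and therefore a slightly smaller foreground.

Foreground keeps original intensities: `F_t(r,c) = I_t(r,c)` where
`|I_t − B| ≥ τ`, else 0, with `gray_threshold` τ (default 50 on the 0–255
scale).  The absolute value is kept for externally supplied backgrounds
even though `I ≥ B` holds by construction for the minimum background.

Connected foreground components (8-connected) are traced with
Moore-neighbour border following into closed integer boundary chains.  The
contour area is the component's pixel count (holes inside a body are
treated as segmentation noise and ignored), the perimeter is the closed
polygonal chain length.  Contours are kept when
`area_min ≤ A ≤ area_max`; larger blobs are presumed animal collisions and
smaller ones artifacts, and both are discarded.  Collisions are therefore
not resolved: participating trajectories end, and the animals re-appear
under fresh identities after separation.

## Posture model

Per-point curvature uses the first pass of the IPAN corner detector: at
each contour point the sharpest angle over admissible triangles with arm
lengths between `d_min` and `d_max` contour points.  The arm defaults
(4 and 7 per 100 contour points, clamped to ≥ 2) are chosen to span
body-width-scale boundary noise without blurring the genuinely sharp tips.
Head and tail are the centres of the two sliding windows (half-width
`curvature_window`, default 2) with the smallest circular mean angle, at
least `head_tail_min_separation_frac` (default 25 %) of the contour apart;
the sharper window is provisionally the head.  The contour is normalized
to a fixed orientation before splitting so the two halves are reproducible.

The two head-to-tail halves are paired point-by-point after linearly
resampling the longer half to the shorter one's point count.  Spine points
are midpoints of pairs taken at arc-length-equidistant positions along the
shorter half (endpoints excluded, fractional indices floored); radii are
half the pair distances.  With `n_spine_points` L = 7 this yields 5
interior spine points — the resolution used by manual annotation protocols
for these animals.  The center of mass is the rounded mean of the enclosed
pixel coordinates, consistent with area-as-pixel-count.

## Tracking

Association between consecutive frames minimizes total cost over a
bipartite matching.  Cost measurements: Euclidean distance between centers
of mass (smooth, spine-independent), between middle spine points (jittery
but guaranteed inside the body), or contour overlap in pixels (a
similarity, negated for minimization).  Solvers: the optimal Hungarian
assignment (via `scipy.optimize.linear_sum_assignment`, which handles
rectangular matrices directly), and a sequential greedy matcher that
visits animals in ascending identity order, takes the best unclaimed
candidate, and accepts only within `greedy_threshold` (maximal distance,
or minimal overlap for overlap costs; ties break to the lower index for
reproducibility).

The Hungarian solver always produces `min(N_t, N_{t+1})` pairs, so each
pair is validated: the match stands only if at least one landmark of the
earlier model lies inside the later contour (overlap-cost pairs with zero
overlap are rejected outright).  Failed pairs terminate the earlier
trajectory and spawn a new identity for the later detection.  Identities
come from a monotone counter and are never recycled or merged.

The combinations matter in practice: overlap costs with Hungarian matching
are robust for slow peristaltic crawling, but fail (by design, with
explicit terminations rather than silent mismatches) when per-frame
displacement exceeds the body size, where distance costs with a generous
greedy threshold still follow the animal.

## Head/tail correction

Curvature alone fixes the head only provisionally.  Per trajectory, on
maximal coil-free runs of frames, the labels are first made temporally
consistent (each frame's head goes to the endpoint nearest the previous
head), then two behavioural regularities vote on the orientation of the
whole run: the fraction of moving frames where the midpoint→head vector
has positive dot product with the center-of-mass displacement (locomotion
conformity), and the fraction of low-velocity frames — velocity below the
go threshold, i.e. reorientations — where the head endpoint moves farther
than the tail endpoint (bending conformity).  Frames where both endpoints
move exactly equally (almost always 0 px at integer resolution) carry no
signal and are excluded.  The two scores are averaged (equal weights,
configurable) into the probability that the current labelling is correct;
below `orientation_flip_threshold` (0.5) the run is flipped, reversing
spine and radii.  Coiled frames inherit the orientation of the preceding
oriented frame.  Contour-derived quantities (center of mass, area,
perimeter) are never modified, and the procedure is idempotent.  The vote
is reliable whenever the animal moves forward in the majority of frames or
reorients by casting the head while the tail holds.

## Features

The main body bending angle γ is measured at the middle spine point:
its deviation from 180° is the unsigned angle between `v1 = h − s_mid` and
`v2 = s_mid − t` (`arccos` of their normalized dot product), and the side
comes from the sign of the 2-D cross product of `v2` and `v1`.  In image
coordinates (y down) a positive cross product is reported as a left bend
(γ > 180°), negative as right (γ < 180°).  This convention is fixed and
documented because an unsigned angle alone cannot express the
left/right distinction; label reversal maps γ to 360° − γ.

Coiled postures (body curled onto itself) make the spine meaningless; they
are flagged when the perimeter-to-spine-length ratio reaches
`π(1 − coil_perimeter_tol)` — the ratio sits near 2 for a straight body
and grows through π as the extracted spine collapses, hence a one-sided
test — or when the circumference of the circle implied by the middle
radius approaches the perimeter (`|2π r_mid / P − 1| ≤ coil_radius_tol`).
Defaults (0.1, 0.15) are set so that straight and gently bent capsules
never fire; this is asserted in the tests.

Motion features derive from the center of mass: accumulated path length,
straight-line distance to the trajectory origin (both 0 at the first
frame), velocity as displacement over a one-second central window divided
by `fps` (px/frame; multiply by fps for px/s), and acceleration as the
absolute difference of consecutive velocities divided by
`acceleration_divisor` (default 2).  A frame belongs to a go phase when it
sits in a run of at least `go_min_frames` frames that are simultaneously
fast (velocity above `go_velocity_threshold`, default 1 px/frame) and
near-straight (|γ − 180°| below `bend_threshold_deg`); all other frames
are reorientation.  Features that are undefined — windows reaching past
the trajectory ends, degenerate geometry, spine-derived features on coiled
frames — are emitted as NaN (empty CSV fields), never as silent zeros.

Stimulus markers (point, line segment, axis-aligned rectangle and
ellipse) add, per animal and frame, the distance from the center of mass
to the nearest marker point, an unsigned bearing angle at the tail (the
tail is used because head casts do not perturb it), and a region flag.
The ellipse nearest point uses the standard centre-ray approximation
(intersect the line through query point and centre with the boundary);
the error is bounded by the difference of the semi-axes and is negligible
at moderate eccentricity, and the exact solution would require solving a
quartic for no practical gain.

## Synthetic scenes and what they establish

The generator renders capsule animals — a parametric midline swept with a
radius profile that is constant mid-body and half-cosine-tapered over the
terminal quarter at each end, the head tip slightly sharper (0.9 px vs
1.8 px tip radius at 9 px body width) so the curvature detector's
"sharpest = head" assumption holds by construction.  Midlines integrate a
tangent field `heading + bend·(W(u) − mean W)`; the bend weight W is
uniform (crawling, undulation, coiling) or concentrated in the front 40 %
of the body (head casts).  Scenes default to a 10 px background, 200
body gray level, additive Gaussian noise of sd 2, and a pair of static
dim artifact blobs that the minimum background must remove — conditions
matching high-contrast dark-field recordings.  Ground truth (head, tail,
5 interior spine points with radii, width-weighted analytic center of
mass, bending angle, coiled flag, identity) comes from the midline before
rasterization; truth and rasterized centroid agree to ≤ 1.5 px.

Named scenarios fix the study conditions: `forward_crawl` (five
peristaltic crawlers, 200 frames, 512×512), `rolling` (lateral jumps of
35 px/frame with zero frame-to-frame contour overlap), `snake`
(±60° undulation), `collision` (two crawlers converging until their
contours merge past the area band), `coiling` (a curl episode up to 330°
of body bend), and `headcast` (tail-anchored ±45° head sweeps).  A
scene at 15 animals / 211 frames / 2040×2048 can be built through the same
`SceneSpec` surface when full-scale behaviour is of interest; the default
test sizes keep the whole suite within minutes on one CPU.

The generator emulates geometry, contrast, static artifacts, and sensor
noise.  It does not emulate non-rigid body-wall deformation, intensity
texture within the body, illumination gradients, motion blur, or genuine
animal-animal occlusion dynamics.  Passing its tests therefore
demonstrates the correctness of the algorithms under the stated imaging
assumptions, not performance on any particular laboratory recording.

## Evaluation protocol

Tracked trajectories are matched to truth identities by majority
nearest-center-of-mass vote; frames voting against the majority count as
identity switches.  Per matched frame the report records the Euclidean
center-of-mass and central-spine-point deviations and the absolute bending
difference — circular (≤ 180°) except on frames where the tracked head is
nearer the true tail, where the raw difference is kept so head/tail swaps
surface as large outliers instead of being folded away.  Summaries give
mean, std, median, min and max over non-outlier values plus the maximum
including outliers and the outlier count, with outliers defined by Tukey
fences (1.5 × IQR beyond the quartiles, configurable), matching the usual
boxplot presentation.  The generator's truth center of mass is
midline-analytic while the tracker's is a pixel centroid; the two
protocols are comparable but not identical, which bounds the achievable
"zero" of the comparison at the discretization scale rather than exactly 0.

## Known limitations

- Collisions terminate identities; there is no merge resolution or
  re-identification after contact.
- The background model is static; slow illumination drift is not handled.
- Head/tail correction needs behavioural asymmetry (net forward motion or
  head-dominant reorientation); an animal that crawls backward for most of
  a recording will be oriented backward.
- Spine extraction degrades gracefully but meaninglessly on coiled frames;
  downstream features are masked rather than corrected there.
- Velocity is reported in px/frame over a one-second window; sequences
  shorter than one second have no defined velocity at all.
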