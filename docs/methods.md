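# Methods

This note documents the models implemented in `cochleapy`, the parameter
choices that matter, what the synthetic phantom does and does not emulate,
and the numerical decisions a maintainer would want to know.

## Canonical cochlear frame

The frame is constructed from the three landmarks exactly as defined in the
cochlear-imaging literature: z = unit(Ap − C) (the modiolar axis), the basal
plane through RW with normal z, origin = the axis point in the basal plane,
x = unit(RW − origin).  The y-axis is z×x for right ears and x×z for left
ears, so the frame is deliberately *left-handed for left ears*: this makes
the cochlear angle increase from 0° at the round window toward the apex for
both sides, and mirrored anatomies receive identical cylindrical
coordinates.  A point on the modiolar axis has undefined azimuth; we return
θ = 0 with an `on_axis` marker so downstream code never branches on an
exception.  Angles along ordered paths are unwrapped cumulatively (+360° per
revolution); isolated points report the principal value in [0°, 360°).

## Synthetic phantom

The phantom is a planar log-spiral midline ρ(θ) = a·e^{bθ} lifted by
z(θ) = h·θ/θmax (+ an optional height wobble), carrying two tubes — ST below
the midline, SV above — separated by a wall whose mid-surface stands in for
the basilar membrane.  Defaults (a = 3.2 mm, b = −0.09 rad⁻¹, θmax = 900°,
h = 3.0 mm, duct radii tapering 0.6 → 0.35 mm, wall 0.25 mm) give a
cochlea-scale object: labyrinth volume ≈ 45 mm³, lateral-wall two-turn
length ≈ 32 mm, A ≈ 6 mm, with ~1.3 mm clearance between successive turns
so that extraction algorithms face a realistic (but not degenerate)
wrap-around geometry.  Tissue classes use fixed CT-like intensities (fluid
0 HU, bone shell 1500 HU, background −1000 HU) plus seeded additive
Gaussian noise, so every test is deterministic.

Deliberate idealisations, and what they imply for test conclusions:

* **Equal ST/SV radii.**  The labyrinth cross-section is then symmetric
  about the midline, so the analytic centroid curve *is* the midline and
  centerline accuracy can be asserted exactly.  Real ST is somewhat larger
  than SV; the extraction code does not rely on the symmetry, but its
  sub-voxel accuracy figures are only demonstrated for the symmetric case.
* **Apex landmark on the axis.**  The helicotrema landmark Ap is placed at
  the top of the modiolus (the generation-axis point at apical height), not
  at the off-axis duct endpoint.  Since the canonical z-axis passes through
  Ap by construction, an off-axis Ap would tilt the frame against the
  generation frame and make ground-truth angles inexact; with the on-axis
  definition the landmark-derived frame coincides with the generation frame
  and every ground-truth angle is exact.
* **The height wobble** used for the "rollercoaster" (basal height dip) is
  dip·cos(2πθ/360°), which is orthogonal to a linear fit over any whole
  turn, so the rollercoaster metric (max |residual| of a linear basal-turn
  fit) recovers the generator amplitude exactly by construction.
* **Implant contacts are placed at equal 3D chord spacing** (consecutive
  center-to-center distance = pitch, 1.2 mm by default, found by bisection
  along the ST axis).  On a curved duct, arc-spaced contacts would show
  chord spacings up to ~2.5 % short apically; chord placement makes the
  generator's pitch exactly the quantity that detection and reconstruction
  measure, so pitch recovery can be asserted at the 1 % level.
* **The lead wire is rasterised at 2200 HU** — bright against bone
  (1500 HU) but below the 2500 HU metal threshold — giving contact
  detection and the metal mask an unambiguous target set.  No metal-artifact
  streaks, beam hardening, or partial-volume blooming are simulated, so
  passing tests demonstrate algorithmic correctness, not robustness to
  clinical artifact levels.

## Centerline extraction

Angular wedges of width `angular_step` (default 18°, matching the usual
sectioning protocol; configurable) around the modiolar axis are tracked from
the basal end: each step mean-shifts a capture ball (0.8 mm) around the
linear prediction from the previous two samples, which separates the duct
from neighbouring spiral turns.  Three stopping rules make the track
well-defined: a no-jump bound (step > 3·Δθ·ρ_local means the tracker latched
onto another turn), radius monotonicity (the cochlear spiral only shrinks
apically), and a same-wedge revisit test (so closed loops such as a torus
terminate after one revolution).  The initial polyline is refined by
re-centering within slabs orthogonal to the running tangent (10 iterations
or 0.01 mm convergence).  For the whole labyrinth, ST and SV are tracked
separately and averaged: the combined two-duct cluster is ~2.9 mm tall and
has no stable single-centroid height, whereas each tube centers exactly.

Accuracy on phantoms: mean distance to the analytic curve ≈ 0.02–0.07 mm at
0.1–0.2 mm voxel spacing.  The apical *truncation* sample, by contrast, is
raster-sensitive: a float-level change (mirroring, grid rotation) can move
the last accepted wedge by one step.  Full-coverage duct lengths therefore
vary by ~0.5–1 % between such runs; fixed-coverage lengths (basal-turn,
two-turn) are stable and are what the invariance tests assert.

## Cross-sections and landmarks

Sections are resampled on an in-plane grid (half the voxel spacing)
orthogonal to the centerline tangent.  Because an orthogonal plane also cuts
neighbouring turns, only connected components within 0.5 mm of the plane
center are kept — above half the inter-scalar wall (the center sits in the
wall between ST and SV), below the ≥ 1 mm distance at which the next turn
appears.  The cross-sectional area integrates the interpolated
partial-volume fractions, which is unbiased; the 0.5-isocontour (used for
the boundary polygon and landmarks) would clip staircase corners and
underestimate small sections by ~5 %.  Ellipse axes come from a
least-squares conic fit to the boundary, rescaled to preserve the measured
area.

Landmark rules: LW / MW are the ST boundary points of maximal / minimal
radial distance; OC lies on the radial ray at 80 % of the axis→LW distance,
at LW's height (configurable to the centroid's height; the height convention
is not standardised).  SG is MW displaced 0.35 mm against the centerline
tangent (toward the base — the longitudinal sign convention is ours, exposed
as a parameter) and radially so that its final axis distance is exactly
ρ(MW) − 0.35 mm; the radial correction is applied along the in-plane
direction orthogonal to the tangent, so both offsets hold simultaneously and
exactly.

## Basilar membrane

The membrane is extracted as the zero crossing of (P_SV − P_ST) restricted
to the overlap region where both probabilities exceed 0.1 — the
equal-probability mid-surface of the inter-scalar wall.  (An iso-level of
min(P_ST, P_SV) yields a two-sided shell around the wall instead of its
mid-surface, with a bias of order the smoothing radius.)  Binary labels are
smoothed with σ = 1.5 voxels first.  When a canonical frame is supplied,
faces whose ST→SV gradient leaves a 60° cone around the modiolar axis are
discarded: those are spurious interfaces where one turn's ST meets the
*next* turn's SV radially.  Face winding is oriented ST→SV, so signed
contact-to-membrane distances are negative on the ST side.  Mean distance to
the phantom's analytic wall is ≈ 0.02 mm at 0.1 mm spacing.

## Global metrics

* **A/B diameters**: A is |RW − LW(θ*)| where θ* ∈ [150°, 210°] minimises
  the chord's distance to the modiolar axis (the "around 180°" window is a
  design choice); B is the LW(90°)–LW(270°) chord.
* **Height**: labyrinth extent along the modiolar axis.
* **Rollercoaster**: max |residual| of a linear fit of z(θ) over the basal
  turn (0–360°).
* **Duct lengths**: cubic-spline arc length per path (LW/MW/OC/SG), with
  basal turn = 360° and two turns = 720°.
* **Wrapping factor**: slope of ln ρ against θ (rad) on the supplied path —
  the log-spiral pitch; reported both as the tangent and as the pitch angle
  in degrees, since the field uses either.  The fit is run on the duct
  midline: the lateral wall adds a tapering duct radius on top of the
  spiral, which biases the fitted slope by ~10 %.  The wrapping *ratio*
  divides the maximal angle by the lateral-wall duct length, as defined.
* **Volumes / surfaces**: voxel counting and marching-cubes mesh area.
  Marching cubes on binary rasters over-estimates curved areas by a few
  percent (staircase effect); volumes are accurate to ~2 %.

## Trajectory model

The constants 1.3 mm, 0.007 mm/° and the 150° switch are fixed calibration
values of the predictor, not re-estimated here.  The switch condition is
interpreted on the *angle* (θ ≤ 150°).  The wall branch subtracts the
physical electrode radius (tapering linearly 0.25 → 0.20 mm, i.e. 0.5 →
0.4 mm diameters) from the lateral-wall radius.  Trajectory height is
interpolated from the ST centerline; the predicted radius is clamped at
0.05 mm with a warning.  No blending is applied at the switch — the model is
piecewise as specified (a smoothing option exists but is off by default).
Depth→angle inversion integrates the 3D curve at 0.5° resolution;
n-electrode queries convert as (n−1)·pitch + basal margin (default 0).

## Electrode array

Detection thresholds the *raw* image at 2500 HU (metal) and finds local
maxima of a 0.15 mm-σ smoothed copy inside that mask, with 0.6 mm
non-maximum suppression and sub-voxel center-of-mass refinement
(≤ 0.13 mm error on noiseless 0.2 mm phantoms).  Array growth seeds at the
candidate-cloud medoid and its nearest neighbour, then alternately
extrapolates one pitch beyond each end and accepts the best-scoring unused
candidate within 0.6 × pitch of the extrapolant.  The extrapolation rotates
the last chord by the rotation between the two preceding chords
(constant-curvature continuation) — linear extrapolation under-shoots badly
in tightly curled apical regions; while the chain still has fewer than four
contacts (no curvature information yet) a fallback accepts candidates in a
pitch-distance band within the forward cone.  Tip fold-over is *allowed*
(non-monotone angles are flagged, not rejected); fewer than two candidates
is a hard failure.  Wire tracing skeletonizes the bright structure above
1800 HU (contact blobs excised), picks the component nearest the first
contact (≤ 2 mm), orders it by nearest-neighbour walking and anchors it at
the first contact, where the wire attaches but cannot be skeletonized.

Insertion depth is arc length along the reconstructed array from the
round-window crossing, located on the lead wire when one was traced, else
the first contact plus a configurable basal margin (default 0).
Characteristic frequencies use the Greenwood form f = A(10^{ax} − k) with
literature-standard human defaults A = 165.4 Hz, a = 2.1, k = 0.88 — these
are configuration, not results; the spiral-ganglion map evaluates the same
form at the ganglion place with an optional linear place compression
(identity by default).  Tests assert monotonicity and endpoint behaviour
only, since the constants are conventions.

## Registration

Pre-alignment composes the two canonical poses and is exact for exact
landmarks (left-handed left-ear frames compose to a proper rotation as long
as lateralities match, which is enforced).  Refinement maximises Mattes
mutual information (64 bins, 25 % random sampling with a fixed seed,
3-level pyramid with shrink 4/2/1, regular-step gradient descent, 256
iterations/level) through SimpleITK.  The similarity mask excludes
HU > 2500 (metal), the declared padding value or anything below −1024 HU
(invalid), and a 1-voxel border; it is applied to both images.  Failures
(vanishing mask overlap, optimizer exceptions) return the initial transform
with a warning and MI = NaN rather than raising, so the flagging stage can
react.  Registration quality is reported as the mean transfer distance of
the three landmarks.

## Failure flags

Seventeen flags across Image / Segmentation / Registration /
ElectrodeDetection categories; each compares one measurable against a
threshold, and flags whose inputs are missing stay unevaluated.  The
combined verdict is a weighted sum (default weights 1) of raised flags
against a cutoff (default 1.0, i.e. any flag cautions), except that
electrode *count* and *ordering* failures are hard flags that always
caution — array-reconstruction failures are not gradual.  All thresholds are
package defaults chosen for cochlear-scale anatomy, exposed in
`FlagThresholds`:

| threshold | default | rationale |
|---|---|---|
| max voxel size | 0.3 mm | coarser inputs are known to fail markedly more often |
| cochlear volume | 20–120 mm³ | generous bounds around the adult range (~35–100 mm³) |
| segmentation reliability | ≥ 0.6 | mean boundary-probability margin; binary labels give 1.0 |
| centerline kink | 60°/step | a smooth spiral turns ≤ ~30° per 18° step |
| segmented mean HU | −300…400 HU | intra-cochlear fluid is near 0 HU |
| mutual information | ≥ 0.05 | empty-overlap registrations score near 0 |
| landmark disagreement | ≤ 1.0 mm | ≈ 2–5 voxels at clinical resolutions |
| outside cochlea / outside ST | > 2 / > 4 contacts | basal contacts legitimately sit outside |
| non-basal outside | any contact with θ > 45° | a deep contact outside the labyrinth is never right |
| contact peak | ≥ 2500 HU | metal must exceed the masking threshold |
| pitch band | 0.6–2.4 mm | half to double the 1.2 mm device pitch |
| clustering | min spacing ≥ 0.6 mm | below half a pitch two detections are one contact |
| radial band | [MW min − 0.5, LW max + 0.5] mm | contacts live between the walls |
| boundary margin | 2 voxels | near-edge detections are truncation-prone |

On the corruption-fixture suite each flag fires on its targeted fixture and
none fire on the clean phantom run — sensitivity and specificity are 100 %
*by construction* on these synthetic cases; no claim about clinical rates
follows from that.

## I/O

Volumes are read via SimpleITK (NIfTI, MHA, DICOM series), reoriented to a
single LPS-aligned axis convention on load, and all modules share one world
convention: physical mm, axis order (x, y, z), voxel centers at
index·spacing + origin.  PII stripping is whitelist-based (geometry and
modality survive; anything else — names, IDs, dates, institutions — is
dropped, including fields we did not anticipate).  ROI crops pad with a
sentinel (−2048 HU) that the registration mask excludes; cropping twice with
the same center and side is idempotent.  Export bundles always contain JSON
and CSV tables (Parquet/Excel behind feature detection), STL meshes, and a
manifest with the pipeline version and input checksums.

## Known limitations

* Apical truncation of extracted centerlines is raster-sensitive by one
  angular step; prefer fixed-coverage duct lengths for comparisons.
* The phantom's idealisations (above) mean the reported accuracies are
  upper bounds on clinical performance; segmentation itself is out of scope
  and always supplied.
* The ellipse axes of two-duct (whole-labyrinth) sections describe a
  peanut-shaped outline and should be interpreted per scala instead.
* Problem sizes in the tests (0.1–0.2 mm phantoms, 10–12 mm fields of view)
  were chosen so the full suite runs in well under a minute per module while
  keeping ≥ 2 voxels across every structure of interest.
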