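# Methods

This note records how `condylometry` models the surface-comparison
protocol, the choices made where the protocol is underdetermined, and
what the synthetic experiments do and do not establish.

## Geometry carrier and units

All surfaces are indexed triangle meshes in millimetres.  STL input is
welded at 1e-6 mm (triangle soup → shared vertices); that tolerance is
three orders of magnitude below the 0.3 mm voxel scale, so welding is
topology repair, not smoothing.  Watertightness (every edge shared by
exactly two consistently wound faces) is required wherever an enclosed
volume or an inside/outside decision is needed, and is checked rather
than assumed.  ASCII STL is written with 9 significant digits under a
fixed header so exports diff reproducibly; colour-coded deviation maps
go to ASCII PLY with per-vertex RGB, because STL cannot carry colour
portably.

## Spatial queries

Closest-point queries prune candidates with a k-d tree over triangle
centroids (k = 8 nearest), then evaluate the exact point-to-triangle
distance per candidate.  In exact mode the candidate set is widened by a
ball query of radius (current upper bound + largest triangle
circumradius), which provably cannot exclude the true nearest triangle;
results then equal a brute-force all-triangle scan to 1e-9 mm, which the
tests verify against an independent implementation.  Inside/outside is
decided by the generalized winding number (van Oosterom–Strackee solid
angles summed over all triangles), robust near thin features; values
above 1/2 count as inside.

## Registration

*Landmark stage.*  Kabsch/Procrustes on the shared landmarks, no
scaling, with the SVD sign correction so a reflection is never returned
even when mirrored correspondences would fit better.  At least three
non-collinear shared landmarks are required.

*Best-fit stage.*  Trimmed ICP: moving vertices (deterministically
subsampled above 50 000) are matched to exact closest points on the
fixed surface; the worst 10 % of correspondences by distance are
rejected to tolerate partial overlap; the update is a Kabsch fit
(point-to-point, the default) or a linearized point-to-plane solve.
The vendor tools this emulates publish neither their variant nor their
trimming, so both the 10 % fraction and the variant are documented
constants, not reconstructions.

*Stopping rule.*  The precision contract is 0.01 mm.  Iteration stops
when the trimmed RMS plateaus: the last improvement **and** the
geometrically extrapolated remaining improvement (ratio of the last two
improvements, capped at 0.95) must both fall below precision/10
(0.001 mm), or 100 iterations elapse.  Plain change-thresholding stops
point-to-point ICP inside its slow linear tail well short of the
contract; extrapolation distinguishes that tail from a genuine plateau
(an irreducible shape difference, e.g. a uniformly offset shell, where
the RMS correctly settles at the offset).  Point-to-point then reaches
≤ 0.005 mm on jittered-landmark starts; point-to-plane reaches ~1e-4 mm
in about 3 iterations and is what the study pipeline uses.

## Condylar ROI

One plane — through Sg with unit normal along (Sg − Li) — bounds the
condylar unit from below; the Sg–Li segment itself is treated as the
construction line, not a second cut.  A single inferior cut matches the
"ROI below the sigmoid notch" reading; whether the original protocol
also cut along the Sg–Li plane (to remove the coronoid) is ambiguous in
its description, and this package's phantoms have no coronoid to
remove.  The plane is always computed from the *reference* model's
landmarks and applied to every registered test model, so deviation and
volume differences reflect surface error, never ROI redefinition.

Clipping splits crossing triangles exactly at the plane; the resulting
boundary loops are chained from the open edges and triangulated by ear
clipping in the plane's 2D frame, traversed in reverse loop order so
the cap's winding is consistent with the kept surface (making the
output watertight by construction, which is asserted).  With several
surviving components, the one nearest the requested side's Sg landmark
is returned — "largest component" cannot distinguish left from right
condyle when a near-horizontal plane leaves both standing.

## Deviation analysis

Deviations are sampled at test-mesh vertices; marching-cubes surfaces at
0.3 mm voxels are already at voxel-scale density, and a midpoint
densifier is available for coarser input.  The signed distance is
positive outside the reference (overestimation).  Magnitudes are
truncated at the 1.00 mm clamp with a per-sample flag; clamped samples
stay in matching-percentage denominators (they are necessarily out of
band, since tolerances may not exceed the clamp — enforced).  The
matching band is closed: |d| = tolerance counts as within.

Volume uses the divergence theorem (signed tetrahedra against the
origin) on watertight meshes; a negative sum means inward winding and
only the magnitude is reported.

Colour mapping: green inside ±tolerance, then a linear ramp to
saturated red at +clamp (overestimation) and to saturated blue at
−clamp (underestimation), matching the conventional reading of warm =
outside, cool = inside.

## Synthetic phantoms

The phantom solid is a generalized cylinder: at height z the
cross-section is the p-norm union (p = 8) of the head-ellipsoid section
and the neck/stub circle, times a low-order seeded modulation
(amplitude 2 %, three azimuthal harmonics tapered to zero at base and
pole) so each phantom is an individual with registration-relevant
features.  Because the boundary radius ρ(θ, z) is closed-form, the
volume of any height slab follows from quadrature of ∫ρ²/2 dθ — an
oracle independent of any mesh, used to validate both total and
ROI-clipped volumes (agreement to a few tenths of a percent at the
default refinement).

Default dimensions (head semi-axes 8.18 × 5.02 × 7.27 mm, neck radius
3.1 mm, flare 5.2 mm) were fixed once so the enclosed volume is
≈ 1632 mm³, the centre of the clinically observed condylar volume
range; the study varies phantom scale by ±4 % to emulate anatomical
spread.  Landmarks are placed analytically: Sg on the surface at
mid-neck height with Li straight below it (so the condylar cut plane is
exact), and four registration landmarks on the ramus stub.

*Voxelization.*  Inside/outside on the 0.3 mm grid is decided by
z-column crossing parity (even–odd of triangle intersections per
column); the grid is offset by a fixed irrational fraction of the
spacing so no column passes exactly through an edge, with deterministic
fallback offsets if a degenerate column still appears.

*Segmentation simulation.*  The binary volume is blurred with a
Gaussian (default σ = 0.45 mm, 1.5 voxels) as the partial-volume
surrogate, optional white noise is added, and the result is binarized
at the operator threshold.  Across a blurred step edge the intensity is
I_out + (I_in − I_out)·Φ(−s/σ), so the threshold that places the
boundary at a chosen signed offset is available in closed form —
`threshold_for_offset` — and thresholds below the midpoint overestimate
while those above underestimate, monotonically.  The largest connected
component is kept and holes filled (the cleanup every tool applies),
the mask is surfaced by marching cubes at the 0.5 level, and one fixed
Taubin pass (λ = 0.5, μ = −0.53, 10 sweeps, uniform umbrella weights)
stands in for the renderers' "un-voxelize" smoothing; it is a
documented constant, not a reconstruction of any vendor's filter.  The
blur default matters: at σ = 0.6 mm the curvature term of Gaussian
blurring (≈ σ²·H) pulls the midpoint iso-surface ~0.04 mm inward on
these radii, while at 0.45 mm the midpoint bias measured on the phantom
is ≈ −0.007 mm and imposed ±0.2 mm offsets are recovered within
0.04 mm.

*Rating tables.*  Repeated volumetric readings are simulated as
truth + fixed rater bias + rater random effect + fixed occasion drift +
residual noise, giving exact control of the ICC's variance components.

## Statistics

Midranks everywhere.  Kruskal–Wallis applies the tie-correction factor
and a χ²(k−1) p-value.  Mann–Whitney U is exact by full enumeration of
rank splits for combined n ≤ 10 (valid under ties, since the midranks
themselves are permuted) and otherwise normal with tie and continuity
corrections; Wilcoxon signed-rank drops zero differences (noted),
enumerates all 2ⁿ sign patterns for n ≤ 12 remaining pairs, and
otherwise uses the corrected normal approximation.  Two-sided exact
p-values sum both tails at or beyond the observed statistic.  All four
are verified against independent oracles (scipy, pingouin, and
test-side enumerations) to 1e-10.

ICC forms follow the conventional mapping where the original reports
give none: test-retest of one operator → ICC(3,1), two-way mixed,
consistency; between-operator → ICC(2,1), two-way random, absolute
agreement.  Both come from the same two-way ANOVA decomposition (data
centred first for conditioning), are labelled in every output, and a
zero between-subject variance raises an explanatory error rather than
returning 0/0.  Post-hoc Mann–Whitney p-values are reported raw *and*
Bonferroni-adjusted, since the emulated protocol names no correction;
the significance labels use the adjusted values.

The distributional gate mirrors routine practice: Shapiro–Wilk per
group plus Levene across groups, with any p < 0.05 routing to the
nonparametric branch; a constant sample (Shapiro undefined) routes
nonparametric with a note.

## Study pipeline

Each synthetic case: build the phantom, voxelize once, then per method
derive the threshold from the method's boundary offset, segment, apply
a seeded rigid misalignment (≤ 10°, ≤ 5 mm — each tool exports in its
own frame) with 0.3 mm landmark-picking jitter, register back, cut the
ROI with the truth plane, and measure.  The four default methods are
two bias regimes per side of the truth (±0.10, ±0.18 mm) with image
noise σ = 6 intensity units on a 0–100 contrast: the mechanisms, not
any specific product, are what is modelled.  The manual reference row
reports its own ROI volume with 100 % matching by definition.

Summary tables report per-method medians with bootstrap standard errors
of the median (2000 seeded resamples — the only self-consistent SE for
a median), minima and maxima; matching tables cover test methods only.
The simulated operator model gives the manual method larger
repeatability noise (9 mm³), a 65 mm³ second-operator bias and a
−7 mm³ re-reading drift, versus 4 / 8 / 2 mm³ for software-driven
methods — reproducing the qualitative pattern that manual segmentation
is expertise-sensitive while semi-automatic methods are highly reliable.
All randomness derives from the config seed; reruns are byte-identical,
and CSV floats are written at fixed precision to keep them so.

Problem sizes — 10 condyles, refinement level 3 (~10 000 faces),
0.3 mm voxels, 4000 ICP samples, 2000 bootstrap/null replicates — were
chosen as the package's standard desk-scale configuration; a full study
completes in about a minute on one CPU.

## What the synthetic experiments show — and do not

The phantoms establish that the *pipeline* is correct: registration
recovers known motions to the stated precision, deviations equal an
independent distance oracle, matching percentages follow the Gaussian
closed form under controlled noise, volumes match analytic solids, the
threshold-bias mechanism has the right sign and monotonicity, and the
statistics match enumeration.  They do not reproduce clinical numbers:
real condylar surface error is spatially structured (disc interface,
cortical thinning, FOV noise gradients), not a uniform offset plus
white noise, and no CBCT physics (beam hardening, scatter) is
modelled.  Absolute matching percentages from the original protocol are
additionally not bit-reproducible because the vendor tool's sampling
density and distance convention are unpublished.

## Known limitations

- Ear-clipping caps assume the cut loops are simple polygons (true for
  plane cuts of watertight genus-0 surfaces); nested loops (genus > 0
  cuts) are not supported.
- The parity-fill voxelizer assumes the mesh has no self-intersections.
- ICC "exact" shift-invariance of the consistency form holds to
  floating-point round-off (≈ 1e-14 relative), not bitwise.
- File mode expects the reference entry to be named `manual` and
  landmarks to use the package's fixed landmark vocabulary.
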