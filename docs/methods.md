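# Methods

This note documents the models, conventions and numerical choices
behind `osteoguide`, and what the synthetic study does and does not
emulate.

## Coordinate conventions and units

Everything is in millimetres. STL carries no units, so the loader
asserts nothing; millimetres are the package-wide convention. The
fibula frame is right-handed with +Z proximal along the shaft and +X
vestibular (the flat, guide-contact surface of the bone). Segments are
listed in chain order from proximal to distal, and each segment's cut
planes carry **outward** unit normals (pointing away from the segment
interior), which fixes every angle and mating sign below.

## Synthetic fibula and virtual plan

The fibula analog is a watertight extruded tube with a
rounded-triangular cross-section `r(φ) = 1 − e·cos 3φ` (triangularity
`e`, default 0.18), scaled so the vestibular–lingual X extent equals
`cross_section_width` (default 14 mm, a typical fibula diaphysis) and
oriented with its flattest side facing +X. An optional circular bow of
curvature κ displaces the centreline in +Y with sagitta κL²/8; cut/plane
intersections along bowed vertex columns are solved in closed form
(quadratic in z), so ground truth stays exact.

A three-segment plan places four cut sites along the shaft: two
transverse terminal cuts and two inter-segment joints. Each joint
removes a closing wedge: the two mating planes share an apex line on
the vestibular edge and are tilted by ± half the wedge angle about the
horizontal (Y) axis, so the wedge opens lingually — the physically
realisable cut, and the reason the vestibular length `L_vest` exceeds
the lingual length `L_ling` of a planned segment. Default vestibular
lengths are (30, 32, 30) mm with 45° wedges, which leaves the middle
segment's lingual length at 20.4 mm, just above the 20 mm perfusion
minimum that the plan validator enforces. Planned neomandible poses are
computed by exactly the same plane-mating chain used for executed
segments (below), so the planned assembly closes every wedge with zero
gap by construction.

Segment meshes are built analytically — each cross-section column is
intersected with the segment's two cut planes, the side surface lofted
between them and the ends capped with planar fans — rather than by
general mesh booleans. This gives exact, watertight ground truth with
labelled cut faces and no boolean robustness failures.

## Executed-cut perturbation model (the study conditions)

The physical study reports deviations, not error distributions, so the
generator imposes a simple additive model per cut plane: a translation
along the segment axis ~ N(shift_mean, shift_sd), an outward bias
`outward_shift_mean` along the face's outward axial direction (positive
= segment lengthening = over-contouring), and a normal tilt
~ N(tilt_mean, tilt_sd) about a uniformly random in-plane azimuth. For
the bilaterally walled slot designs the tilt is rejection-sampled to
the groove bound θ_max = arctan((slot − kerf)/height), which is the
mechanism through which guide height and instrument kerf act. Every
segment plane is perturbed independently (each cut passes through its
own slot; two planes per segment, 540 per default study).

Fixed default conditions, chosen once as plausible for guided
osteotomies (sub-millimetre positioning, few-degree tilts):

| cell          | shift_sd | tilt_sd | outward bias | truncated |
|---------------|----------|---------|--------------|-----------|
| SS, saw       | 0.4 mm   | 2.0°    | +0.3 mm      | yes       |
| AS, saw       | 0.4 mm   | 2.0°    | 0            | yes       |
| FS, any       | per-instrument | 3.0° | −0.2 mm   | no        |
| piezo (SS/AS) | 0.35 mm  | 1.8°    | as design    | yes       |

The signs mirror the qualitative in vitro findings (standard slot
over-contours, flange under-contours and tilts more for lack of a
second wall, anatomical slot tracks the plan). What the generator does
**not** emulate: scan segmentation noise, surface roughness of a real
kerf, blade deflection dynamics, soft tissue, or operator learning
effects — so green tests demonstrate the correctness of the measurement
chain, not the physical error magnitudes of any particular guide.

Randomness: each fibula gets an independent `SeedSequence((master,
cell_index, replicate))`; per plane the draw order is shift, tilt
(with rejection), azimuth. Everything downstream is reproducible from
the master seed alone.

## Measurement

Cut faces are found by region growing over mesh faces whose adjacent
normals agree within `planarity_tol` (default 5°), keeping regions with
area ≥ `min_area` (default 20 mm²) that are also globally planar within
the tolerance; the two largest become proximal (+principal-axis side)
and distal. The principal-axis sign convention (largest component
positive) stands in for the leg-positioning reference of a real
digitisation, and sidecar vertex labels can bypass detection entirely —
the study runner uses the generator's ground-truth labels by default,
mirroring manual marking.

Planes are fitted by total least squares (centroid + smallest scatter
direction of the SVD), which is rotation invariant and closed form;
degenerate inputs (two smallest scatter directions below 1e-12 of
scale) are rejected. `fit_rms` is the RMS orthogonal residual.

Lengths are the signed axial distances between the two cut planes
measured along the **planned** axis through named points of the
mid-slab silhouette: `L_vest`/`L_ling` at the ±X extremes, `L_max` /
`L_min` over all boundary points. Because the length field is linear in
position, these extremes are well defined and analytically checkable
(a cap tilted by θ over width w spreads the lengths by exactly
w·tan θ). Deviations are executed − planned, over-contouring positive.
Cut-angle deviation is the angle between executed and planned outward
normals (the planned-vs-executed choice, rather than an absolute
leg-based reference, is deliberate and documented here).

## Assembly, alignment and global deviation

`mate_planes` maps a moving cut plane onto a fixed one: plane points
coincide, outward normals oppose (bone contact), and the moving
vestibular direction aligns with the fixed one projected into the
contact plane — a deterministic osteosynthesis surrogate with no roll
freedom and zero joint gap, avoiding any manual repositioning. Segment
1 mates to the planned proximal cut pose (with inward normal, playing
the remnant mandible); segment *i* mates to segment *i−1*'s placed
distal cut. Executed cut-angle errors therefore propagate through the
chain exactly as a screwed plate with full plane contact would carry
them.

Best-fit alignment is point-to-point ICP on (seeded) subsampled source
vertices with KD-tree correspondences and closed-form Kabsch updates;
reflections are always excluded (det R = +1) so anatomy cannot mirror.
Point-to-point correspondences can stall in shallow azimuthal minima on
near-tubular meshes, so the search is multi-started from centroid
alignment composed with small rotations (0°, ±4°, ±8°) about the
target's principal axis, keeping the lowest final RMS. RMS is
non-increasing across iterations by construction; convergence is an RMS
change below 1e-6 mm.

The U-distance is the distance between the two most laterally exposed
points, operationalised as the extreme vertices along the planned
lateral axis (the line between the planned end-cut centroids). When
several vertices tie for an extreme — flat end faces perpendicular to
the axis — the farthest pair across the tied sets is taken, which makes
the measure deterministic and isometry invariant. ΔU is reported after
best-fit alignment; the raw assembly-frame value is recorded alongside.

Heat-map distances are exact point-to-triangle (vectorised
closest-point-on-triangle with KD-tree candidate pruning over triangle
centroids; the pruning radius uses the largest centroid-to-vertex
radius, so no candidate can be missed). Distances are unsigned by
default; a signed variant (positive outside the planned surface) is
available behind a flag.

## Statistics

Friedman (within-block mid-ranks, tie-corrected), Wilcoxon signed-rank
(W⁺ over mid-ranked |d|, zeros dropped) and Kruskal–Wallis (tie-
corrected H) are implemented from their formulas. Reference
distributions depend on sample size: Wilcoxon is exact (full sign-
pattern distribution) for n ≤ 20 without ties, else a tie- and
continuity-corrected normal approximation; Friedman enumerates all
within-block rank permutations when that enumeration is ≤ 250 000,
falls back to a seeded 200 000-draw Monte-Carlo permutation null for
moderate designs, and uses χ²(k−1) at study scale, where the
approximation is accurate — at 5×3 the χ² tail can be off by ~0.1, so
small samples get the permutation treatment; Kruskal–Wallis likewise
uses a seeded permutation null for pooled N ≤ 30. A `method` argument
forces any reference. Quartiles are type-7 (linear interpolation);
whiskers are Tukey 1.5·IQR, clamped to data.

The study runner's mapping of comparisons — slot design and guide
height via Friedman blocking on all other factors, instrument via
paired Wilcoxon, per-segment and U-distance contrasts via
Kruskal–Wallis — follows the paired/independent structure of this kind
of factorial accuracy study and is an explicit assumption. Post-hoc
pairwise comparisons carry no multiplicity correction by default.

## Problem sizes and performance

Default meshes use 48 circumferential × 48 axial vertices per shaft;
the full 90-specimen study including reconstruction and heat maps runs
in well under a minute on one CPU, and the acceptance script (two full
studies plus the reference computations) in about one minute. ICP
subsamples at 2000 vertices; heat maps are computed on every fused
vertex.

## Known limitations

* The perturbation model is Gaussian and per-plane independent; real
  cut errors are likely correlated within a specimen and skewed.
* Plane mating assumes perfect bone-to-bone contact at the cut
  centroids; plate bending and screw placement are out of scope.
* The U-distance extreme-vertex definition depends on the planned
  lateral axis; strongly asymmetric executed constructs could expose a
  different vertex pair than a clinician would palpate.
* Detection assumes planar osteotomies; curved cuts are out of scope.
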