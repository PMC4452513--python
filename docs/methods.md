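# Methods

This note documents the model assumptions, the numerical choices, and the
limits of what the synthetic validation shows.  It complements the API
docstrings; nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Shape model and assumptions

A root system at acquisition time t is a finite set of voxels 𝕍ₜ on an
integer grid with a physical edge length (mm).  Three assumptions carry
the whole construction:

* **A1 — additive growth.**  Roots grow only by elongating at tips and by
  adding branches at forks, so 𝕍ₛ ⊆ 𝕍ₜ for s ≤ t (after registration).
  This is why registration can always use the earliest shape as the
  contained reference, and why the final shape can carry the whole
  history.
* **A2 — tree topology.**  The shape is connected and loop-free.
  Disconnected inputs are reduced to their largest component with a
  warning.  Loops (touching branches) are tolerated: loop-closing arcs
  are ignored during decomposition (first-spanning-tree behaviour) and
  counted by a heuristic — an intra-component arc whose endpoints share
  no third mutually adjacent voxel closes a non-local cycle.  The
  heuristic sees point contacts but under-counts area contacts; actually
  separating touching branches is out of scope.
* **A3 — dense sampling.**  When a side branch first appears it is still
  shorter than its parent.  This is what makes depth/time conflicts at
  forks diagnostic of a mis-classified through-branch (see switches).

The voxel graph joins 26-neighbours with weights 1, √2, √3 voxel edges
(face/edge/corner).  An integer-weight variant (1, 2, 3) is available for
comparison but not used by the pipeline: geodesic depth is meant to
approximate Euclidean within-shape distance.

**Known limitation — chamfer bias.**  The 1/√2/√3 metric overestimates
Euclidean length by up to ~8% in a coordinate plane (worst near 22.5°
tilt) and ~12% for skew directions, and is exact along lattice axes and
45° diagonals.  Branch lengths and tortuosities inherit this bias for
tilted branches, partially offset in curved tubes by inner-wall
shortcuts and at junctions by corner cutting.  This is the dominant error
term in the validation and the reason curved-branch tortuosity errors
average ~5–7% rather than ~1%.

## Registration

Coarse alignment searches randomized 4-point bases: wide (≥ 25% of the
diameter), approximately coplanar quadruples from the earlier shape whose
diagonals intersect; congruent candidates in the later shape are found by
matching both pair lengths and the two intersection ratios (affine
invariants), each candidate is turned into a motion by least-squares
(Kabsch) fit, and candidates are scored by the fraction of an
earlier-shape sample within δ (default one voxel edge) of the moved later
shape — under A1 the true motion scores ≈ 1 no matter how much the root
grew.  The identity motion is always scored as a baseline so
pre-registered series cannot be degraded, and the search exits early at
score ≥ 0.95.  Point-to-point ICP then refines the motion; samples are
drawn from the earlier (contained) shape so new growth cannot bias the
correspondences; the per-iteration RMS is non-increasing by construction
and iteration stops when it improves by < 10⁻⁵ mm (cap 60).

Alignment quality is reported as the mean distance from a 10% sample of
the first shape to each aligned shape, in voxel edges; shapes beyond
10.00 edges are excluded from the analysis and logged.

## Seed area and depth

The seed area anchors the depth function; consistency across the series
matters more than biological exactness, so it is detected once on the
final shape and propagated backwards by the rigid motions (each mapped
seed voxel claims its nearest voxel in the earlier shape).

Detection flags voxels whose neighbourhood within radius R (voxels) is
both *isotropic* (smallest/largest covariance eigenvalue ≥ 0.6) and
*filled* (occupancy of the R-ball ≥ 0.5).  The occupancy condition is
ours: rounded branch tips are isotropic but half-empty, a seed blob
interior is both.  R defaults to twice the estimated mean branch radius
(at least 3 voxels), following the guidance that R should lie between one
and two branch radii — with R at or below the branch radius every
tube-interior neighbourhood looks isotropic and detection degenerates.
The branch radius estimate is 3× the mean interior distance-to-boundary
(Euclidean distance transform), exact for solid tubes.  If no voxel
qualifies, or the qualifying set exceeds 25% of the shape, the seed falls
back to the voxel nearest the centroid of the topmost horizontal slice
(z is up; gravity is −z).

Depth is multi-source Dijkstra from the seed area (scipy's compiled
implementation); all seed voxels are at distance 0 and |φ(u) − φ(v)| is
bounded by the arc weight along every arc.

## Branch decomposition

Voxels are traversed in decreasing depth (ties broken lexicographically);
an arc activates once both endpoints are visited.  Components carry their
deepest voxel as *tip*.  When an arc (u, v) joins two components with
tips p (shallower) and q: if the protrusion φ(p) − φ(u) is below the
merge threshold the whole component is absorbed into q's branch,
otherwise p's branch is consolidated with fork v and parent q.  The merge
threshold defaults to twice the estimated branch radius: stubs shorter
than a branch is thick are surface noise, not branches.

Arcs that activate together are ordered by the depth of the other
endpoint's current component tip (deepest attachment first).  This
dynamic order — rather than a static sort by endpoint depths — makes the
algorithm reproduce deepest-path-first semantics exactly at junction
voxels even under depth ties, which the test suite verifies against a
brute-force oracle on random lattice trees.

## Time function and switches

τ is initialized to T and built back-to-front: each tip of 𝕍ₜ is matched
to its nearest final voxel v (gated at 5 voxel edges to prevent
wrong-branch stamping; farther matches are skipped and logged), and all
members u of v's branch with φ(u) ≤ φ(v) receive τ(u) = min(τ(u), t) —
the earliest observation wins.

A fork v of child branch p is *in conflict* when p carries material older
than v itself (min τ over p's members adjacent to v is below τ(v)) —
impossible under A3 unless the depth-based choice of through-branch
contradicts the growth order.  The repair *switch* reassigns the parent's
stretch up to depth φ(v) to p, clamps the reassigned times to τ(v), and
makes p the through-going branch; children whose forks moved migrate with
the stretch.  Forks are scanned in increasing depth and the scan repeats
to a cap of 10× the fork count.  A final pass clamps junction-surface
voxels that sit shallower than a fork yet carry a younger time (painting
artifacts of the per-branch stamping); repairs only ever lower τ.  On
consistent series zero switches occur; a constructed out-growth scenario
(side branch appears short, out-grows its parent by T) triggers exactly
one.

## Traits

All traits are evaluated on sublevel sets 𝔹ᵢᵗ = {v ∈ branch i : τ(v) ≤ t};
a branch counts as present at t only once it has material deeper than its
fork (junction-surface voxels alone, stamped through a neighbouring
branch's match, do not constitute a branch).  The tip at time t is the
deepest member.  Length is φ(tip) − φ(fork); for the topmost branch, which
has no fork, length is φ(tip) and the chord is measured to the branch's
shallowest member.  Average radius √(V/(πL)) assumes a circular
cross-section.  Axis-based angles use the major covariance eigenvector of
the member coordinates; axes are orientation-less, so angles are folded
into [0, 90]°, and the topmost branch's angle-to-parent is 0 by
definition.  Tortuosity of branches only a few voxels long is
discretization-dominated and may fall below 1 (hand measurement shows the
same); the invariant τ ≥ 1 − 0.05 is only meaningful for branches with
some extent.

The biological classification is geometric and provisional: topmost
branch → primary; fork inside the seed area → seminal; fork above the
seed area's bounding box → crown; otherwise lateral.  A lone branch
emerging above the seed annexes the stem and forks at the seed boundary
(classified with the seminal group); in a crown whorl the shallower
members fork on the stem above the seed and are recognized as crown
roots.  Elongation-rate-based crown detection is not implemented.

## Synthetic models

A synthetic branch is the set of voxels within a (possibly linearly
tapering) radius of a curve truncated at a per-timepoint tip arc length —
a swept ball with hemispherical caps at both ends.  Curves are built from
tilt profiles (tilt to the vertical varying linearly — a circular arc —
or relaxing exponentially, as gravitropic bending does) or as constant-
pitch helices (root waving); specification sets are validated against A1
(schedules non-decreasing), A2 (parent links form a tree) and A3
(children shorter than parents at first appearance).  Optional per-
timepoint random rigid motions (returned as ground truth) exercise the
registration; optional voxel dropout exists but defaults to off.

Ground truth per branch and time: arc length, chord, tortuosity =
arc/chord, cylinder volume π∫r(s)²ds, and a cap/junction-corrected swept
volume (cylinder + two hemisphere caps − the stretch buried inside the
parent, found by walking the curve until it exits the parent tube).

The stock three-timepoint validation model has a straight vertical
primary (growing 63.8 → 95.2 mm, radius 1.5 mm) and six gravitropic
laterals with radii 1.0/0.885/0.685 mm appearing at t = 0, 1, 2, always
shorter than their parents at first appearance; branch lengths per
timepoint follow the hand-measured geometry of the printed validation
models this fixture emulates.  The curved validation suite is three
circular arcs (tilt ranges 35→5°, 50→10°, 45→0°, azimuths 20°, 0°, 300°)
and two helices (pitch 15°/1 turn, 20°/1.5 turns), all radius 1.5 mm.
All validation runs use a 0.5 mm voxel edge; registration robustness
tests use half-scale models at 0.7 mm to keep the suite fast.  Problem
sizes are a few thousand to ~13,000 voxels per shape.

**What passing these tests does not show.**  The generator produces
clean, exactly nested tubes.  Real reconstructions have surface noise,
thickness loss, touching branches (A2 violations), missed thin laterals,
and imperfect frame-to-frame consistency; the exclusion threshold, the
tip-match gate, and the switch repair exist for those regimes but are
exercised here only through constructed scenarios.  Absolute volume
accuracy on real data is limited by the reconstruction, not by this
pipeline.

## Determinism

Every randomized step (base sampling, scoring subsamples, ICP sampling,
perturbation motions) draws from a generator seeded through a single run
seed; depth ties, traversal ties and component ties are broken
lexicographically.  Re-running with the same inputs and seed reproduces
all outputs byte-for-byte, which the test suite asserts.
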