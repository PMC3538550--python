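# Methods

## Scope and abstraction

`dnaxis` models a DNA duplex purely geometrically: a smooth axis curve
plus canonical B-form parameters (3.4 Å rise, 10.4 bp/turn) determine
every atom position.  It is a *shape* tool, not a chemistry tool —
sequence-dependent geometry (roll, slide, propeller), nicks, mismatches
and energetics are out of scope; a built model is intended as a starting
point for external refinement (e.g. Amber-style MD after PDB export).

## Axis curves

Curves are chains of quadratic/cubic Bézier segments with a shared
junction control point (positional continuity enforced to 1e-6 Å), open
or closed.  The global parameter u ∈ [0,1] is split uniformly across
segments; it is *not* arc length.  Arc-length queries go through
per-segment cumulative tables (64 panels per segment, 8-point
Gauss–Legendre each — effectively exact for the degree-≤3 speed
integrand) inverted by bracketed Newton iteration (5 steps inside the
bracketing panel, residual ≪ 1e-6 Å).  The public `arc_length` uses
adaptive quadrature (`scipy.integrate.quad`, relative tolerance 1e-9).

Degenerate tangents (coincident control points) fall back to a symmetric
finite difference with step 1e-6 in u; if the derivative is still zero
the curve is rejected with an error naming the segment.

### Samplings

*Adaptive* sampling (axis display): parameter intervals are subdivided
while the tangent swings across an interval by more than half the turn
threshold (default 5°, configurable), followed by a verification pass
that bisects around any vertex whose measured chord-to-chord angle still
exceeds the threshold.  A straight segment therefore yields exactly its
two endpoints.

*Uniform* sampling (base-pair anchors): open curves sample at arc lengths
0, s, 2s, … with s = 3.4 Å; a trailing remainder shorter than one
spacing is dropped rather than stretched, keeping the rise exact (the CLI
logs the model size).  The sample count uses `floor(L/s + 1e-6)` so arc
lengths that are exact multiples of the spacing up to float rounding keep
their final sample.  Closed curves use s = L/round(L/s) so the sampling
closes exactly; the realized spacing is reported on the result.

### Bead interpolation

Coarse-grained sequences are interpolated with a centripetal Catmull–Rom
construction (knot increments = √chord length), emitted as cubic Bézier
spans.  Centripetal parameterization avoids the cusps and
self-intersections uniform Catmull–Rom produces on unevenly spaced beads.
End tangents are one-sided; closed loops wrap.  The construction is
rigid-motion equivariant and passes through every bead exactly.

## Rotation-minimizing frames

Frames are propagated with the double-reflection method: reflect (t, n)
through the bisecting plane of the step chord, then reflect again so the
tangent maps onto the next tangent.  The method is second-order accurate
in the spacing and exactly preserves the out-of-plane direction on planar
curves.  Initialization is the deterministic rule "project +z onto the
plane ⟂ t₀, fall back to +x when t₀ ∥ z", which makes rebuilt models
bit-identical.  Frames are always recomputed from scratch after a curve
edit; there is no incremental update.

On closed curves the frames stay strictly rotation-minimizing; the
angular mismatch accumulated around the loop is *measured* (one extra
transport step back to the start, signed angle about t₀) and reported as
`seam_mismatch_deg`, never silently folded into the frames.  Strand
closure is instead carried by the twist schedule's adjusted pitch; user
twist offsets are applied on top and may reopen the seam — documented,
not prevented.  An exact-RMF ODE integration exists only as the test
oracle (a 10×-oversampled double-reflection sweep, agreement within 0.5°
total twist on a helical axis with DNA-realistic curvature).

## Twist schedule and sequence

θ_i = (i−1)·2π/B + a_i with B = 10.4 (open) or N/round(N/10.4) (closed,
so default twist = integer turns).  Offsets a_i interpolate linearly in
index between constrained pairs; before the first and after the last
constraint the offset is constant.  Angles are radians internally,
degrees at the CLI.  Positive twist is right-handed about the tangent.
Base pairs are 1-based everywhere.

The sequence defaults to the generic repeat (ACTG)* on the leading
strand; an explicit sequence of matching length is accepted as an
extension.  Pair ids are leading base + Watson–Crick complement.

## Base-pair templates

The four templates (AT, TA, CG, GC) are synthetic idealized geometry,
generated once by `scripts/generate_bp_templates.py` and frozen in
`_bp_geometry.py`:

* base heavy atoms in the standard base-pair reference frame (planar
  idealized bases; helix axis = +z, pseudo-dyad = +x, strand-I backbone
  side = +y);
* a generic C2'-endo sugar-phosphate backbone solved by least squares
  over standard bond lengths, bond angles and B-form torsion priors,
  subject to the helix symmetry x → R_z(2π/10.4)x + 3.4ẑ so that
  O3'(i)–P(i+1) is a proper bond (1.61 Å) in the default helix;
* strand II as the dyad image (x, −y, −z) of strand I, which makes the
  strands antiparallel and preserves backbone connectivity by symmetry.

Hydrogens are omitted.  Templates are rigid: where the axis curves
sharply, inter-residue O3'–P distances stretch and severe curvature can
clash atoms at the apex — accepted consequences of the shape-first
abstraction, to be fixed by downstream refinement.  Instantiation maps
local (x, y, z) onto (n, b, t) after rotating by θ_i about local z, a
pure rigid motion.

## PDB export

Fixed-column PDB v3, coordinates to 3 decimals (round-trip error ≤ 5e-4 Å
per coordinate).  Chain A holds strand I in build order (residues 1..N),
chain B holds strand II in its own 5'→3' order (pair N first, renumbered
1..N); a TER record (which consumes a serial) closes each chain.  Both
terminal residues keep their full phosphate group.  Serial numbers past
99,999 and residue numbers past 9,999 wrap modulo the field width with a
logged warning, preserving single-file export of very long strands.
Re-parsing an exported file and re-writing it is byte-identical.  The
chain/numbering scheme follows common nucleic-acid PDB conventions so MD
packages and viewers accept the files.

## Hierarchy, LoD and picking

Binary tree over anchor indices: a node of size m splits into ⌈m/2⌉ +
⌊m/2⌋ while m > 10.  Spheres are centroid-centered with exact
max-distance radius — cheap and exactly containing.

LoD classification is *defined per leaf*: a leaf's representation comes
from the distance between the viewpoint and its sphere (beyond `far` →
line, beyond `near` → ribbon, else atomic; defaults 500/5000 Å,
configurable — any screen-space criterion is render-specific and out of
scope).  Because centroid child spheres are not strictly nested in parent
spheres, a naive internal-node test can disagree with the per-leaf rule
near thresholds; each internal node therefore stores conservative bounds
(max over descendant leaves of d(C, C_leaf) ± r_leaf) and the traversal
prunes a subtree only when the bounds prove every leaf below classifies
identically.  The output is exactly the per-leaf classification, with
adjacent equal ranges merged.

Picking: anchors within `hit_radius` of the ray (point-to-ray distance,
ray = origin + t·d, t ≥ 0) qualify; the one nearest the ray origin wins,
ties to the smaller index.  Subtrees whose sphere inflated by
`hit_radius` misses the ray are pruned.  Both queries are tested against
brute-force scans (500 random rays/viewpoints over a ~1,000-bp random
smooth curve).

## Meshes

The "helicoidal double ribbon" is read literally as a double helicoid:
ribbon k ∈ {0,1} at pair i spans from the axis point o_i to
o_i + (w/2)·d_i with d_i = cos(θ_i + kπ)n_i + sin(θ_i + kπ)b_i.  Tying
the direction to the twist schedule makes local unwinding visible in the
ribbon view.  Defaults: width 9 Å, one cross-section per base pair
(`sides_per_bp` > 1 interpolates extra sections); visual choices,
configurable.  Tubes sweep a regular polygon (default 12 sides, rings
every 3.4 Å) along RMF frames; open ends are capped with apex fans,
closed paths weld the seam into a torus.  Triangles are consistently
wound and zero-area faces are dropped.  Export is VRML97
(IndexedFaceSet, per-vertex color when present) or OBJ (colors dropped
with a logged warning); both re-import exactly.

## Synthetic data and what the tests show

No external dataset exists for this tool; all test inputs are generated:
straight axes (exact closed forms), four-arc circle approximations
rescaled to exact lengths (closure, planarity, pitch adjustment), a
helical axis with DNA-realistic curvature (radius 50 Å, pitch 100 Å —
curvature radius ≫ rise, as for any physical DNA axis) for frame
accuracy, and correlated-random-walk bead curves for statistical
properties.  These cover the geometric contract completely, but say
nothing about chemical realism of real DNA beyond the idealized template
geometry, and the frame-accuracy bound is only demonstrated for
curvature radii ≫ the rise (tighter curves degrade gracefully but are
physically dubious anyway).

Problem sizes: the scale demonstration builds 10⁵ base pairs (≈ 2 s,
memory ∝ frames); the million-pair claim follows from the lazy design
(no per-atom storage) rather than from a routine full-size run.

## Known limitations

* B-form only; A-/Z-form parameter sets would need their own rise/twist
  and templates.
* No sequence-dependent base-step geometry; no hydrogens.
* Closed-strand closure acts on the twist schedule, not the frames; a
  large RMF seam on a strongly non-planar closed curve shows up as a
  visible discontinuity between pair N and pair 1.
* `import_points` reads coordinates only; occupancy/altloc logic of real
  PDB files is ignored.
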