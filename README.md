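# dnaxis

All-atom B-DNA models from smooth axis curves.

Structural models of whole DNA molecules — plasmids, loops, wrapped or
supercoiled stretches — are rarely available from experiment, yet
biologists building cell-scale scenes need them at atomic resolution.
`dnaxis` solves the geometric half of that problem: you describe the
*helical axis* of the duplex as a smooth space curve, and the library
produces a full atomic model of canonical B-DNA following that curve, of
arbitrary length and shape, open or circular, with per-base-pair control
over the twist.  The result exports to PDB for downstream refinement
(e.g. molecular dynamics) and to plain triangle geometry (OBJ / VRML97)
for 3D tools.

It is a library first (`import dnaxis`), with narrative scripts under
`examples/` and a thin `dnaxis` command-line front end.

## The model

The axis is a piecewise quadratic/cubic Bézier curve **C**, or a smooth
centripetal Catmull–Rom interpolant through a coarse-grained bead sequence
(one point per monomer, as from worm-like-chain simulations).  From **C**
the pipeline computes:

1. **Uniform sampling** `S_u = {o_i}`: points one helical rise apart in
   arc length (3.4 Å, the B-DNA rise).  On closed curves the spacing is
   adjusted to `L / round(L/3.4)` so the sampling closes exactly.
2. **Rotation-minimizing frames** `F_u = {(o_i, t_i, n_i)}`: an
   orthonormal frame at each anchor, transported by the double-reflection
   method so the frames carry no spurious torsion — a strand at rest is
   untwisted.  A planar axis keeps an exactly constant binormal.
3. **Twist schedule**: base pair *i* is rotated about the tangent by
   `θ_i = (i−1)·2π/10.4 + a_i`, with 10.4 bp/turn the canonical B-form
   pitch.  The offsets `a_i` are user constraints at chosen pairs,
   linearly interpolated in index between them and held constant outside —
   so pinning two pairs untwists (or overtwists) everything between them.
   Closed strands adjust the pitch to `N / round(N/10.4)` so the default
   twist makes an exact integer number of turns.
4. **Instantiation**: one of four idealized base-pair templates (AT, TA,
   CG, GC; 41 heavy atoms each, Watson–Crick paired, generic `(ACTG)*`
   sequence by default) is rigidly placed at each frame.  Atoms are
   generated lazily — a million-base-pair model stores only frames and
   angles.

Around the model sit a PDB writer (chain A = strand I 5'→3', chain B =
strand II 5'→3', byte-stable round trip), a bounding-sphere hierarchy
(binary halving, ≤ 10 pairs per leaf) for level-of-detail classification
(atomic / ribbon / line) and base-pair picking along a ray, and mesh
builders for the polyline, helicoidal double-ribbon and linker-tube
representations.

## Worked example

```sh
python examples/build_straight_dna.py
```

prints

```
base pairs:       101
atoms:            4141
mean rise:        3.4000 Å   (B-DNA rise: 3.4 Å)
twist per step:   34.6154°  (360/10.4 = 34.6154°)
pitch:            10.4000 bp/turn
wrote straight_dna.pdb (chains A and B, 101 residues each)
```

A 340 Å straight axis anchors 101 base pairs (340/3.4 + the endpoint);
each pair carries 41 heavy atoms; the measured rotation between
consecutive pairs is exactly one 10.4-bp-per-turn step.  The other
examples close a 147-bp minicircle (`circular_plasmid.py` — note the
adjusted 10.5 bp/turn pitch that makes 14 exact turns), back-map a
coarse-grained bead snapshot to 36,900 atoms
(`backmap_coarse_grained.py`), query level-of-detail and picking on a
3,769-bp strand (`lod_and_picking.py`), and export ribbon/tube meshes
(`ribbon_and_tube_meshes.py`).

The same pipeline from the shell:

```sh
dnaxis build curve.yaml -o model.pdb            # curve file -> PDB
dnaxis from-points beads.xyz -o curve.yaml      # beads -> smooth curve
dnaxis mesh curve.yaml --kind tube -o tube.obj  # geometry export
```

Curve files are YAML: a `closed:` flag and a `segments:` list, each
segment a row of 3 (quadratic) or 4 (cubic) control points in Å.  Twist
constraints are text lines `index angle_deg`.

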