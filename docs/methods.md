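# Methods

This note records the modelling choices behind `fetalecho`: what the
procedural hearts and the simulator do and do not represent, the
numerical conventions, and the limits of what the test suite shows.

## Coordinate conventions and units

All lengths are millimetres.  The canonical heart frame is x = fetal
left, y = fetal posterior, z = fetal cephalad, with the origin at the
centre of the four-chamber crux.  No anatomical frame is standard for
cast models, so this is a package convention; it matters only in that
the shipped view presets are expressed in it.  The probe/image frame
puts the transducer contact point at the top-centre of the image, x
lateral, y depth, z out of plane; a pose maps image to heart
coordinates, and its rigid inverse is computed analytically
($R^\top$, $-R^\top t$) so that frame-invariance holds to round-off.

## Procedural hearts

The generator emulates the *blood-pool* geometry a corrosion cast
preserves: chambers and vessel lumina as solids, no myocardium, valves,
or wall tissue.  Chambers are tapered ellipsoids (apex-narrowed for the
ventricles), vessels are tubes swept along interpolating cubic splines
with parallel-transported cross-section frames and flat end caps; every
structure is a closed, outward-oriented 2-manifold by construction.
Absolute sizes are mid-gestation defaults (ventricular long axis
~16-18 mm, great-artery radii 1.7-2.4 mm) appropriate to a 25-26-week
specimen; no published per-structure dimensions exist for such casts, so
these are plausible values fixed once, not fitted quantities.

Structures are allowed to interpenetrate slightly where they join.
Junctions that must register as *connected* (the arch limbs into the
aorta and descending aorta, the ductus into the pulmonary trunk and
descending aorta) bury a tube end ~0.45 mm past the partner's surface,
which guarantees an edge in the vessel-adjacency graph (defined by
mutual vertex containment).  Junctions that only need to *look*
continuous stop ~0.05 mm short of the partner's surface.  Overlap is
resolved by priority, assigned so that smaller structures win: the
double-counted junction volume is then charged to the larger partner,
keeping every structure's priority-resolved volume within ~4% of its
mesh volume — the budget that makes the digitisation round trip
meaningful.  A seeded sub-micrometre vertex jitter (sd 4 µm) breaks the
exact lattice and symmetry degeneracies that would otherwise produce
ray/edge ties in the parity tests; it is far below voxel and pixel
scale.

Case presets: `normal`; `double_aortic_arch`, where the ascending aorta
forks into left/right limbs shaped as up-and-over loops that rejoin the
descending aorta and encircle a trachea placeholder (the trachea is a
plain tube, radius 1 mm — a placeholder, not airway anatomy);
`hrh_vsd_mga_pa`, where the right ventricle is rescaled about a basal
fixed point so its mesh volume is exactly `rv_lv_ratio` (default 0.4)
times the left ventricle's, a septal channel of radius `vsd_radius`
(default 1.5 mm) runs between points 1.5 mm inside each ventricular
cavity, the aorta arises anteriorly from the RV, and the pulmonary
trunk's initial segment is absent (blind lower end, supplied only via
the ductus).  The perfusion-pressure distortion of real casts (structures near the
injection inlet over-inflated, distal ones compressed) is exposed only
as the `scale_factors` calibration hook (per-structure scaling about
the centroid), since no quantitative distortion model is available.

## Cast-CT emulation and segmentation

`rasterize` labels each voxel by the structure containing its centre
(priority on overlap), using the same watertight ray/triangle parity
machinery as the simulator, with one +x scan ray per voxel row.  The
grid origin is offset by an irrational voxel fraction (0.381966·h) so
lattice-aligned geometry is sampled without systematic bias.  The
default spacing (0.4, 0.4, 0.6) mm mirrors a clinical cast-CT protocol.
`add_acquisition_noise` produces a two-phase grey volume (air ~40, cast
~200 by default) with seeded Gaussian noise — enough to make
thresholding non-trivial, but with none of CT's beam hardening, partial
volume or streak artefacts.

Segmentation is deliberately automatic: global threshold, connected
components (components ordered by descending size, ties by scan order),
and naming by maximal Dice against a reference label volume.  This is a
faithful simplification for a two-phase resin/air cast; it does not
model the interactive contour refinement used on real data.  Because
cast lumina merge at the vessel junctions, the thresholded foreground is
essentially one component — anatomical naming must come from the
reference, which is why `match_labels` (and the reference-guided split
in the CLI) exists.

`extract_surfaces` runs marching cubes at level 0.5 per label after
padding (so border-touching labels still close) and 2× nearest-neighbour
mask upsampling, which halves the corner-chamfer volume bias that
otherwise pushes thin tubes (radius ~3 voxels) beyond the 5% round-trip
budget.  Smoothing is a volume-constrained Laplacian (default 15
iterations): it removes the staircase texture — bringing, e.g., a
rasterised sphere's surface area within a few percent of analytic —
while preserving the enclosed volume exactly, so volume checks are
independent of the smoothing setting.

## Simulator numerics

Ray/triangle intersection is watertight Möller–Trumbore with a single
epsilon policy (relative 1e-9 on barycentric inclusion, 1e-12 parallel
guard) shared by the BVH, the brute-force reference and the containment
tests, so accelerated and reference results agree exactly, including on
grazing hits — ties are *consistent*, not adjudicated.  The BVH uses
median splits on the longest centroid axis with 32-triangle leaves; its
build and traversal are deterministic.  A ray passing exactly through a
shared edge or vertex yields one hit per adjacent triangle; the fill
step collapses hits of one structure at one distance into a single
crossing (a balanced enter/exit group is a tangential graze and cancels),
and point-in-mesh queries cast along a fixed asymmetric direction to
stay off tessellation symmetry planes.

The intensity model is a constant grey value per material with optional
exponential depth attenuation and optional multiplicative speckle
(off by default) — matching the flat-filled appearance of
surface-model ultrasound simulators.  There is no wave physics: no
refraction, shadowing, enhancement, or reverberation.  The background
outside all structures renders black, the appearance of a cast scanned
in air.  Linear-probe scan conversion maps columns to scan lines
(nearest or bilinear); curvilinear conversion maps pixels to
(angle, radius) about the transducer arc centre with pixels outside the
fan set to 0.  Label slices always use nearest interpolation, since
structure ids must not blend.

Default probe: curvilinear, 60° field of view, 28 mm transducer radius,
55 mm depth, 160 scan lines × 256 samples, 300×300 pixels at 0.2 mm —
chosen so the whole mid-gestation heart fits the fan with clinical-ish
line density.  Sample i sits at depth (i+0.5)·Δ and pixel row r at
(r+0.5)·p, so a linear probe with Δ = p and matched counts is an exact
identity under nearest interpolation (the property the scan-conversion
tests pin down).

## Views and verification

The eight standard views ship as poses in `data/standard_views.yaml`
(4×4 row-major, full precision) with their required-structure sets
(e.g. four-chamber ⊇ {LA, RA, LV, RV}; three-vessel ⊇ {PA, AO, SVC};
bicaval ⊇ {SVC, IVC, RA}), following the usual clinical definitions of
the planes.  The poses were designed against the default generator
anatomy — plane anchors from structure centroids (the four-chamber
plane is the best-fit plane through the four chamber centroids, like a
tilted apical view), probe stood off 28 mm so the target sits
mid-field — and can be regenerated with `scripts/make_view_library.py`.
Published probe positions for such models do not exist; these presets
are package conventions validated by the verification step, not
reproductions.

`verify_view` runs on the label slice only (grey values are not
identity-preserving) and passes a view when each required structure
covers ≥ `min_pixels` pixels and each forbidden one does not.  The
default threshold, 30 pixels, is defined at 0.2 mm pixel spacing
(= 1.2 mm²) and should be rescaled via `scaled_min_pixels` at other
spacings; it is an arbitrary but fixed floor on "adequately
demonstrated".  A spec requiring a structure the model lacks fails the
report (with the unknown names listed) rather than raising, so the
normal presets can be applied to pathological models for comparison.
Pathology checks are pixel-topological on the slice: region counting
for the double-arch cross-sections, union-connectivity for the VSD
channel, 8-neighbour adjacency for the atretic trunk.  `find_view` is a
seeded hill climb over rigid perturbations (1 mm / 2° sd), accepting
score improvements; it is a convenience for recovering mildly
mis-specified poses, not an optimal planner.

## Problem sizes and determinism

Default tessellation (icosphere subdivision 3, 18-segment tubes,
~1.2 mm ring spacing) gives ~11k triangles per heart; a default frame
simulates in ~0.2 s and the full digitisation round trip at 0.4 mm in
~2 s, so the test suite and the acceptance script each run in well under
a minute.  Everything stochastic (vertex jitter, acquisition noise,
speckle, view search, acceptance rays) is driven by explicit integer
seeds through `numpy.random.default_rng`; repeated runs are
byte-identical with speckle off.

## Known limitations

Static anatomy (no cardiac motion), no myocardium or valves, no
acoustic physics, stylised vessel courses chosen to keep junction
overlap small rather than to follow specimen geometry, and a
segmentation stage that presumes the two-phase cast contrast.  Passing
tests therefore demonstrate the geometry/simulation pipeline is
self-consistent and reproduces the qualitative imaging signatures of
the modelled malformations — not that images match any real specimen.
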