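# Methods

`neuromorph` measures embryonic mouse brain morphology at two scales —
whole-organ iso-surfaces and apical epithelial cell lattices — and ships a
ground-truth phantom generator so that every measurement can be validated
end to end without access to imaging data. This note records the models,
the numerical choices, and what the synthetic data does and does not show.

## Organ-scale morphometrics

**Volume and area.** Surfaces are closed triangle meshes in mm. Volume is
the signed-tetrahedron sum V = Σ det(v₀, v₁, v₂)/6 over faces (divergence
theorem), exact for any closed, consistently wound triangulation and
translation invariant. Outward winding is validated first: an open mesh or
a negative signed volume raises instead of being silently repaired, because
a sign flip usually indicates an inverted segmentation rather than a
harmless convention. Area is the plain triangle-area sum. Both are
cross-checked in the tests against an independent mesh library and against
closed forms (sphere, cube, ellipsoid — the triaxial ellipsoid area uses
Legendre incomplete elliptic integrals), with tolerances tied to mesh
refinement (0.5% at icosphere subdivision 4) rather than one global
epsilon.

**Sphericity.** S = π^{1/3}(6V)^{2/3}/A, the area of the volume-equivalent
sphere over the actual area; 1 for a sphere and < 1 otherwise
(isoperimetric inequality). Mesh-measured sphericities are clamped at 1
within 1e-6 numerical tolerance.

**Cortical thickness.** The cortex is idealised as a hollow cylinder:
h = 2V_cortex/(A_outer + A_inner), with V_cortex the brain volume minus the
total ventricular volume, A_outer the outer brain area, A_inner the (uncut)
ventricular area. For true cylindrical side walls the formula reduces
algebraically to r_out − r_in; for thin concentric shells it recovers the
wall width to O((Δr/r)²); for thick, strongly curved shells it carries a
systematic thin-shell bias which we document and deliberately do not
"correct" — the printed formula is applied as stated. A per-lobe variant
(same formula on midline-split half shells) is available behind a flag and
labelled an interpretation, since lobe-wise area partitioning is not
otherwise defined.

**Ventricle separation.** The ventricular surface is split by the midline
plane (standing in for the septum pellucidum). Cutting uses plane slicing
followed by ear-clip triangulation of each (possibly non-convex) cut
polygon, so both halves stay closed and V, A, S remain defined. The two
half volumes must sum to the whole within 0.1% or the split errors out.

**Group summaries.** Mean and sample SD (n−1). Ventricle-level metrics
(volume, area, sphericity) are pooled across lobes — two brains give four
ventricle observations — while brain-level metrics count per animal,
matching how this kind of cohort is reported. The ± values in the emulated
study are treated as sample SDs, not SEMs: a cohort of two with ±0.002 is
only consistent with the SD of two values. No hypothesis test is run by
default (the emulated study reports none); a Welch t-test is available
behind `--test` and its raw p-values are labelled exploratory.

## Apical lattice morphometrics

Interior (non-border) cells of a 2D polygonal lattice are characterised by
neighbour number n, apical area, and elongation. Border cells are excluded
from all statistics because the field of view truncates their
neighbourhoods, but their own n still enters m(n) of interior neighbours.

**Adjacency from label images.** Two labels are neighbours iff they share
≥ 2 four-connected pixel contacts; the two-contact rule suppresses
corner-touch artifacts and stabilises trivalence at finite resolution. Its
flip side is a detection limit: a shared boundary shorter than two pixels
cannot produce two contacts, so true lattice edges narrower than ~2 px are
invisible in any raster. Voronoi lattices genuinely contain such sub-pixel
edges (lengths down to 10⁻³ µm), which is why the oracle-equivalence tests
compare extracted adjacency against the *resolvable* truth (true edges with
shared boundary ≥ 2 px must all be found; nothing outside the true
adjacency may appear). Under that comparison agreement is ≥ 99% of interior
cells at 0.1 µm/px, with zero spurious neighbours observed.

**Lewis' law.** Ā_n/Ā = (n−2)/4 relates the mean relative area of n-sided
cells to n. The empirical table reports observed Ā_n/Ā per polygon class
(classes with ≥ 5 cells; pooling of ≤4 and ≥9 classes is display-only) and
a count-weighted least-squares line. A lattice constructed to satisfy the
law exactly returns slope 0.25, intercept −0.5 to machine precision;
unrelaxed Poisson-Voronoi lattices give slopes ≈ 0.22, one Lloyd step
≈ 0.17 (established by simulation at 2000 cells, 5 seeds).

**Aboav-Weaire's law.** m(n), the mean neighbour number of the cells around
an n-sided cell, decreases weakly with n with n·m(n) linear in n. The
default reference is the standard form m(n) = 5 + 8/n (n·m(n) = 5n + 8),
consistent with trivalent topology and with our simulations
(fitted slope ≈ 5.3 on Poisson-Voronoi). A decreasing variant
m(n) = 5 − n/8 also circulates in print; it contradicts both the linear
n·m(n) description and measured lattices (it gives m(6) = 4.25 where
lattices give ≈ 6.3), so it is kept only behind `form="literal"` for
comparison and never used as the default reference.

**Aspect ratio.** Rather than an iterative boundary ellipse fit, each cell
outline's aspect ratio is computed from the closed-form second central
moment tensor of the polygon interior: the unique ellipse with identical
second moments has axis ratio sqrt(λ_max/λ_min). This is deterministic,
exact for polygons, and invariant under rotation, translation and uniform
scaling (verified to 1e-9 under 100 random rotations). 3D vertex loops are
first projected onto their own best-fit (principal) plane, a planar
stand-in for measuring on a curved apical surface; cell areas are likewise
planar, an approximation to geodesic areas on curved tissue.

**Topology.** In a trivalent periodic tessellation Euler's formula forces a
mean neighbour number of exactly 6; the pipeline reproduces 6.0 within 0.02
on ≥ 2000-cell periodic Lloyd-relaxed Voronoi lattices, and this is the
quantity `scripts/acceptance.py` recomputes.

## The synthetic-data generator

The generator emulates the two-genotype embryonic study whose printed group
statistics parameterise the defaults: wild type n = 2 with ventricular
sphericity 0.70 ± 0.01, intraocular distance 1.75 ± 0.002 mm, cortical
thickness 0.08 ± 0.02 mm, brain volume entered as mean 3.28 mm³ with the
two-value sample SD (the source gives two individual values, 3.41 and
3.15 mm³); heterozygote n = 5 with 0.67 ± 0.03, 1.85 ± 0.10 mm,
0.10 ± 0.03 mm, 3.60 ± 0.56 mm³. Group differences are simulated as shifts
of the configured means, not as a mechanistic tissue model: the emulated
claims are descriptive group statistics. Per-sample draws are independent
normals truncated (by redraw) to physical ranges — sphericity ≤ 0.97,
lengths and volumes > 0; at the configured SDs truncation is a ≥4σ event
and does not bias the means measurably.

**Brain phantoms.** The outer cortical surface is a smooth random radial
perturbation of an icosphere (amplitude 0.08 by default), uniformly scaled
so the enclosed volume equals the drawn brain-volume target exactly. The
ventricular system is a symmetric dumbbell: two prolate lobes (semi-axis
ratio k:1 along the midline axis, centres at ±0.95k) fused at a waist on
x = 0. Lobe elongation is tuned so each midline-split half has exactly the
drawn sphericity; because the map elongation → half-lobe sphericity depends
only on the fixed discretisation, it is precomputed once as a monotone
inversion table (320 log-spaced knots, inversion error ~1e-4 ≪ the
configured SDs). A vertex ring lies exactly on x = 0, so the pipeline's
plane split reproduces the generator's half-lobes identically. The overall
dumbbell scale is then solved (Brent) so the thickness formula, evaluated
with the measured outer and ventricular areas, returns the drawn thickness
target; pupil landmarks are placed exactly the drawn distance apart.

Two caveats are intrinsic to this construction. First, the emulated study's
printed values are not mutually consistent under its own thickness formula
(its volumes and areas imply ≈ 0.17 mm, not 0.08 mm), so a phantom hitting
every printed metric cannot also reproduce the printed ventricular volumes:
ventricular volume is emergent here (≈ 1.1 mm³ per lobe). Second, the
surfaces are measured independently downstream, so the phantom does not
enforce anatomical nesting of ventricles inside the cortex; the geometry is
schematic. Consequently, passing recovery tests demonstrate that the
measurement chain is unbiased and correctly propagates the generative
parameters — they do not certify performance on real iso-surfaces with
anatomical shape, contact artifacts, or segmentation noise.

**Lattices.** Voronoi tessellations of uniform random seeds in a box of
area n × 25 µm² (a typical apical cell area), optionally Lloyd-relaxed
(each step moves seeds to centroids; more steps → higher hexagon fraction),
periodic via 3×3 tiling (no border cells) or bounded via mirror-point
reflection (cells exactly clipped to the box, boundary-touching cells
border-flagged). Study defaults use 0 relaxation steps because unrelaxed
tessellations best match the printed apical frequencies (29–31% hexagons,
16–20% heptagons); rasterisation assigns each 0.1–0.2 µm pixel to its
nearest seed, which is exact for Voronoi cells. Label images are 16-bit
TIFF; everything is byte-identical under a fixed master seed
(per-sample seeds are spawned from a SeedSequence).

## Problem sizes and tolerances

Defaults were chosen so the full validation suite runs on a laptop-class
single core: icosphere subdivision 3–4 (0.5% closed-form agreement),
dumbbell discretisation 40 profile × 48 azimuthal samples, lattices of
150–2000 cells, recovery experiments of 20 replicate studies at 50 samples
per genotype (each group mean recovered within 3 SE of the configured
value). Split-volume conservation is enforced at 0.1%; law-recovery
constructions are checked at 1e-6; degenerate inputs (open meshes, inverted
winding, planes missing the mesh, all-border lattices, polygons with zero
area) raise errors rather than returning silently wrong numbers.

## Known limitations

* No image-to-mesh reconstruction, mesh repair, deconvolution or watershed
  segmentation: inputs are assumed to be clean closed meshes and label
  images, as exported by upstream tools.
* The hollow-cylinder thickness is a shape idealisation; on thick curved
  shells it underestimates the true wall width.
* Planar cell areas and per-cell tangent-plane projection approximate the
  curved 2.5D apical surface; geodesic areas are out of scope.
* The phantom cohort shares one blob family and one dumbbell family;
  biological shape variability beyond the four configured metrics is not
  modelled.
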