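# Methods

This note documents the models, numerical choices and known limitations of
`scalpmap`. It complements the API docstrings; nothing here reports an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Geometry conventions

All geometry lives in world millimetres, RAS orientation. Volumes carry a
4×4 voxel-index→world affine (0-based indices); NIfTI inputs are
reoriented to canonical RAS on load, so left/right labels are only as
trustworthy as the input header affine. Distances are never computed in
voxel units: paediatric acquisitions are frequently anisotropic (3 mm
slices with sub-millimetre in-plane voxels) and voxel-unit distances would
be wrong by up to 3×.

## Surface extraction

**Scalp mask.** The head/air interface is found by intensity thresholding:
supra-threshold voxels are hole-filled and the largest connected component
is kept. Hole-filling runs *before* component selection because, at a
mid-tissue threshold, the dark layers (CSF, compact bone) fall below
threshold and the bright shells (marrow, cutis) are disjoint from the
brain; filling reconnects them into one head component whose boundary is
the outer head surface. For phantom volumes the recommended threshold is
half the cutis intensity: the partial-volume ramp then crosses threshold
at the true boundary, making the mask edge unbiased. This operator is a
simplified stand-in for gradient-based scalp finding in full
skull-stripping tools and is not intended for artefact-laden clinical
scans.

**Isosurfaces.** Meshes are extracted by marching cubes at the 0.5 level
of an anti-aliased mask field. Running marching cubes on the raw binary
mask produces a staircase surface whose area overestimates a smooth
surface by ~9%; a one-voxel Gaussian pre-filter reduces the area error of
a 0.5 mm-voxel sphere mask to under 0.1% and makes vertex positions
sub-voxel accurate. Structures so small that the filter erases them
(e.g. a single voxel) are instead supersampled 2× with nearest-neighbour
interpolation so the surface wraps the voxel faces. Masks touching the
grid border are rejected (the surface would be open); callers pad
instead.

**Brain hull.** The envelope surface is built by morphological closing of
the brain mask with a Euclidean ball (default radius 10 mm), marching
cubes, and 10 iterations of uniform Laplacian smoothing (λ = 0.5). The
closing ball bridges concavities narrower than its diameter — sulci, the
interhemispheric fissure — while leaving convex cortex in place, giving
the "shrink wrap" behaviour the distance map needs. The closing is
implemented with two distance transforms (dilation = EDT ≤ r on the
background, erosion = EDT > r on the dilated set), whose cost is
independent of the ball radius; an explicit 41³-voxel structuring element
would be infeasible at 0.5 mm resolution. Two safeguards preserve the
enclosure contract (`hull ⊇ mask`): the closed mask is OR-ed with the
input mask, and the anti-aliasing field is floored to 1 at mask voxels so
the 0.5 level passes outside every mask voxel centre. Because Laplacian
smoothing shrinks surfaces slightly, vertices that end up inside the 0.5
level after smoothing are pushed back out along their normals in 0.1-voxel
steps until they sit on or outside it.

**Normals.** Per-vertex normals are angle-weighted averages of incident
face normals. Orientation is decided once, globally, by the sign of the
mesh's signed volume (faces flipped if negative) — not by per-vertex
heuristics, which fail on concave patches. Degenerate faces are skipped
with a warning.

**Ventral truncation.** Inferior head regions (ears, ear canals, skull
base, neck) have no meaningful brain-to-scalp distance. Vertices below an
axial plane — default 30% of the bounding-box height above the mesh
bottom, configurable or replaceable by an explicit world-z cut — are
flagged invalid; geometry is untouched so vertex indexing stays stable.

## Distance computations

**Normal-ray distance map.** From every valid hull vertex, a ray along
the outward normal is intersected with the scalp mesh; the distance to
the first hit is the map value. Rays with no hit within `max_distance`
(default 100 mm) are flagged invalid and excluded from summaries — this
is what removes ear pinnae, canal openings and other ill-defined regions.
Ray origins are nudged 10⁻³ mm *inward* along the normal (the distance is
still measured from the true vertex, clamped at 0): with an inward nudge a
scalp triangle locally coincident with the hull correctly yields distance
zero, whereas an outward nudge can never re-hit a coincident surface. The
scalp always lies outside the hull, so the inward nudge cannot cause
spurious self-intersections.

**Nearest-point distance.** The landmark-to-scalp distance is the exact
minimum over all triangles (interiors, edges, vertices — not a
vertex-only search, which would be biased by mesh resolution), with ties
broken to the lowest face index for determinism. Landmarks farther than
`max_distance` outside the scalp bounding box are flagged unverified
rather than silently returned.

**Exactness of the accelerated queries.** Both query types are written
in-repo (`_geometry.py`) because the contract is bitwise equality with
exhaustive scans, and the accelerated backends of general mesh libraries
(rtree/embree) are neither available here nor tie-break-deterministic.
The KD-tree acceleration only *prunes*: for rays, candidate triangles are
gathered by ball queries around sample points spaced h apart with radius
h/2 + (max triangle circumradius) — a superset of every triangle the ray
segment can touch; for nearest-point queries, the nearest-vertex distance
gives an upper bound and all triangles whose bounding sphere could beat
it are tested exactly. Tests assert exact equality against brute force on
meshes up to 2,000 faces.

**Slice-constrained distance.** The scalp mesh is sectioned by the axial,
coronal or sagittal plane through the landmark (via exact mesh–plane
intersection) and the minimum point-to-segment distance to the resulting
contour is returned. Restricting the feasible set to one plane can only
increase the minimum, which is the point: it quantifies the bias of
measuring on 2D slices.

## Phantoms

The head phantom is a brain ellipsoid wrapped in four shells — CSF +
inner table, marrow, outer table, cutis — whose boundaries are ellipsoids
with semiaxes grown by the cumulative shell thickness. Semiaxis inflation
is an approximation to a true constant-offset surface: exact for spheres,
and within a few % of the nominal gap for mild eccentricity (a
60/50/45 mm ellipsoid with a 7 mm nominal gap shows < 5% deviation along
normals; the test suite measures this bound by dense sampling). Every
test that needs exact truth therefore uses concentric spheres, where the
gap equals the thickness sum in all directions. `PhantomTruth` evaluates
distances analytically for the *inflated* geometry (quadratic
ray–ellipsoid intersection; Nelder–Mead surface minimisation for
nearest-point truth), so phantom and truth are always mutually
consistent.

Voxel intensities take the T1-like values brain 100, CSF/inner table 30,
marrow 180, outer table 30, cutis 180, air 0 (arbitrary units; the
invariant is fat-bright/fluid-dark contrast), with a one-voxel linear
ramp at each boundary emulating partial-volume averaging. The ramp is
what makes 0.1 mm interval recovery possible at 0.5 mm voxels: the
mid-intensity threshold crossing sits at the true boundary, whereas a
hard-step voxelisation localises edges only to half a voxel.

Default shell thicknesses are the two study conditions the interval
analysis distinguishes — newborn (3.4, 2.2, 0.8, 1.2) mm and child
(7.0, 2.8, 1.5, 1.5) mm for (CSF+inner table, marrow, outer table,
cutis). Requesting a voxel size larger than the thinnest nonzero shell is
an error (the shell would vanish from the grid).

Phantom landmarks are placed where rays from the centre along canonical
unit directions meet the brain surface: poles and vertex at the
coordinate extremes; the parieto-occipital-sulcus pair at fixed
posterior-superior parasagittal directions and the inferior-frontal pair
at lateral-anterior-inferior directions (a configurable dictionary),
since an unfolded ellipsoid has no sulcal anatomy to anchor them.

## Cohort simulation

Each (landmark, hemisphere) stratum follows D = a·t + b + ε,
ε ~ N(0, σ²), ages uniform on 0–144 months, one row per
subject × stratum. Default slopes and intercepts are per-landmark
literature values for this age range (e.g. occipital pole a = 0.038
mm/month, b = 4.7 mm; right vs left Heschl intercepts 8.7 vs 7.2 mm,
which reproduces the reported rightward temporal asymmetry of ~1.6 mm at
the mean age). Residual SDs are back-computed from each fit's reported r²
under the uniform-age design: σ = |a|·sd(t)·√((1−r²)/r²), sd(t) =
144/√12. Handedness is Bernoulli (90% right) with no distance effect —
it is deliberately a null factor. Draws that would be non-positive
(physically impossible distances) are redrawn; at the default parameters
this affects < 0.3% of draws in the worst stratum and biases slope
recovery negligibly. A single seeded generator per call makes tables
bit-reproducible.

## Interval decomposition

Profiles are sampled by trilinear interpolation at 0.1 mm steps along an
in-plane ray from the cortical point L (axial plane for the occipital and
frontal poles, coronal for the vertex, sagittal for the parietal
landmarks). The band-edge detector requires exactly two supra-threshold
bright bands (marrow, cutis) and places A/B and C/D at their edges,
snapping each threshold crossing to the nearest 0.1 mm sample — matching
the marking resolution, with no sub-sample fit. The default threshold is
the midpoint of the dark- and bright-layer intensities. Profiles with
merged or missing bands (zero-thickness outer table; muscle overlying the
skull at temporal/frontal-lateral sites) are rejected rather than
guessed; in vivo this step was a manual rater task, and the detector is
valid on phantom-like contrast only — external point tables are accepted
for real data. Interval lengths are flagged as 2D in-plane measurements:
they upper-bound the perpendicular tissue thickness by 1/cos(obliquity).

## Statistics

Growth fits are ordinary least squares per stratum with r² = 1 −
SSres/SStot, F = (n−2)·r²/(1−r²) on (1, n−2) df (equal to the squared
slope t-statistic; asserted as an identity in tests) and two-sided p
from the F distribution. Fits need ≥ 3 rows and non-constant ages.

The factorial ANOVA treats age group (0–18, 19–60, 61–144 months,
inclusive bounds; older ages are an error unless explicitly allowed),
the nine landmark/hemisphere combinations, and optionally handedness as
fixed effects, with requested interactions. Sums of squares are Type III
with sum-to-zero contrasts (statsmodels `anova_lm`); Type II is available
as a sensitivity switch. Rows with unknown handedness are dropped when
handedness is a factor. Designs with empty cells for a requested
interaction are rejected with the offending cells named. p-values are
reported at full precision with no multiple-testing correction, flagged
as such in the result metadata.

Laterality contrasts pair left and right measurements by subject (paired
t-test, two-sided), with an unpaired pooled-variance option. Interval
group comparisons use the unpaired pooled-variance t-test with df =
n₁+n₂−2; the degenerate all-equal case reports t = 0, p = 1 by
convention.

## Problem sizes and numerical tolerances

The full-scale phantom validation uses a 50 mm brain sphere with newborn
shells at 0.5 mm voxels (≈252³ grid, ≈190k hull vertices; about 1.5 min
on one CPU). Unit tests use 20–30 mm spheres at 0.5–0.75 mm, which
preserve every contract at a fraction of the cost; interval truth is
independent of brain radius. Statistical calibration uses 3,000 null
replicates of a balanced 3×3 design so the type-I-rate estimate's
binomial SE (~0.004) is small against the ±0.02 acceptance band, and
1,000 permutations for the regression-p uniformity check. Parameter
recovery uses 200 cohorts of 90 subjects — the study scale the default
generator encodes.

Key tolerances: interval conservation (Σ lengths = |L−D|) to 10⁻⁶ mm;
ANOVA SS additivity on balanced designs to 10⁻⁹ relative; noise-free
growth recovery to 10⁻⁹; mesh-geometry checks at half a voxel or the
stated analytic bounds. Ties in spatial queries break to the lowest face
index everywhere, making all geometric outputs deterministic.

## What the phantoms do not show

The generator has no cortical folding, no MRI noise or bias field, no
temporalis muscle, no scanner-specific geometry, and layer boundaries are
smooth ellipsoids. Passing tests therefore demonstrate correctness of the
geometric and statistical machinery under known ground truth — not
robustness to segmentation errors, motion artefacts or anatomy that
violates the layered model (sutures, fontanelles, venous lacunae).
Real-data use depends on upstream mask quality, and the band-edge
detector is explicitly phantom-grade: for clinical images the A–D points
should come from a rater or a dedicated segmentation. Interval
measurements are in-plane upper bounds by construction. The hull is a
closing-ball envelope: structures separated from the brain by more than
the closing radius are not bridged, and the radius is a modelling choice
(10 mm default) rather than an anatomical constant.
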