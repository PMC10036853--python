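# Methods

This note documents the models, parameter choices and limitations behind
`osteomorph`. Units are millimetres and degrees throughout.

## Synthetic bone generator

Each bone is the zero level set of a min-union of signed-distance
functions of primitive solids (spheres and capsules; the pelvis
additionally subtracts two "acetabular" spheres from host spheres so that
laterally opening sockets remain exact spheres centred on the true hip
joint centres). The level set is polygonized by marching cubes at
`voxel_size` (default 3 mm; grid nodes falling exactly on the surface are
nudged inward by 1e-9 so the triangulation stays watertight, and
coincident vertices are merged topologically).

The construction frame is x anterior, y proximal, z toward the subject's
right; left-side bones are generated by mirroring the implicit model
across the sagittal plane, which keeps the clinical (side-normalized)
signs of anteversion and torsion.

Key constructions:

* **Femur** — condyles are two spheres of radius
  (epicondylar − condylar)/2 centred ±condylar/2 off the midline, so the
  posterior/distal/epicondylar landmark poles realize the spec widths
  exactly. The neck capsule is elevated (neck-shaft − 90)° above the
  transverse plane and rotated anteriorly by the anteversion angle; the
  head sphere sits on the neck axis. Femoral length is enforced as the
  head-top-to-condyle-bottom extent. Lesser/greater trochanter bumps add
  realism; the shaft-cylinder patch is restricted to lie below the lesser
  trochanter.
* **Tibia + fibula** — condylar spheres proximally, a shaft capsule whose
  distal end is offset in the coronal plane by −y·cot(mechanical angle)
  so the mechanical angle is exact, and two equal-radius malleolar bumps
  whose centre-to-centre direction is the malleolar axis, rotated about y
  by the torsion angle (positive external). The lateral malleolus
  terminates a slender fibula, a separate closed component.
* **Pelvis** — four iliac-spine bumps (the ASIS/PSIS landmarks are their
  anterior/posterior poles), ring connectors, and the two carved
  acetabula. ASIS, PSIS and the frame axes are coplanar by construction
  so the pelvic frame coincides with the construction frame.

Every TruthTable entry is either a spec parameter realized exactly by
construction or (femoral mechanical angle) computed in closed form from
the exact landmark coordinates — never through the mesh pipeline.

The generator emulates the geometry and discretization of MRI-derived
segmentations, not their appearance: there is no cortical/trabecular
detail, no growth plates, no segmentation bias, and condyles are perfect
spheres. Accuracy numbers obtained on it therefore bound discretization
and algorithmic error, not anatomical model mismatch on real bones.

The shape-population generator applies a rank-k linear model of smooth,
orthonormalized displacement fields to the template nodes. The Gaussian
scores are empirically decorrelated so that their sample covariance is
exactly diagonal with the requested per-mode amplitudes: finite-sample
cross-correlations between modes would otherwise rotate the population's
principal axes away from the nominal modes, making exact PCA-recovery
statements impossible at realistic training-set sizes.

## Template correspondence

One template per bone type is generated at a fixed neutral spec
(deliberately different from the default target specs — e.g. femur
360 mm/127°/10° vs. 380 mm/130°/15° — so template fitting is always a real
deformation). Fitting proceeds in stages:

1. **Initialization.** Centroid-matched rigid ICP; for batch measurement
   a similarity (Umeyama) step recovers overall size, and a full affine
   step — seeded with per-principal-axis std ratios of the two point
   sets, because closest-point correspondences on a long bone are
   dominated by shaft points that carry no axial-scale information —
   recovers the anisotropic length/width ratio. For the long bones two
   local end affines, blended in with smoothsteps along the bone axis,
   capture torsion and end varus/valgus offsets that no global affine
   can express.
2. **RBF warping.** At each level of a decreasing Gaussian kernel-width
   schedule (40, 20, 10, 6 mm with Tikhonov regularization 1e-3 … 1e-5),
   a farthest-point subsample of template nodes (default 800) is pulled
   toward its closest points on the target; the displacement field —
   Gaussian RBF plus affine term, solved with the standard orthogonality
   side conditions — is applied to all nodes. Up to 4 iterations per
   level, stopping when the RMS improves by less than 1e-4 mm.
3. **Coverage (reverse) constraints.** Closest-point pulls are one-sided:
   target regions no template node maps to (condyle caps, concavities)
   would never attract the warp. At the coarse levels (width ≥ 10 mm),
   target samples further than 2 mm from every template node add a
   constraint at their nearest template node, thinned to a minimum
   spacing of 0.35 × width from all other constraints and capped at
   width/2 per step — near-duplicate constraint rows with conflicting
   displacements otherwise destabilize the near-interpolating solve.

The fitted mesh keeps the template topology bit-for-bit; final RMS and
maximum surface distance are recomputed independently and recorded. The
quality gate (default 1 mm RMS, configurable) aborts measurement of
surfaces the template cannot explain — e.g. a pelvis passed as a femur.

## Landmarks and frames

Detection is two-stage: template landmark anchors (barycentric
coordinates on template faces) are propagated to the fitted mesh, then
extremal landmarks are refined in a provisional anatomical frame that is
rebuilt once. Two robustness policies matter:

* **Snap-to-target.** When the original segmented surface is available
  (the normal `measure_bone` path), patch points are snapped to their
  closest points on it (drop beyond 2.5 mm): the correspondence defines
  the anatomical *region*, the segmentation supplies the exact
  *geometry* that primitives are fit to.
* **Pole landmarks.** Extremal landmarks on sphere-like patches
  (posterior/distal condyle points, epicondyles, malleoli, iliac spines)
  are evaluated as poles of the patch's sphere fit, not as extremal
  vertices: a raw vertex extremum is first-order sensitive to where the
  tessellation places nodes near the pole. Sphere fits are trimmed
  (two passes discarding the worst 25 % of residuals) and, when the
  target surface is present, re-grown from all target vertices on the
  fitted sphere, making them independent of residual correspondence
  slip. The malleoli are additionally re-seeded at the most distal
  target vertex of their side, because the near-cylindrical fibula lets
  a warped patch slide axially at no RMS cost.

Frames are right-handed (x anterior, y proximal/superior, z toward the
subject's right): femur — y from the epicondyle midpoint to the
head-sphere centre, z mediolateral from the epicondyles; tibia — y from
the intermalleolar to the intercondylar midpoint, z from the condylar
centres; pelvis — z along RASIS–LASIS, x anterior in the ASIS/PSIS-mid
plane. For left-side bones the mediolateral hint is negated so z always
points to the subject's right; this is what side-normalizes the signed
angles.

## Morphometry conventions

The projection conventions complete the bare "angle between" definitions
the measures inherit: anteversion and torsion are measured in the
transverse plane (normal = frame y), the mechanical angles in the coronal
plane (normal = frame x), and the neck-shaft angle is the unprojected 3-D
angle between the head-directed neck axis and the distally-directed shaft
axis (the distal direction is what yields the clinical ~130°; measuring
against the proximal direction would give its supplement). Signed angles
use an explicit in-plane basis (reference axis plus the anterior or
posterior direction), so anteversion is positive anterior and torsion
positive external on both sides.

Condyle "centres" are obtained from per-condyle sphere fits rather than
cylinder fits: on condyles that are locally spherical a per-condyle
cylinder is ill-posed, while the sphere centre is exactly the quantity
the knee-axis and shaft-axis definitions need. Neck and shaft axes use
trimmed cylinder fits (Levenberg–Marquardt over axis point, Gauss-map
axis tilts and radius, principal-direction initialization, parameter
tolerance 1e-12, axis sign canonicalized toward the data frame's +y).

Femoral/tibial length are defined as the surface extent along the shaft
axis (femur) or mechanical y-axis (tibia); the extent is evaluated on
the original segmented surface when available, whose extremes are
sharper than the fitted proxy's. Fields not applicable to a bone are
absent from the report, never zero-filled.

Vessel morphometry is purely geometric: polyline arc length, per-point
closest-point distance from centerline to lumen surface, and an
arc-length-weighted mean radius. Vessel dimensions are reported in mm
(centilitre-scale printed units in some clinical tables are not
plausible for the vessels concerned).

## Shape model

The point-distribution model uses raw mm coordinates (size is part of
paediatric shape variation and is deliberately not normalized),
covariance normalized by (n − 1), at most n − 1 components from an SVD
of the centred data matrix, and a deterministic sign convention (largest
loading positive). Alignment before PCA is centre-of-mass translation
plus Procrustes rotation to a reference — COM alignment alone cannot
remove rotational variation. PCA is per bone, not pooled across bone
types.

## Numerical choices

* Closest-point queries use a k-d tree over triangle centroids with an
  exactness guarantee: any query whose k-th candidate centroid could
  still hide a nearer triangle (within best distance + the largest
  centroid-to-corner radius) is re-queried with 4× the candidates, up to
  the exhaustive limit. Results equal the brute-force per-triangle
  oracle to machine precision.
* Binary little-endian PLY is written with float64 coordinates so mesh
  round trips are bit-exact; STL merges duplicated facet corners at
  1e-6 mm.
* The algebraic sphere fit is exact on noiseless data; a Gauss–Newton
  geometric refinement exists as an independent cross-check, not as the
  default path.
* All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); noise-free generation is bit-for-bit
  reproducible and seed-independent.

## Problem sizes

Default polygonization (3 mm voxels) yields meshes of roughly 5–11 k
vertices; correspondence uses 800 control points and ~2 000-point ICP
subsamples; the recovery analyses sweep 20 femur and 20 tibia specs drawn
uniformly from paediatric-plausible ranges (femoral length 320–420 mm,
neck-shaft 120–142°, anteversion 2–30°, tibial torsion 5–35°, …) at
noise 0. These sizes keep a full run on a single CPU core at a few
seconds per bone while leaving landmark discretization error an order of
magnitude below the 1°/2 % reporting thresholds.

## Known limitations

* Accuracy is demonstrated on the synthetic generator; real condyles are
  not spheres and real segmentations carry bias and topology noise, so
  measured-vs-true errors on clinical data will be larger.
* The correspondence is closest-point driven; it guarantees small
  surface distance, not small anatomical correspondence error in
  featureless regions (tangential sliding is unobservable there).
* Torsion differences between template and target much beyond ~20° can
  degrade malleolar correspondence; the distal affine stage and the
  extremal re-seeding cover the tested range but are not a guarantee for
  arbitrary deformity.
* No soft tissue, cartilage, growth plates, or pose articulation; one
  template per bone type, no template construction from data.
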