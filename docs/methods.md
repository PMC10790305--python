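# Methods

This note documents the models, algorithms, defaults and known limits of
the pipeline. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Canonical frame and volumes

All volumes are standardised to RAI axis order (first data axis runs
Right→left, second Anterior→posterior, third Inferior→superior) at 1 mm
isotropic spacing before any geometry is extracted. Internally the affine
follows the NIfTI convention (index → RAS world, mm), so an RAI volume has
a diag(−s, −s, +s) linear part; meshes therefore live in RAS world
coordinates and "posterior" means smaller y. Reorientation permutes and
flips array axes using the affine's axis codes only — voxel values are
never interpolated and world positions are preserved. Resampling is
trilinear for intensities and nearest-neighbour for label volumes
(averaging label integers is meaningless); voxel (0,0,0) keeps its world
position and the extent is preserved to within one voxel. The
interpolation kernel for resampling is not dictated by the input data;
trilinear is the package's choice and is exact for affine intensity
fields at voxel centres.

## Structure identification and labelling

The vein/appendage class of the segmentation is first enumerated into
provisional labels, largest connected component first (ties broken by
centroid lexicographic order). Identification then uses one operator seed
per structure at its distal end: stations are placed every voxel along
the seed → bloodpool-centre-of-mass line; at each station the
cross-section of the bloodpool perpendicular to the line is extracted on
a 2-D grid (60 mm window), restricted to the component containing the
line, and its largest inscribed-disk radius is taken from the in-plane
Euclidean distance transform. The profile is smoothed with a 3-station
moving average; the first station attaining the maximum second difference
is the vein–body junction, returned as a disk the caller may move. A
profile whose maximum second difference is below 0.15 mm (a uniform tube)
raises a detection error rather than guessing. The junction disk defines
the label boundary along the centreline: component voxels on the body
side of the junction plane revert to the body label.

The surface is extracted by marching cubes at the 0.5 iso-level of the
binarised bloodpool; each triangle takes the label of the labelled voxel
nearest its centroid. Label verification keeps, for every non-body label,
only the largest connected patch and reassigns disconnected minority
patches to their largest neighbouring patch, iterated to a fixed point
(idempotent). Clipping removes triangles whose centroids fall inside
operator-chosen spheres (one per PV, one for the mitral valve; the
appendage is never clipped), keeps the largest remaining component and
leaves the openings uncapped. A sphere that would remove more than half
the surface area, or a clip that splits the mesh into comparable halves
(second component > 30% of the largest), is rejected as suspicious. The
mitral opening is always made by an operator (or synthetic-operator)
sphere, mirroring the manual workflow, even when a valve class exists in
the segmentation.

Default label codes: LA = 1, LSPV = 11, LIPV = 13, RSPV = 15, RIPV = 17,
LAA = 19; segmentation classes are background 0, body 1, PV∪LAA 2,
MV 3.

## Remeshing and export

Isotropic remeshing is the classic incremental scheme: split edges longer
than 4/3 of the target (consistent midpoint subdivision with labels
carried to child triangles), collapse edges shorter than 4/5 of the
target (link-condition guarded; boundary and label-boundary vertices are
protected and collapse only absorbs free vertices into them), flip
interior same-label edges when that equalises vertex valences without
inverting normals, then relax vertices tangentially (uniform Laplacian
projected to the tangent plane, λ = 0.5, boundary and feature vertices
fixed). Five passes or convergence to within 10% of the target, whichever
first. The tolerance bands asserted in tests — mean edge within ±20% of
target, total area within 2%, per-structure area fractions within 3% —
are the package's own acceptance bands for this operator.

openCARP export writes the plain-text triple: `.pts` (count, then x y z
in μm = mm × 1000), `.elem` (`Tr i j k tag` with the structure label as
region tag), `.lon` (one — or two, if a sheet direction is configured —
unit vectors per element). Export→parse→export is byte-stable after one
cycle.

## Universal atrial coordinates

Boundary construction snaps the four landmarks (LSPV–body junction,
RSPV–body junction, lateral wall, septal wall near the fossa ovalis) to
mesh vertices (error if farther than 10 mm). The two α boundary lines are
shortest edge-graph paths mitral-rim → landmark → superior-PV rim (septal
side through the fossa-ovalis point to the RSPV rim; lateral side through
the lateral point to the LSPV rim). The mitral rim is split into
posterior and anterior arcs at the two α-path endpoints, posterior being
the arc with the smaller mean anterior–posterior coordinate. α solves the
Laplace equation with the septal line at 0 and the lateral line at 1;
β with the posterior arc at 0 and the anterior arc at 1. The solver uses
cotangent weights, Dirichlet elimination, and a direct sparse
factorisation, and verifies the reduced-system relative residual to
1e-10. The rims are classified by the majority structure label of their
incident triangles, so no orientation heuristics touch image content.

The exact boundary-line conventions of the original UAC tooling are not
fully published; this construction is concrete and testable but may
differ systematically from it, which matters only if coordinates are
exchanged with models parameterised elsewhere.

## Fibre mapping

Per-element local frames are built from the in-plane gradients of α and β
(linear shape functions), Gram–Schmidt orthonormalised and oriented
right-handed against the element normal. Atlas transport finds, for each
target element, the atlas element nearest in (α, β) (centroid KD-tree,
deterministic ties), decomposes the atlas fibre in the atlas frame,
reconstructs with the target frame, projects to the target tangent plane
and re-normalises. Elements with no atlas counterpart within UAC distance
0.1, or with degenerate frames (near the Dirichlet lines where a gradient
vanishes), are filled by sign-aligned neighbour averaging projected to
the tangent plane.

Two built-in fields serve as the atlas: a rule-based field
(circumferential along α where β < 0.15 or β > 0.85 near the mitral rim,
longitudinal along β near the septal/lateral edges where the PV ostia
sit, oblique (α+β)/√2 on the roof) and a smoothly rotating field
θ(α, β) = π(α + β) that stands in for a DTMRI-derived atlas file — it is
labelled a stand-in and makes no claim to reproduce measured human fibre
architecture. Bilayer use is two co-located fields on one surface
distinguished by an endo/epi tag; endo is the simulation default.

## Electrophysiology surrogate

The eikonal solver minimises, per vertex and incident triangle,
(1−λ)T_a + λT_b + √(eᵀMe) over the opposite edge, where
M = ffᵀ/v_l² + ttᵀ/v_t² is the element's travel-time metric (f the
tangent-projected fibre, t = n×f). The interior minimiser solves the
quadratic (c1 − c2λ)² = u²·g(λ); endpoint candidates cover edge-only
updates. Jacobi sweeps repeat until the largest update is below 1e-6 ms.
By construction every accepted value is ≤ the edge-graph Dijkstra time
under the same metric, which the tests assert exactly. Speeds are
v = speed_scale·√σ with speed_scale = 0.95 mm·ms⁻¹·(S/m)^(−1/2), chosen
so σl = 0.4 S/m gives v_l ≈ 0.6 m/s (physiological order); conductivity
enters simulation only through this map and the diffusion tensor, so the
2:1 anisotropy ratio √(σl/σt) is preserved exactly. CV = 1/‖∇LAT‖ with
the per-element linear-shape-function gradient; elements with gradient
below 1e-9 ms/mm are flagged undefined. The stimulus for paced activation
is the full RSPV boundary loop (the rim subset is not otherwise
specified).

The AF surrogate is an explicit-Euler surface-FEM monodomain with
Aliev–Panfilov kinetics (k = 8, a = 0.1, ε0 = 0.01, μ1 = 0.12, μ2 = 0.3,
12.9 ms per dimensionless time unit) and diffusion tensor
D = d·[σt·I + (σl−σt)·ffᵀ] in the tangent plane, d = 0.25 mm²/ms per
S/m, lumped mass. It replaces a biophysically detailed ionic model: the
protocols (stimulus site, conductivities, four-spiral initiation, PS
analysis) are preserved so *comparative* metrics between paired models
are meaningful, but absolute activation or cycle times are not expected
to match clinical-model values. dt defaults to 0.05 ms; divergence
(|u| > 10) aborts with a CFL diagnostic.

Spiral initiation builds the phase field
φ = Σ_k s_k·θ_k − Σ_k s_k·r_k/b over UAC space with cores at
(0.25, 0.25), (0.25, 0.75), (0.75, 0.25), (0.75, 0.75) and chirality
(+1, −1, −1, +1). The angular terms fix the topology — exactly one ±1
singularity per core, nothing else — while the smooth radial terms give
each core an Archimedean spiral of pitch b (default 0.2; smaller pitches
produce phase gradients that alias on coarser meshes near the compressed
PV-rim regions of UAC space). The (u, w) state at phase φ is read from a
travelling-pulse cycle precomputed on a 1-D periodic ring (300 nodes,
0.5 mm spacing, 800 ms), parameterised by angle around the loop centre in
the (u, w) plane. The same centre defines the phase for PS detection:
a vertex is a singularity when the wrapped phase differences around its
angle-ordered one-ring sum to ±2π within 0.2 rad; since a core inside a
triangle trips all three of its vertices, edge-adjacent equal-charge
detections are merged into one (representative: lowest vertex index).
Boundary vertices are skipped. Detections are binned per frame onto a
101×101 UAC grid; the analysis window discards the first 200 ms and
samples every 5 ms by default.

## Reproducibility metrics

Shape statistics (Hausdorff = max, mean, median) are computed on the
symmetric array of point-to-nearest-point distances, per structure and
overall, with **no** distance cutoff. Every other comparison — fibre
agreement, LAT, CV, PS — uses only correspondences within 1 mm. LAT maps
are resampled onto the UAC grid (linear scattered interpolation) before
correlating, which makes differently meshed models comparable; whether
point-correspondence sampling would differ materially is untested. The
ICC is the two-way random-effects, absolute-agreement, average-measures
form, (MS_R − MS_E)/(MS_R + (MS_C − MS_E)/n), with the standard F-based
confidence interval (single-measure interval mapped through
Spearman–Brown) and F = MS_R/MS_E for the p-value; an all-equal table
returns ICC 1 with a degeneracy flag. SSIM uses a sliding 7×7 uniform
window, sample covariance, c1 = (0.01L)², c2 = (0.03L)² with L the
maximum cell value over both maps, averaged over fully interior windows;
two all-zero maps are defined identical (SSIM 1, correlation flagged
undefined).

## Synthetic cohort

A case is an ellipsoidal body (semi-axes 15–20 mm), four capsule veins
(radius 4–6 mm, length 15–22 mm) at anatomically plausible directions, an
appendage lobe, and a mitral disc marker just outside the inferior-
anterior wall, on a 112³ grid at 1 mm. MRA intensity: background 100,
bloodpool 600, Gaussian noise σ = 20. LGE: background 80, bloodpool 200,
healthy wall 160, fibrotic wall 400, σ = 5 — the wall values bracket the
IIR 1.2/1.32 thresholds while the fibrotic value (IIR 2.0, a strong scar)
keeps the planted patch separable from projection noise. The patch is an
angular cap of body-wall shell voxels, sized so its voxel count is the
requested fraction of the *scoreable* wall (body shell outside the mitral
clipping sphere), excluding vein-adjacent zones; shell-voxel counts
approximate surface area, so recovered scores track the planted fraction
to within the ±0.03 acceptance band. Operator jitter is independent
Gaussian noise on every manual input; defaults are intra σ = 1 mm and
inter σ = 2–3 mm, with 3 mm on the mitral-sphere centre because valve
placement dominates inter-operator shape differences. The generator makes
no attempt at MR physics, motion, bias fields, partial-volume wall
gradients, or realistic vein branching — passing tests demonstrate that
the algorithms are correct on geometry of the right scale and topology,
not that clinical images of arbitrary quality will segment well.

## Problem sizes and profiles

The default case profile remeshes to 0.8 mm mean edge (~30k triangles,
~15k vertices), which the whole suite — two full cases, an AF run, and
forty jittered replicates — processes in a few minutes on one CPU; the
clinical profile (0.3 mm, as used for openCARP-bound exports) is a config
switch and exercises identical code. Eikonal accuracy is verified at
0.3 mm edges on the flat sheet. AF runs default to 400–500 ms with a
200 ms transient; longer runs only add frames to the PS binning.

## Known limitations

- UAC distortion near the PV rims can reach large per-edge coordinate
  jumps; fibre frames and spiral phases are filled or regularised there,
  and one-ring PS detection adjacent to rims is skipped, but a very tight
  spiral pitch (b ≲ 0.1) can still alias into spurious detections on
  coarse meshes.
- The rule-based and smooth fibre fields are geometric constructions, not
  measured fibre architecture; absolute fibre-agreement percentages
  between them calibrate the metric, not human anatomy.
- The two-variable surrogate has no atrial restitution or AF remodelling;
  rotor counts and cycle lengths are model properties, not predictions.
- The mitral rim split uses an anatomical-axis rule (posterior = smaller
  anterior–posterior coordinate); a strongly rotated acquisition that
  defeats RAI standardisation would need manual arc assignment.
- MRA→LGE registration is assumed done upstream; the pipeline performs
  no registration and simply samples the LGE volume in the mesh's world
  coordinates.
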