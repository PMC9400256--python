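# Methods note

This note records the model behind `palato3d`, the main numerical choices,
and the limits of the synthetic validation. The README covers usage; this
document covers *why* the computations are built the way they are.

## Problem

Free gingival and connective-tissue grafts are harvested from the palatal
masticatory mucosa. The harvestable volume is the soft-tissue layer between
two surfaces of the same anatomy:

* the **bone surface** segmented from CBCT (the deep boundary), and
* the **gingival surface** from an intraoral scan or cast digitisation
  (the superficial boundary).

After rigid superimposition of the two models, the mucosal thickness at a
point of the gingival surface is its distance to the bone surface, and the
graft volume over a region of interest (ROI) is the integral of that
thickness over the region. The package computes per-ROI area, mean/min/max
thickness, volume, and the volume/area ratio, plus non-parametric pairwise
comparisons between ROIs across a cohort.

## Pipeline stages

### 1. Bone segmentation (`segmentation`)

CBCT volumes are thresholded with an inclusive HU window (default
150–2000 HU: above soft tissue, below metal/artefact), small connected
components below 27 voxels are discarded, and the largest component is kept.
The iso-surface is extracted by marching cubes at the 0.5 level of the
binary mask with the grid origin and spacing restored, and oriented outward
by signed volume. Boundary loops up to a configurable edge count are closed
with a centroid fan so downstream distance queries see a closed surface;
larger rims (e.g. the scan's field-of-view cut) are reported and left open.

Marching cubes on a binary mask has a staircase texture: volumes converge
quickly with voxel size but areas are biased high (~9 % at 0.5 mm voxels for
a sphere). Area-bearing quantities in the pipeline are therefore always
measured on the *gingival* mesh, never on the segmented bone.

### 2. Registration (`registration`)

Two stages, mirroring clinical practice of registering on tooth surfaces
(teeth are rigid and shared between CBCT and surface scan, mucosa is not):

1. **Coarse landmark alignment** — least-squares rigid fit (Kabsch/SVD, no
   scaling) of landmark pairs matched by (name, side). Fewer than three
   non-collinear pairs is an error, not a warning.
2. **Tooth-masked best-fit ICP** — source faces within a 5 mm geodesic
   radius of the `tooth_seed` landmarks are matched to nearest points on the
   target surface; pairs beyond 3× the median distance are rejected each
   iteration; the rigid update is re-solved from the original points so the
   best-seen transform is always recoverable. Convergence is a change in
   point-to-surface RMS below 1e-4 mm.

Nearest-point queries use an internal engine (k-d tree over triangle
centroids, vectorised point–triangle projection, adaptive candidate
growth with a certainty bound), so no external spatial-index dependency is
needed.

### 3. ROI partition (`roi`)

The measured region is the palatal mucosa between:

* the **paramarginal boundary**: 3 mm geodesic offset from the gingival
  sulcus curve, on the palatal side (graft harvest spares the marginal
  gingiva to protect the periodontal attachment);
* the **posterior boundary**: the polyline along the distal border of the
  region (behind it lie the greater palatine structures);
* the midline is included; the region is split into five antero-posterior
  bands (ROI 1 = canine/first-premolar band … ROI 5 = second-molar band) by
  cutting planes through left/right boundary-landmark pairs parallel to the
  occlusal-plane normal.

Geodesic distances to the sulcus polyline run Dijkstra on a surface graph
with a virtual source. Seeding uses *chordal* distances for all vertices
within 1.5 median edge lengths of the densified polyline; this radius-based
seeding is rotation-stable (no nearest-face tie-breaking), and the small
radius keeps chords from cutting across surface curvature. The graph
contains the 1-ring mesh edges plus one edge per adjacent-face pair
connecting the two opposite vertices, weighted by the straight-line distance
in the *hinge-unfolded* plane of the two triangles (the exact two-triangle
surface geodesic when the unfolded segment crosses the shared edge,
otherwise the shorter path through an edge endpoint). On structured grid
meshes, 1-ring edges alone overestimate anti-diagonal distances by up to
41 %; the unfolded edges cap the metric anisotropy at ~8 % and — unlike raw
2-ring chords — can never tunnel through surface creases.

### 4. Deviation analysis (`deviation`)

Distances are signed by the bone-surface normal at the foot point. A vertex
measurement is valid when the distance is below 15 mm and the angle between
the gingival normal and the connecting segment is below 60° (guards against
matching across the arch or to unrelated surfaces). A face is valid when all
three vertices are.

* **MeanDist** per ROI is the area-weighted mean of valid vertex distances
  (vertex weight = one third of incident valid-face area).
* **Volume** integrates per-face frusta between the gingival triangle and
  its foot-point triangle: V = d̄/3·(A_top + A_bot + √(A_top·A_bot)), with
  both areas projected onto the plane perpendicular to the face's sweep
  direction (mean vertex→foot segment). The projection removes the
  sec(tilt) inflation of slanted faces; the frustum form (rather than plain
  prisms A·d̄) is exact for linearly tapering gaps and keeps curved shells
  (sphere-in-sphere) correct to O(t³κ²), where plain prisms already err at
  the 1 % level. Negative (intersecting) distances are clipped to zero for
  the volume only and counted in a warning.
* The colour map ramps green → yellow → red → dark red over [0, scale_max]
  and paints invalid vertices grey.

### 5. Statistics (`stats`)

Pairwise per-ROI comparisons use the Wilcoxon signed-rank test with the
zero-difference policy of dropping zeros and midranks for ties. For n ≤ 25
the null distribution is computed exactly by dynamic programming over the
doubled midranks (equivalent to full 2ⁿ enumeration, verified in tests);
above that, a normal approximation with tie correction Σ(t³−t)/48 and
continuity correction 0.5 is used. The 10 p-values per metric are adjusted
by Benjamini–Hochberg step-up; degenerate pairs — zero-variance differences,
including the all-zero case — are flagged and excluded from the adjusted
family (a constant difference carries no within-pair evidence to rank).

## Synthetic generator and ground truth (`synthetic`)

The generator produces bone + gingiva mesh pairs with analytically known
per-ROI answers, which is what makes end-to-end recovery testable.

The bone is a height field: a cylindrical vault −depth·cos²(πx/2x_v) plus
Gaussian alveolar ridges and tooth crowns. The gingiva is the bone offset
along its normal by a thickness field

t(x, y) = profile(y) · lateral(x)/c · f_patient + noise,

where `profile(y)` is piecewise through the five per-band mean thicknesses
(1.9, 2.4, 2.7, 2.9, 4.0 mm — a representative measured profile, increasing
anterior → posterior), `lateral(x)` is a mild midline dip, `c` normalises
the lateral factor so band means are preserved, `f_patient` is a log-normal
patient effect (σ = 0.22, mean-one), and `noise` is optional Gaussian
thickness noise (σ = 0.05 mm default). Over the tooth crowns the thickness
is smoothly forced to zero so bone and gingiva share the crown surfaces —
exactly the shared rigid structures the ICP stage registers on.

Two construction-validity constraints make the requested field geometrically
realisable as an actual tissue layer whose thickness *is* the
surface-to-surface distance:

1. **Reach cap.** A normal offset by t is only valid while the offset
   point's nearest bone point is its own foot, i.e. while t stays below the
   bone's *normal reach* (distance to the medial axis — this covers both
   focal folding at sharp ridge flanks, t·κ ≥ 1, and the opposite wall of
   the ridge/vault groove). The requested thickness (up to ~8 mm for strong
   patient effects) exceeds the reach there, so t is capped at 0.8× the
   reach, found per node by bisection of `dist(b + t·n, bone) ≥ t` against
   a half-resolution bone sampling. Without the cap the "ground truth" is
   simply false for the generated geometry.
2. **Gradient bound.** The raw cap leaves near-vertical thickness cliffs;
   real mucosa varies smoothly and near-vertical tissue walls defeat any
   nearest-point measurement. A Lipschitz erosion
   t(b) ← min_b′ (t(b′) + 1.0·dist(b, b′)) over the grid graph bounds
   tissue walls at 45° (well inside the pipeline's 60° validity filter).

Both constraints only lower the field, are deterministic, and are applied
*before* anything downstream: meshes, landmarks and ground truth all flow
from the same final field.

Ground truth integrates the *realised* thickness field over each ROI on a
4× refined triangulation using the same diagonal split as the mesh
(triangle-linear, not bilinear — the distinction is ~1 % in volume), with
Simpson integration along the sweep (exact: the integrand is quadratic).
Region membership mirrors the pipeline's geodesic construction: a 16-way
stencil multi-source Dijkstra on the fine grid (metric anisotropy ~0.5 %)
measures on-surface distance from the sulcus curves, and the paramarginal
border is its 3 mm level set.

Default generator parameters (0.5 mm grid, 36 mm arch width, 40 mm arch
length, 7 mm vault depth, the thickness profile above) are the study
conditions; the validation suite runs them as-is.

`voxelize_phantom` rasterises a sample into a HU phantom (bone 1200 HU,
mucosa 60 HU, air −1000 HU) so the segmentation stage can be exercised
end-to-end from voxels.

## Error budget observed in validation

On 20-patient cohorts with 10°/5 mm pose perturbation:

* registration recovery: < 0.1° and < 0.05 mm in all runs;
* MeanDist recovery: ≤ 0.02 mm per patient-ROI (distance measurement along
  the normal of a smooth surface is essentially exact);
* volume recovery: within ±1 % per patient-ROI — dominated by boundary
  quantisation of the ROI partition on a 0.5 mm mesh, not by the volume
  integrator (which agrees with a 0.1 mm voxel-counting oracle to < 1 % on
  the fixtures and with analytic plates/shells to ≤ 1 %).

## Known limits

* The generator's vault is y-cylindrical away from crowns, so the normal
  sweep stays in-plane; real palates have doubly curved vaults. The volume
  integrator itself is validated separately on spheres, which are doubly
  curved.
* HU thresholding is a hard window; voxels exactly at the boundary follow
  floating-point comparison, so HU values should not be synthesised exactly
  at 150/2000.
* Hole closing is a centroid fan, adequate for small (< 100 edge) defects
  only; large apertures are deliberately passed through.
* Statistics assume paired per-patient ROI values; the degenerate all-zero
  pair flag exists because synthetic null cohorts can produce them.
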