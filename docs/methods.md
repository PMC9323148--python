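# Methods

This note documents the models and numerical procedures implemented in
`cranioshape`, the choices made where the design was genuinely open,
and what the synthetic test substrate does and does not demonstrate.

## Mesh primitives and the area mass matrix

Meshes are plain `(p, 3)` vertex / `(t, 3)` face arrays in millimetres
with counterclockwise winding. OBJ/PLY I/O goes through trimesh with a
strict triangle check on top (a quad face is a parse error naming the
face, not something to silently triangulate).

Weighted PCA needs an area weighting so that densely meshed regions
(the face) do not dominate the statistics. The mass matrix `M ∈ R^{p×p}`
holds per-vertex weights on the diagonal and per-edge weights on the
off-diagonal, in the spirit of barycentric dual cells. Construction:
each triangle's area is partitioned among its three vertices and three
edges by classifying sample points against the *six representative
points* of the face — the three corners and the three edge midpoints —
and splitting the area proportionally. Two details matter:

* Classifying against edge *segments* instead of midpoints would
  degenerate: every interior point of a triangle is at least as close
  to an edge segment as to that edge's endpoints, so vertices would
  receive exactly zero weight. The representative-point rule gives
  both element types positive area.
* Sampling uses the centroids of the `20² = 400` congruent subtriangles
  of a level-20 subdivision. Centroid sampling is exactly uniform over
  the face and never lands on a tie boundary of generic configurations;
  samples that do tie (symmetric configurations) are split equally
  among the tied elements, which keeps symmetric meshes exactly
  symmetric in `M`. The partition conserves each face's area to
  machine precision, and agrees within 1% with a dense
  random-sampling oracle.

`M` is replicated channel-wise to `M₃ = M ⊗ I₃ ∈ R^{3p×3p}` (indices
interleaved x,y,z per vertex). `M` is symmetric nonnegative but not
guaranteed positive semidefinite as an operator (edge couplings can
produce negative eigenvalues for highly oscillatory vectors); on smooth
shape differences the quadratic form approximates the surface integral
of the squared displacement and is positive. Any Gram eigenvalue below
the rank cutoff — including a numerically negative one — is dropped
(see below), which keeps the model well-posed regardless.

## Correspondence: landmark Procrustes + optimal-step nonrigid ICP

The template is first aligned to each target with the closed-form
similarity transform (Umeyama; translation, rotation, isotropic scale)
that maps its ten landmarks onto the target's annotated landmarks. The
target scan itself is never transformed.

Nonrigid morphing then uses one 4×3 affine transform per template
vertex. Each iteration minimizes the quadratic energy

* stiffness `α² ‖(M_G ⊗ G) X‖²` — differences between transforms of
  edge-adjacent vertices, `G = diag(1, 1, 1, γ)` with `γ = 1`
  weighting the translational part;
* distance `‖W(DX − U)‖²` — current vertices against their closest
  points `U` on the target surface (point-to-triangle, via a KD-tree
  over triangle centroids with exact closest-point evaluation on the
  candidate set); correspondences with normal angle > 90° or distance
  > 10× the template's median edge length get weight 0;
* landmark `β² ‖D_L X − U_L‖²` — annotated template vertices against
  target landmark positions,

solved exactly per iteration as a sparse normal-equation system
(`scipy` sparse LU, three right-hand sides). The stiffness `α` follows
a decreasing schedule, default `100 → 1` in 8 geometric steps with the
landmark weight decaying linearly `10 → 0`; each level iterates until
the transform change `‖ΔX‖_F < 10⁻⁴·p` or 20 iterations. A reduced
schedule (`NICPConfig.fast()`: 4 levels, ≤ 4 inner iterations) is used
for batch cohort morphing; it trades a formal convergence flag for a
~5× speedup and reaches sub-0.01 mm mean surface distance on the
synthetic heads. All schedules are user-configurable; the defaults are
this package's choices in line with published optimal-step N-ICP
practice, not values taken from elsewhere.

Properties relied on downstream: template topology is bit-identical
after morphing; with target = template the identity is the exact
optimum; a globally scaled target is inside the per-vertex affine model
class and is recovered exactly after landmark pre-alignment.

## The weighted-PCA point distribution model

Corresponded shapes are rigidly aligned by generalized Procrustes
analysis — rotation and translation only, Euclidean metric, iterating
align-to-mean/recompute-mean until the relative mean change is below
10⁻⁷ (max 100 iterations). Scale is deliberately **not** removed:
head size covaries with age and with the deformities themselves, so it
is treated as an attribute of shape.

With the centred observation matrix `X_zm ∈ R^{3p×n}` the model is the
eigensystem of the weighted sample covariance, computed through the
dual (Gram) route, which costs `O(n³)` instead of `O(p³)`:

    G_W = X_zmᵀ M₃ X_zm,   G_W = U_G Λ_G U_Gᵀ  (descending),
    V = X_zm U_G Λ_G^{-1/2},   Λ = Λ_G / (n − 1).

`V` is M₃-orthonormal by construction (`Vᵀ M₃ V = I`). Because the
data are centred, the smallest Gram eigenvalue is zero; the rank cutoff
drops all eigenvalues below `10⁻¹⁰·λ₁` (negatives included). Each
component's sign is fixed so its largest-magnitude entry is positive,
making model builds deterministic. The `n − 1` denominator is applied
with whatever `n` a given (sub)model was built from.

Synthesis and analysis:

    x = x̄ + V Λ^{1/2} α,        α = Λ^{-1/2} Vᵀ M₃ (x − x̄).

The M₃-weighted projection is the left inverse of synthesis and gives
the M₃-optimal truncated reconstruction; whether a plain least-squares
projection should be preferred is genuinely open, and the weighted form
was chosen for consistency with the components' M₃-orthonormality.
Gaussian sampling draws `α ~ N(0, I)` per component with a seeded
generator. Submodels (per class, and cranium-only on the masked
submesh) each run their own GPA and mass matrix. Models serialize to
HDF5 (mean, components, eigenvalues, faces, COO mass matrix, labels).

## Evaluation metrics

* **Landmark error**: mean distance between morphed template landmark
  vertices and the target's annotated landmarks.
* **Vertex-to-nearest-neighbour distance**: mean point-to-triangle
  distance from morphed vertices to the target surface.
* **Surface-normal deviation**: per class, after a per-class rigid GPA,
  the mean pairwise angle between corresponding vertex normals across
  class members, averaged over vertices; classes are combined weighted
  by class size. Classes of size 1 are excluded with a warning.
* **Compactness**: cumulative eigenvalue fraction at `m` components.
* **Generalization**: leave-one-out — rebuild the model without one
  shape, rigidly align the left-out shape to the fold mean, project
  with `m` components, synthesize; error is the *mean* per-vertex
  Euclidean distance in mm (mean rather than RMS was an open choice;
  mean is documented and used throughout). `m` beyond a fold's rank is
  clamped with a warning.
* **Specificity**: mean per-vertex distance of Gaussian samples to the
  nearest training shape, using corresponded vertex distance (cheap and
  meaningful on shared topology) rather than surface distance.

## Classification protocol

Features are the first `k` standardized cranial-model coefficients,
fed to the classifiers without further standardization (the `√λ`
scaling is inherent in `α`). One *global* cranial model projects all
observations; rebuilding the model per fold is available via the
library but is not the default, matching the single-model protocol the
coefficients come from. Cross-validation is stratified 10-fold over
the unmirrored scans only (deterministic per seed); mirrored twins
augment training folds and are excluded from any fold that tests their
original — the no-leakage invariant is asserted programmatically on
every run. The confusion matrix is pooled over folds (each original
tested exactly once). The g-mean is the geometric mean over all four
per-class sensitivities. A component sweep (`k = 1..100`, pooled
accuracy as fitness, smallest `k` on ties) mirrors the usual
model-selection loop; note its selected accuracy is optimistically
biased, which is why the end-to-end study reports accuracy at a fixed
`k = 10` instead.

## Shape-editing applications

**Pathology removal.** Class mean coefficient vectors `α_μ,c` are the
projections of each class's aligned training shapes into the full
model, averaged. Editing translates a subject's coefficients by
`α_μ,to − α_μ,from`; translations form a group, so the operation is
exactly invertible.

**Fixed-cranium flexibility modes.** With `S = V Λ^{1/2}` and `A`/`B`
the rows of `S` at free/fixed coordinates, modes solve

    (AᵀA) w = λ (BᵀB + εI) w.

The Tikhonov floor `ε = 10⁻⁸·tr(BᵀB)/m` is required because `BᵀB` is
rank-deficient whenever the model contains directions that leave the
fixed region still — precisely the interesting case; the pure ratio
problem would be singular there. Which quantity sits in the numerator
versus denominator, and the `ε`-regularized formulation itself, are
this package's design choices for the constrained problem.
Eigenvalues are free-to-fixed displacement energy ratios and are
invariant to component sign flips. Constrained sampling draws standard
normal amplitudes along the top modes, each normalized to unit RMS
displacement over the free region.

## Synthetic cohort generator

No infant scan data can be shipped, so the generator is first-class,
tested code and defines the study conditions:

* **Head proxy**: subdivided icosphere scaled to infant proportions
  (semi-axes 65 × 80 × 70 mm lateral × AP × vertical), with smooth
  cosine-window frontal protrusions for face and nose. Default
  subdivision 4 (2562 vertices); the end-to-end study uses
  subdivision 3 (642 vertices), a resolution chosen so the full
  160-scan morph-model-classify run completes in about a minute.
* **Landmarks**: ten named points (nasion, sellion, opisthocranion,
  vertex, paired exocanthion/tragion/euryon) at analytically known
  unit directions; every deformation field is a function that is
  applied identically to mesh vertices and landmark points, so
  landmarks ride the deformations exactly.
* **Class fields** (magnitude `m`, per-class uniform draws):
  sagittal — anisotropic scaling `y·√(1+m)`, `x/√(1+m)` (the AP/lateral
  ratio grows by exactly `1+m`); metopic — anterior wedge pulling the
  forehead toward the midline (range 0.3–0.5); coronal — unilateral
  frontal flattening with contralateral bulge, side random per scan
  (range 0.25–0.45); control — a small random, exactly left-right
  symmetric smooth radial field (10× reduced magnitude). Magnitudes
  were set to clinically evident deformity scales (1–3 cm of
  displacement).
* **Facial variability**: eight symmetric localized bumps (nose,
  mouth, chin, paired cheeks/jaw/ears/mastoid, neck), amplitudes
  `N(0, 2 mm)` per scan, with a vertical taper that keeps their
  support strictly below the cranial mask. This emulates the
  inter-subject facial variation real cohorts have and is what makes
  fixed-cranium flexibility modes non-trivial.
* **Nuisance**: global size scale `U(0.9, 1.1)` (age surrogate) and
  i.i.d. Gaussian vertex noise, default σ = 0.5 mm (mesh only;
  landmarks stay exact, as a careful annotator would place them).
* **Cranial mask**: template vertices above the horizontal plane at
  15% of maximal height — above eye/ear level, excluding the face.

All randomness flows from one integer seed; identical seeds give
bit-identical scans.

### What the synthetic substrate does and does not show

Passing the end-to-end study (pooled LDA accuracy ≥ 0.9 on 40 scans
per class) demonstrates that correspondence, the weighted-PCA model,
mirror-aware CV and the classifiers compose correctly and recover
class structure that is separable by construction. It does **not**
reproduce the clinical accuracy on real patients: real scans have
holes, clothing artifacts, non-ellipsoidal anatomy, continuous
deformity severity down to the diagnostic boundary, and annotation
error. The worked example on the printed 367-subject confusion counts
covers the reporting arithmetic on real-cohort numbers; the absolute
morphing/model metrics of a real cohort are out of reach without the
patient data.

One deliberate asymmetry: the paper-style protocol mirrors each
*subject* and morphs the template onto both (2N morphs). The pipeline
here mirrors the *corresponded morph* (reflection + the template's
left-right vertex involution), which is the morph-equivariant
equivalent at half the cost; `mirror_scan` for raw scans exists for
data preparation.

## Known limitations

* The NICP distance term uses closest-point correspondences only;
  sliding along the surface is controlled by stiffness and landmarks,
  not eliminated, so point identifiers can drift tangentially on
  feature-poor regions (real cohorts mitigate this with curvature-rich
  anatomy).
* `M` indefiniteness is handled by eigenvalue clipping rather than a
  provably PSD construction (e.g., an FEM consistent mass matrix); the
  clipped spectrum has been positive on all tested data.
* Mirror augmentation makes laterally asymmetric classes (coronal)
  symmetric *in distribution*, which caps what mean-based classifiers
  like LDA can extract from asymmetry directions — visible as residual
  control/coronal confusion in both the synthetic study and the
  clinical counts.
* The generator's deformity fields are smooth low-order bumps; they do
  not emulate photogrammetry artifacts (holes, isolated parts) and the
  preprocessing that removes them is out of scope.
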