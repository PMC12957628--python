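# Methods

`craniomorph` implements a geometric-morphometric pipeline for estimating
sex from the exterior (exocranial) surface of the human cranium, together
with a synthetic cranial-population generator that lets every stage be
tested without CT data. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic experiments do and do
not demonstrate.

## Exocranial surface extraction

Raw cranial surfaces include endocranial walls, sinus cavities and other
interior geometry that carries segmentation noise rather than anatomy. The
exterior surface is isolated automatically by visibility culling: an
axis-aligned cube is placed around the mesh with its centre at the vertex
centroid and a side length of 100 times the maximum pairwise vertex
distance, and visibility is probed from the cube's 8 corners, 12 edge
midpoints and 6 face centres (26 viewpoints). A face is kept when it is
visible — no other triangle intersects the open probe segment — from at
least `min_views` viewpoints (default 2).

Choices the construction leaves open, and how they are resolved here:

- **What "a face is visible" means.** Visibility is defined for points; we
  probe each face at its centroid, offset by ε = 1e-5 × cube side along
  the face normal toward the viewpoint's side (a per-face `any-vertex`
  probe rule is available). The probed face and all faces sharing a vertex
  with it are excluded as occluder candidates.
- **Ray test.** Möller–Trumbore with a relative degeneracy tolerance of
  1e-9 computed per (segment, triangle) pair, so the verdict does not
  depend on how pairs are batched. Grazing edge hits count as occlusion
  (conservative: a face is only kept on unambiguous visibility).
- **Acceleration.** A median-split AABB BVH with batched slab-test
  traversal. Its contract is exact agreement with the exhaustive
  all-triangle scan, which the tests enforce on random non-convex
  surfaces.
- **Invariance.** Counts are exactly translation invariant (the cube
  follows the centroid). They are *not* exactly rotation invariant — the
  cube stays axis-aligned while the specimen rotates — though keep/remove
  decisions are stable far from the 2-view threshold.

## Dense correspondence (CPD-DCA)

Statistics require the same anatomical location to occupy the same matrix
column in every specimen. Correspondence is established in four steps:

1. **Landmark GPA.** Generalized Procrustes analysis of the eight
   craniometric landmarks (glabella, inion, opisthion, nasospinale,
   mastoidale dx/sin, zygomaticofrontale dx/sin) gives each specimen a
   rigid transform into a common frame. Landmarks are used *only* for this
   alignment.
2. **Non-rigid CPD.** Each rigidly aligned surface is deformed onto a
   template ("base") mesh by coherent point drift: the moving cloud is a
   Gaussian mixture whose centroids move through a motion-coherent field
   `T(Y) = Y + G W`, with `G` a Gaussian kernel of width β. EM alternates
   soft assignments with a regularised solve for `W`; σ² is tracked and is
   non-increasing to tolerance.
3. **Quasi-landmarks.** For every base vertex, the nearest deformed
   specimen vertex is found; its position in the specimen's *rigid*
   (pre-deformation) frame is recorded, so real specimen geometry — not
   the smoothed CPD field — enters the statistics. Matches farther than
   `prune_factor` (default 3.0) × the median match distance are masked
   out; masks are intersected across specimens to keep the matrix
   rectangular.
4. **Second GPA** over all surviving quasi-landmarks, which suppresses the
   residual influence of landmark placement error. *Form* space keeps each
   specimen's scale; *shape* space normalises centroid size.

Parameter defaults, all config-exposed:

| parameter | default | meaning |
|---|---|---|
| β | 0.5 × cloud RMS scale | deformation smoothness length |
| λ | 2.0 | coherence regularisation weight |
| w | 0.1 | uniform-outlier mixture weight |
| tol, max_iter | 1e-6, 150 | EM stopping rule |
| low_rank_modes | 100 (clouds > 5000 pts) | kernel eigendecomposition rank |
| prune_factor | 3.0 | quasi-landmark pruning threshold |

β deserves a comment: narrow kernels (≲ 0.2 × RMS scale) let individual
points slide to wrong neighbours and the recovered field is *worse* than no
deformation at all on known-warp benchmarks; 0.5 × RMS scale recovers
smooth warps to close to the noise floor and matches the magnitude used by
common CPD implementations on unit-scale data.

The base mesh defaults to the specimen whose landmark configuration is
closest to the landmark-GPA consensus (minimising average deformation); any
specimen can be designated instead.

**Frame convention.** A GPA solution is only defined up to a global
rotation. We canonicalise the output frame (consensus principal axes,
deterministic signs, determinant +1) so that quasi-landmark rows are
well-defined quantities: rigidly moving any input specimen leaves every
output row unchanged to numerical tolerance, a property the tests verify
end to end.

## Variability and dimorphism statistics

- **Centroid size** `CS = sqrt(Σ ||p_i − centroid||²)`, the standard
  geometric-morphometric size measure (mm).
- **High-dimensional PCA.** The quasi-landmark matrix has ~3k columns per
  specimen (≈100k for 50,000-triangle surfaces), so components are
  computed through the n × n Gram matrix of centred rows; scores and
  variances are identical to the direct covariance eigendecomposition (up
  to component sign), which a dual-route test enforces. At most n − 1
  components are returned.
- **Difference maps.** Per-vertex dimorphism is the male-mean minus
  female-mean displacement projected on the outward unit normal of the
  grand-mean surface (mm in form space, dimensionless in shape space).
  Using grand-mean normals (rather than per-group surfaces) keeps the map
  exactly antisymmetric under group swap. Maps export as the PLY `quality`
  vertex property; colour rendering is presentation-layer and out of
  scope.
- **ANOVA / Tukey HSD.** The dependent variable defaults to centroid size
  (any per-specimen scalar can be passed). Sex × population ANOVA uses
  Type II sums of squares by default (Type III with sum-to-zero contrasts
  available) via statsmodels; pairwise population comparisons use the
  Tukey–Kramer studentised-range test (scipy), reported as a symmetric
  p-value matrix with unit diagonal. Whether PC1 "is size" is *measured*
  (`pc_size_correlation`), not assumed.

## Sex classification

A radial-kernel SVM is trained on the first m principal-component scores,
m swept over 1..30. Leave-one-out cross-validation scores each m, and the
*lowest* m attaining the maximal LOOCV success rate is selected; the final
model is refit on all training specimens. PCA is fit once on the training
pool and held fixed across folds (the score matrix is an input to the
sweep, not refit per fold). Defaults: C = 1, γ = 1/(m × score variance)
(`scale`); an inner hyperparameter grid search is deliberately absent.

Posterior probabilities P(male) come from Platt-style sigmoid calibration
fitted on internally cross-validated decision values
(`CalibratedClassifierCV(SVC(), method="sigmoid", ensemble=False)`), and
are monotone in the SVM decision value. Decisions use a symmetric band:
male if P(male) ≥ t, female if P(male) ≤ 1 − t, otherwise *unclassified*;
t defaults to 0.9, the forensic high-confidence setting, and t = 0.5
classifies everything (ties go to male by the ≥ rule). Male is the
positive class throughout, making the over-calling tendency
Bias = FP / (FP + TN) well-defined; it is reported as undefined (not 0)
when no true female is classified. Threshold sweeps report hit / miss /
unclassified counts overall and per sex, plus the smallest t at which the
miss rate falls to 5% of the sample — the crossing point of the miss curve
with the 5% reference line (the set of thresholds meeting the bound is
upward-closed, so its largest element would trivially be the grid
maximum).

Cross-population transfer (`cross_population_apply`) requires test
specimens corresponded to the training base, projects them through the
training PCA reference, and embeds a provenance record (training
populations, m, space, threshold) in the report.

## Synthetic cranial populations

The generator grows skull-like meshes from an icosphere-based template:
an anisotropic ellipsoid (semi-axes 90 × 70 × 65 mm, adult neurocranium
proportions) with frontal and occipital prominences, eight landmarks bound
to surface vertices at anatomically motivated directions, and an optional
nested interior shell (fake endocranial structure) for extraction tests.
Specimen vertex displacement is

    pop_field + individual_field + is_male · δ · patch   (along normals)
    + iid noise,   then scale by g · s^is_male · exp(N(0, size_sd))

where `pop_field` is a population-shared smooth random field (spherical-
harmonic spectral synthesis, degrees 1–6, exponentially decaying power),
`individual_field` is each specimen's own such field, `patch` is a smooth
mask over the glabellar and occipital regions, δ the dimorphism amplitude,
s the male size factor and g the population scale. Both sexes share the
population field, isolating the dimorphism term.

The individual field and size jitter exist because i.i.d. vertex noise
alone is not a credible model of within-sex variation: PCA averages it
away almost entirely, the classifier becomes perfectly separable, and
out-of-distribution behaviour degenerates. Adult crania show smooth
individual shape variation and a within-sex centroid-size CV of a few
percent; defaults are 0.6 mm RMS and 2.5% log-SD. Setting both to zero
recovers the bare displacement formula, which the property tests of that
formula do.

The `table1` preset reproduces the study design: five populations (CZE
143, SVK 92, FRA 103, DEN 179, EGY 101; 618 specimens, 304 F / 314 M) with
population contrasts chosen once so the synthetic regime matches the
published one — single-population and combined classification accuracy in
the low-to-mid 90s, Danes weakly dimorphic (δ = 1.2 mm vs 3.0–3.5 mm,
male size 1.03 vs 1.06–1.07), Egyptians smaller overall (g = 0.93) with
the most distinct mean form. The `mini` preset divides all counts by five
(123 specimens) for fast runs. Default mesh resolution is icosphere
subdivision 3 (1,280 faces, 642 vertices), the desk-scale setting used by
the test suite and the acceptance script; pipelines targeting real-scan
fidelity can raise the resolution and the 50,000-face simplification
target.

**What the synthetic experiments show — and don't.** Generated cohorts are
vertex-homologous by construction, so study-scale experiments use the
`correspond_homologous` shortcut (the final GPA only); the full CPD path
is exercised separately on small studies, including a rigid-equivariance
check through the entire pipeline. Passing tests demonstrate that the
pipeline recovers known planted signals (dimorphic patches, size ratios,
population contrasts) and reproduces the qualitative transfer
phenomenology: a weakly dimorphic test population transfers worse than a
same-distribution control, and a globally size-shifted test population
fails male-first at the 0.9 threshold (smaller males land on the female
side of a form-space classifier; smaller females only become more
confidently female). They do not demonstrate accuracy on real crania:
real anatomy has regional correlation structure, asymmetry, secular
trends and segmentation artefacts the generator does not model, and
real-data accuracies depend on scanner protocols and population history
that no synthetic calibration can stand in for.

## Numerical choices and degenerate inputs

- Mesh loading welds vertices closer than 1e-6 × bounding-box diagonal
  (STL carries no vertex sharing); degenerate faces are dropped and
  counted. Simplification is quadric-error edge collapse with a link
  condition and normal-flip rejection, implemented in-package.
- GPA iterates to consensus change < 1e-10 (max 100 iterations);
  reflections are always forbidden; shape-space consensus is normalised to
  unit centroid size. Collinear configurations are rejected.
- `hd_pca` discards eigenvalues below 1e-12 × the largest; all-identical
  rows raise rather than return NaNs. Constant ANOVA responses, empty
  design cells, single-sex training pools and groups of size < 2 in Tukey
  comparisons all raise typed errors.
- LOOCV at n specimens performs exactly n fits per candidate m; sweeps
  cap m at the available component count.
- Every stochastic component draws from `numpy` Generator streams keyed
  by explicit seeds; study regeneration is bit-identical for a given
  (specs, seed).

## Known limitations

- Visibility counts are not rotation invariant (axis-aligned cube); see
  above.
- The quadric decimator is O(E log E) pure Python: adequate to ~10⁴ faces,
  slow at the 50,000-face pipeline target.
- CPD uses the full M × M kernel below 5,000 points; very large clouds
  rely on the low-rank approximation whose rank is a quality/runtime
  trade-off.
- Platt calibration on small training pools (< ~15 per sex) is coarse;
  posterior thresholds near 0.9 then behave conservatively (many
  unclassified).
- The generator's populations differ by smooth mean fields, dimorphism
  amplitude and size only; it cannot emulate covariance-structure
  differences between populations.
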