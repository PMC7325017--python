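# Methods

## Measurement model

The pipeline measures thickness change of three coupled layers of the cheek
between two timepoints of the same patient:

1. **Superimposition.** The post scan is mapped onto the pre scan by a
   proper rigid transform (rotation + translation, mm). The transform is
   estimated only from treatment-stable cranial structures: a closed-form
   least-squares (Kabsch/orthogonal-Procrustes) fit on paired stable
   landmarks, with the reflection guard (sign-correction of the smallest
   singular vector) so chirality is preserved, optionally refined by
   point-to-point ICP on a bone surface. ICP uses nearest-vertex
   correspondence through a k-d tree and a Kabsch update per iteration;
   accepted iterations never increase RMS. When no initial transform is
   supplied, vertex centroids are aligned first, which removes the
   translational component of the misalignment and widens the convergence
   basin considerably (a box-shaped test surface then recovers misalignments
   of at least 5° / 5 mm to ~1e-6°; from an identity start, pure
   translations of a few mm can strand point-to-point ICP in a
   lattice-shifted local minimum).

2. **Anatomical frame.** The Frankfort horizontal (FH) plane is the
   total-least-squares plane of bilateral Orbitale and Porion (smallest
   covariance eigenvector), oriented cranially using the Menton→Nasion
   direction so that the construction is rigid-equivariant. The midsagittal
   plane is perpendicular to FH and contains ANS and PNS. These give the
   orthonormal anteroposterior / superoinferior / lateral axes used by every
   2D construction ("projected on the sagittal plane" = coordinates along
   the AP and SI axes). FMA is the angle between FH and the supporting line
   through projected Menton that keeps the projected mandibular lower-margin
   contour above it (the shallowest Me→sample ray); ANB is the signed angle
   between the projected N→A and N→B rays, positive when A is anterior to B
   (positive = Class II direction, matching the positive means reported for
   such cohorts).

3. **Region extraction.** The masseter area of the face (MAS) is cut from
   the facial surface by four planes perpendicular to the sagittal plane.
   "Tangent lines" are implemented as axis-aligned supporting lines of the
   projected contours — FH-parallel for the zygomatic-arch and
   mandibular-body lower margins (touching from below), FH-perpendicular at
   the most anterior projected point of the masseter mesh — because a
   supporting line is the operational meaning of a tangent in a
   cephalometric tracing and is deterministic; the posterior boundary is the
   projected line through the articular-tubercle midpoint and the posterior
   gonial point. The anterior tangent is taken from the *pre-treatment*
   masseter so pre and post are cut by the identical region (one boundary
   per patient, removing a pre/post inconsistency the procedure itself does
   not address). Since planes perpendicular to the sagittal plane extend
   across both hemifaces, the per-side measurement additionally restricts
   the face model to the requested side of the sagittal plane. Triangles
   crossing a clipping plane are split at the plane; an empty result names
   the offending plane.

   The muscle's lateral half is obtained by PCA of its vertex cloud.
   Principal axes are labeled anatomically — assigned bijectively to the
   superoinferior / anteroposterior / mediolateral roles by maximal |cosine|
   with the frame axes (Hungarian assignment), then sign-aligned — rather
   than by eigenvalue order, which can swap for squat muscles; a near-tie of
   leading eigenvalues (1e-9 relative) is flagged and resolved by the same
   frame alignment. The cut plane passes through the centroid and is spanned
   by the SI and AP axes; the kept half lies laterally.

4. **Deviation analysis.** "Average deviation" between two surfaces is the
   area-weighted mean of nearest-point distances sampled at the reference
   (pre-treatment) surface's vertices, each weighted by its barycentric
   vertex area. Nearest points are exact: a k-d tree over triangle
   centroids prunes candidates, an exact vectorized point-to-triangle
   projection evaluates them, and a conservative ball query re-checks any
   point whose candidate set cannot certify the minimum; ties break toward
   the lowest triangle index, so results are deterministic. The signed
   variant carries −sign(n̂·(q−x)), making medial displacement of the moved
   surface — a thickness decrease — positive. Whether the original
   deviation analysis was signed or absolute is not documented; signed with
   the pre surface as reference is adopted because it reproduces the
   reported near-zero fat-change means with larger SDs, which an absolute
   metric cannot produce.

5. **Decomposition.** ST (total soft tissue) is the unsigned average
   deviation from the muscle's lateral surface to the facial surface;
   FT change = ST_pre − ST_post exactly; MAS, MM, FT are each the mean of
   the left and right sides. MAS ≈ MM + FT holds exactly only for parallel
   offsets; the test suite bounds the closure error at 0.05 mm on
   uniform-offset phantoms.

## Synthetic phantoms

The phantom replaces unavailable patient imaging with geometry whose every
measured quantity has a closed-form ground truth:

* **Muscle:** a superellipsoid (exponent 4 — slab-like with flat caps) with
  half-extents 28 × 18 × 7 mm (SI > AP > ML), the proportions of an adult
  masseter, one per side, lateral to the midline at ±45 mm.
* **Skin:** the muscle surface offset outward along its *analytic* implicit
  gradient normals by a fat field f = 8.3 mm ± 0.5 mm of smooth sinusoidal
  variation (matching reported pre-treatment soft-tissue thickness ~8.3
  mm). The face model is the closed offset of the whole muscle rather than
  an open lateral sheet: parallel offsets make the nearest-point distance
  field exact everywhere and avoid free-edge artifacts; photorealism is out
  of scope. The medial-facing patch this adds to the MAS region carries the
  same offset ground truth and does not bias the measurement.
* **Post state:** the muscle surface moves inward along the local outward
  normal by δ_MM and the skin by δ_MM + δ_FT — exact inward parallel
  surfaces, so the signed average deviation of MM is δ_MM, of MAS is
  δ_MM + δ_FT, and ST decreases by δ_FT. Defaults δ_MM = 1.284 mm,
  δ_FT = 0.006 mm reproduce the reported extraction-group means. All post
  geometry and landmarks then undergo a configurable true rigid transform.
* **Skull block:** a 70 × 50 × 20 mm box with its 8 corners as stable
  registration landmarks and a subdivided surface for ICP — the
  treatment-stable "cranial base" analog.
* **Landmarks:** generated consistently with the target angles — the
  mandibular contour rises posteriorly from Menton at exactly FMA (default
  25°), the A/B rays subtend exactly ANB (default 4°) at Nasion — and with
  the boundary structures (zygomatic margin at mid-muscle height, posterior
  boundary line behind the muscle) so all four MAS planes genuinely cut the
  face model.
* **Noise:** optional i.i.d. Gaussian vertex jitter along normals
  (default SD 0); the seed fixes all randomness bitwise.

Meshes are direction-scaled icospheres; the subdivision level is chosen so
the edge length meets the `resolution_mm` target (default 2 mm, ~20k
triangles per muscle).

What the phantom does **not** emulate: CT intensity physics (volumes are
two-level), anatomically realistic mandible/zygoma geometry, spatially
correlated or heteroscedastic treatment change, landmark placement error.
Passing recovery tests therefore demonstrates correctness of the geometry
and statistics pipeline under known ground truth, not robustness to
segmentation error or anatomical variation in real CBCT data.

### Known discretization behaviour

MAS and MM changes are differences of parallel surfaces and are recovered
almost exactly at any resolution (relative error ~1e-6 at default
settings). ST is a distance *level*, not a difference: chords of the
faceted target surface lie inside the true offset surface, biasing ST low
by the chordal sagitta (~1.4% at the 2 mm default, ~3% at 5 mm). The FT
change, a difference of two ST values, inherits a partially cancelling
bias of a few hundredths of a mm — the reason the FT recovery tolerance is
quoted as an absolute 0.05 mm plus 5% rather than purely relative, and the
reason resolution-convergence of FT is assessed on the ST scale.

## Cohort simulator

Covariates and thickness changes are drawn from a Gaussian copula: the
latent Pearson correlation is 2·sin(πρ/6), the exact bivariate-normal
inverse of the Spearman target, and marginals are Gaussian with
group-specific means/SDs (a monotone transform of the latent variable, so
ranks — and Spearman — are preserved). If an entrywise-transformed latent
matrix loses positive semi-definiteness it is projected to the nearest
correlation matrix; a non-PSD *target* is an error. The default spec
encodes the published two-group structure (22 extraction / 20
nonextraction; group means/SDs for duration, age, FMA, ANB, the three
thickness changes, ST_pre; the whole-sample 8×8 Spearman matrix, which is
positive definite as printed). An optional linear response model can
overwrite a column for regression-recovery experiments. Zero SDs produce
the group means exactly.

## Statistics

* **Summary-statistic t tests** operate on (mean, SD, n) triples so printed
  tables can be re-tested directly. The two-sample default is the pooled
  (equal-variance Student) form — the convention of the software the
  original analysis used — with Welch as a first-class variant, since the
  reported between-group duration p-value is reproduced only by Welch while
  the thickness comparisons are reproduced by the pooled form.
* **Normality gate:** Shapiro–Wilk per group at α = 0.05 (no specific test
  is documented in the source analysis; Shapiro–Wilk is the common default
  at these sample sizes). Groups with n < 3 or zero range fall back to the
  rank path with a flag.
* **Rank tests:** Mann–Whitney U and Wilcoxon signed-rank are exact by full
  enumeration (all group labelings / sign assignments, average ranks so
  ties are handled) for combined n ≤ 12, two-sided p = 2·min(tails) capped
  at 1; larger samples use the tie-corrected normal approximation with
  continuity correction (agrees with enumeration to < 0.01 at n = 6+6).
* **Regression:** OLS on z-scored response and predictors (the dummy
  z-scored like any column) gives standardized β with the p-values of the
  unstandardized fit; backward elimination at α = 0.05 mirrors the
  "included variables" reporting style, with the full-model fit always
  available alongside. VIF_j = 1/(1−R²_j). No multiple-testing correction
  is applied anywhere, matching the original analysis.
* **ICC:** two-way mixed, absolute agreement, single measures — ICC(A,1)
  from the ANOVA mean squares (the specific form is not documented in the
  source; A,1 is the appropriate form for repeated measurements by fixed
  examiners). Cross-checked against an independent implementation in the
  test suite.
* **Power:** smallest integer n per group whose two-sided two-sample t
  power (noncentral-t) reaches the target; d = 1.0 at power 0.80, α = 0.05
  gives n = 17.

## Problem sizes and numerical choices

Default phantom meshes target 2 mm edges (~20k triangles per muscle); the
property-test suite uses a 5 mm target where only invariances are asserted,
and the recovery tests run ten phantoms at the default resolution with
misalignments up to 5° / 5 mm. The cohort-recovery checks use n = 10⁵
copula draws. ICP tolerance defaults to 1e-4 mm RMS improvement, 50
iterations. Plane/axis orthogonality is enforced to 1e-9; marching-cubes
isosurfacing of binary masks applies a 1-voxel Gaussian pre-filter (the
usual anti-aliasing step after threshold segmentation — raw staircase
surfaces overestimate a sphere's area by ~8%, filtered ones are within
0.5% at 0.5 mm spacing and converge as spacing shrinks); NIfTI affines
with off-diagonal rotation are rejected rather than reinterpreted, as the
in-memory convention is world = origin + index·spacing.

## Limitations

* The registration stand-in is landmark/surface-based, not voxel-intensity
  based; no claim is made about replicating any proprietary
  superimposition's error characteristics.
* Muscle segmentation from real CBCT (the learning-based step in the
  original workflow) is out of scope; phantoms supply muscle surfaces, and
  a threshold-segmentation route exists for volumes with a configured
  threshold (no universal default exists).
* Whether the MAS region should be re-cut independently on the post model
  is undocumented in the source procedure; this implementation reuses the
  pre-built boundary for both timepoints.
* The cohort simulator uses one shared copula across groups; real
  between-group correlation structure may differ.
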