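# Methods

This note documents the models, the numerical choices, what the synthetic
testbed does and does not emulate, and the design decisions taken where
the problem was genuinely open.

## Problem setting and data model

All computation assumes *dense point correspondence*: every skull mesh in
a study shares one triangle topology, every face mesh shares another, and
vertex *i* denotes the same anatomical location in every sample.  A mesh
is then fully described by its flattened vertex vector
(x₁,y₁,z₁,…,x_N,y_N,z_N) in millimetres, a training set by two matrices
**S** (M × 3N_s) and **F** (M × 3N_f), plus per-sample age (years) and BMI
(kg/m²).  Establishing the correspondence itself (non-rigid registration
of raw surface scans or CT segmentations) is out of scope; inputs are
assumed pre-corresponded, and the synthetic generator produces them
corresponded by construction.  Pose normalization is provided as optional
anchor-based plumbing (`normalize_pose`): the anchor centroid moves to the
origin, mean anchor distance scales to 1, and an anchor-derived orthonormal
frame fixes rotation — a deliberately landmark-free stand-in for anatomical
(Frankfurt-plane) alignment, which would require landmark detection.

## Region segmentation

Per-vertex features concatenate the vertex's mean position (3 columns)
with its centered across-sample coordinate trajectory (3M columns); each
column is standardized, and the trajectory block is rescaled so its total
variance is 25% of the position block's (`traj_weight`).  The weighting
matters: per-vertex trajectories vary *smoothly* over a mesh, so a fuzzy
clustering driven mostly by them has no discrete cluster structure to find
and its centers coalesce; position-dominant features anchor the partition
spatially while the trajectory block still pulls boundaries toward
co-moving vertex groups.

The feature matrix is denoised by robust PCA (principal component pursuit
solved by inexact augmented Lagrangian; λ = 1/√max(N,d′), multiplier
growth ρ = 1.05 — aggressive schedules satisfy the split X = L + S quickly
but freeze an inaccurate L/S allocation), then projected to d = 6
principal dimensions (deterministic sign convention: the largest-magnitude
loading of each component is positive).

Fuzzy c-means with fuzzifier m = 2 and C = 5 clusters alternates the
center update v_i = Σ_j u_ij² x_j / Σ_j u_ij² with the membership update
u_ij ∝ ‖v_i − x_j‖^(−2/(m−1)) until the sup-norm membership change falls
below 1e-5 (≤ 300 iterations).  Memberships per vertex sum to 1 at every
iteration and the objective J = Σ u_ij^m ‖v_i − x_j‖² is non-increasing;
both are recorded for inspection.  Coincident point/center pairs receive
full membership in that center.  m = 2 clusterings can still degenerate
(coalescing centers, or a cluster collapsing onto a handful of vertices);
`segment_modality` therefore accepts a partition only if every cluster
holds ≥ 1% of the vertices, and otherwise walks a deterministic ladder of
k-means++ init seeds, then of lower feature dimensions (few-dimensional,
position-dominant features cluster most stably).  Clusters are named
anatomically from centroid geometry: largest = frame; of the rest, the two
most lateral are the eyes (left = +x), the higher of the remaining two is
the nose, the lower the mouth.

Regions are defined on the *face* and carried to the skull by angular
nearest neighbour (each skull vertex takes the label of the face vertex
with the closest direction from the respective centroids), so a region's
skull model sees exactly the bone under the soft tissue its face model
predicts.  Clustering the two modalities independently and matching
regions by name was tried first and rejected: the independent partitions
shared almost no vertices (Jaccard overlap ~0.01 between same-named
regions on synthetic data), leaving the skull-side model uninformative
about its paired face region.

An optional greedy merge (`merge_similar_regions`) combines clusters whose
centers are closer than a threshold τ; it is off by default since C = 5 is
already the target region count.

## Regional latent spaces (GP-LVM)

Each modality × region is modelled by a GP-LVM: D = 3 × (region vertex
count) output dimensions share one ARD squared-exponential kernel and one
latent configuration X (M × q); the data are centered and the mean stored.
The log marginal likelihood

L = −(D/2) log|K+σ_n²I| − ½ tr((K+σ_n²I)⁻¹ Y Yᵀ) − (MD/2) log 2π

is maximized jointly over X and the log-hyperparameters (per-dimension
lengthscales M_d, signal variance σ_f², noise variance σ_n²) by L-BFGS-B
with analytic gradients (verified against central finite differences to
rel. 1e-5 in the tests), at most 300 iterations inside the pipeline (500
for standalone fits), gradient tolerance 1e-6, and a Cholesky jitter
ladder 0 → 1e-10 → 1e-8 → 1e-6 (relative to the mean diagonal).  X is
initialized from PCA scores scaled to unit RMS; hyperparameters at
M_d = 1, σ_f² = mean data variance, σ_n² = 1% of it.

The latent dimension q defaults to the smallest PCA dimension explaining
99% of the region's variance, capped at 8 and at M−2.  A 95% threshold
was found to starve the models (q = 2–3 where 6+ meaningful directions
exist; with 0.2 mm vertex noise against multi-millimetre shape signal the
99% criterion still excludes the noise floor).

Decoding is the standard GP posterior mean plus the stored data mean, with
predictive variance clipped to [0, σ_f² + jitter].  Encoding a new shape —
needed because an unknown skull arrives in data space, not latent space —
minimizes the negative predictive log-density ½D log s²(x) + ‖y−μ(x)‖²/2s²(x)
(s² = posterior variance + σ_n²) by L-BFGS with analytic gradients,
started from the latent coordinate of the nearest training shape.  Using
the full predictive density rather than squared error alone keeps the
projection consistent with the probabilistic model: far-from-manifold
latents are penalized through the variance term.

## Skull→face regression (LSSVR)

Per region, a multi-output LSSVR maps skull latent coordinates (z-scored
per input dimension) to face latent coordinates — one independent
single-output model per face-latent dimension, all sharing the same
support inputs and kernel, so the (n+1)×(n+1) KKT factorization is done
once with multiple right-hand sides.  The trained coefficients satisfy
Σα = 0 identically (bias constraint).  The regression target is the face
*latent* vector; decoding through the face GP-LVM restores the shape.

Hyperparameters (C, σ²) are tuned by seeded 5-fold cross-validation over
log-spaced grids C ∈ {10²…10⁵}, σ² ∈ {10⁰…10³}, centered on the customary
starting point (1000, 100).  Tuning is on by default: with fixed σ² = 100
on z-scored latent inputs the RBF Gram matrix is nearly rank-one
(all pairwise distances ≪ σ), which makes the dual solution ill-conditioned
and produced occasional worst-case chain errors above 20 mm on some
populations; CV reliably selects a width matched to the latent scale.

Attribute conditioning appends z-scored age and BMI columns (training
statistics stored and reused at reconstruction time) to the regression
inputs.  Zero-variance attribute columns are rejected.

## Region fusion

Reconstruction runs per region — encode skull region, regress, decode face
region — and the five predictions are assembled on the global face
topology.  Every region model's *support* is its region plus a collar
reaching one blend band into the neighbouring regions, so at each region
boundary two models hold a genuine opinion; the spec of the splice is:

* **Base**: the mean training face with frame vertices replaced by the
  frame model's prediction, and each feature-region boundary vertex set to
  the averaged prediction of the *other* models whose collar covers it.
* **Bands**: the part boundary B₀ is shrunk k rings into the part
  (contour B₀′) and k rings outward (B₁′), with
  k = max(1, round(S₀ / mean edge length)); S₀ defaults to 3 mean edge
  lengths.  Ring distance is graph BFS distance on the global topology —
  robust on irregular meshes where geodesic tracing is brittle.  Sides
  thinner than k rings reduce k with a warning.
* **Splicing**: midpoint targets P₂ = (P₀+P₁)/2 at the seam; a 3-D
  thin-plate spline f₀ (polyharmonic r³ kernel + affine part, pure
  interpolation) fixes B₀′ and sends P₀ → P₂, its partner f₁ fixes B₁′ and
  sends P₁ → P₂.  Both are exact at their controls, so the two sides meet
  at the seam to machine precision and everything beyond the contours is
  untouched bit-for-bit.  Coplanar control sets (flat patches) fall back
  to the minimum-norm least-squares solution, still exact at controls.
* **Rigid positioning** (orthogonal Procrustes with det(R) = +1, no
  scaling) is implemented and is the default for standalone
  `fuse_regions`, but the pipeline disables it: decoded regions already
  live in the training canonical frame, and aligning a correct prediction
  onto the base (whose feature-region interior cannot be a faithful
  reference) was measured to double the test error.
* **Overlaps**: with regions that tile the surface, adjacent parts' bands
  would always collide; the pipeline resolves collisions first-come
  (largest boundary first, `on_overlap="skip"`), while standalone use
  defaults to raising, since with feature regions separated by frame an
  overlap signals misuse.

The global baseline is the identical pipeline with one region (the whole
mesh) and no fusion; `clusters=1` in the config degenerates to it exactly.

## Synthetic testbed

The generator emulates the statistical role of a paired skull/face CT
database.  A closed deformed-ellipsoid grid (default 40×40 + 2 poles ≈
1,602 vertices, semi-axes 70/80/85 mm) carries five planted regions —
large anterior patches for eyes/nose/mouth, remainder frame — defined by
angular windows with raised-sine tapers.  Per sample:

* regional latents z_r ~ N(0, I_q), q = 2 per region;
* skull displacement: radial, linear in z_r through smooth harmonic bases
  restricted to the region window;
* face displacement: radial, through a *distinct nonlinear* map of the
  same z_r (linear + centered quadratic + sine warp, O(1) coefficients,
  scaled by the region amplitude — scaling the warp frequency instead
  would make the relation unlearnable at any sample size);
* soft-tissue offset along the outward direction: base depth 10 mm plus
  β_bmi (bmi−24) w_b(v) + β_age (age−45)/10 w_a(v) with β_bmi = 0.3 mm per
  BMI unit, β_age = 0.5 mm per decade, and smooth positive weight fields;
  age ~ U(19, 75), bmi ~ N(24, 3);
* i.i.d. Gaussian vertex noise, σ = 0.2 mm per coordinate, on both meshes.

Region amplitudes default to 2.5 mm (eyes), 3 mm (nose, mouth) and 4 mm
(frame).  The defaults give a population whose total latent dimension (10
regional factors + 2 attribute directions) exceeds the default latent cap
(8), so the global baseline is genuinely capacity-limited while each
regional model is not — the designed analogue of the finding that regional
modelling beats global modelling.  The ground-truth record can replay any
sample noise-free as an error floor.

What the testbed does *not* emulate: anatomical geometry and topology of
real skulls (orbits, nasal aperture, mandible), registration error and
correspondence drift, non-radial soft-tissue deformation, sex effects, and
measurement artefacts beyond i.i.d. noise.  Passing tests demonstrate that
the pipeline recovers known region-structured skull→face relations at
realistic noise — not that it attains any particular accuracy on real CT
data.

## Evaluation protocol and typical figures

Default study conditions: one population of 72 pairs, split 60 train / 12
test with a seeded shuffle.  On these conditions the regional pipeline
reaches ≈ 0.8–1.4 mm mean test averageError across generator seeds, versus
≈ 0.9–1.5 mm for the global baseline and ≈ 2–4 mm for the mean-face
predictor; the regional margin over the global baseline is modest (as in
the source domain, where regional methods win by ~10%) and can invert at
an occasional population draw.  Error decreases monotonically in training
size over 20/40/80 (mean over three seeds).  The attribute-conditioned
pipeline responds to BMI 20 → 30 with ≈ +2 mm mean outward offset and cuts
the unexplained attribute variance, roughly halving test error.  All of
these are recomputed, never stored, by `scripts/acceptance.py` and
`tests/test_acceptance.py`.

## Determinism

Every stochastic step (population draw, train/test split, k-means++ inits,
CV folds) derives from explicit integer seeds; L-BFGS and all linear
algebra are deterministic.  Retraining with the same config reproduces
model parameters to 1e-12 and evaluation CSVs byte-for-byte.

## Known limitations

* Segmentation quality on real data is untested; the FCM feature design
  (position-dominant, trajectory-refined) was calibrated for stability on
  smooth synthetic surfaces.
* The GP-LVM uses dense Cholesky factorizations: fine for M ≲ a few
  hundred samples, not for thousands (no sparse/inducing-point path).
* `encode` is a local optimizer; a multimodal posterior could trap it in
  the wrong basin despite the nearest-neighbour start.
* Fusion assumes the regional predictions share a canonical frame; truly
  independent regional coordinate systems would need the rigid-positioning
  step re-enabled with a trustworthy base.
* Attribute conditioning is linear-in-features through the kernel map; no
  causal claim about age/BMI is implied.
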