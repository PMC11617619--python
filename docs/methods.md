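# Methods

This note documents the models, procedures and numerical choices behind
`paniclekit`: a geometry-processing toolkit for extracting panicle length
and volume from smartphone-video 3D reconstructions of field-grown rice
panicles. The neural components of such a workflow — structure-from-motion
pose estimation, learned 2D segmentation, radiance-field training — are
consumed as files (poses, candidate/rough masks, density grids); everything
downstream of them is implemented and validated here.

## Pose filtering

Hand-held orbit video yields frames whose cameras do not all point at the
target. Two steps remove them:

1. **Scene center.** Each camera contributes a viewing ray (position `p_i`,
   unit direction `d_i`). The scene center is the least-squares closest
   point to all rays, minimizing `Σ ||(I − d_i d_iᵀ)(x − p_i)||²`, solved in
   closed form via the 3×3 normal equations. It is exact when the rays
   intersect and deterministic always; a condition number above 1e12
   (near-parallel rays) raises a degenerate-geometry error. The RMS
   point-to-ray distance is reported as a quality residual.
2. **Angular filter.** A frame is kept iff the angle between its viewing
   direction and the camera-to-center line is at most `max_angle`
   (default 20°; the boundary value is kept because the exclusion rule is
   strict-greater). The filter is monotone in the threshold.

The center is estimated once from all cameras; iterative re-estimation
after filtering changed retained sets by at most one frame on jittered
synthetic rigs and is left off by default.

Frame subsampling of the source video is "keep every `round(src/target)`-th
frame" over an ordered frame sequence; decoding is out of scope. A 15-s
30-fps clip subsampled at 15 fps yields exactly 225 frames.

## Mask fusion

Inputs per frame: generic candidate masks with an opaque stability score in
[0, 1], and rough instance masks labelled *panicle* or *tag_label*.
Processing:

- **Candidate filter:** drop candidates with area < 10,000 px or stability
  < 0.8 (strict inequalities, so exact boundary values survive).
- **Erosion:** each rough mask is split by a disk erosion (radius 5 px)
  into an inner region and an edge ring. If erosion would empty a thin
  mask, the radius halves until the inner region survives; at radius 0 the
  whole mask is the inner region (warned).
- **Prompts:** positive points are sampled uniformly without replacement
  from the inner region — 3 if its area is under 20,000 px, 4 under
  50,000 px, else 5 (a monotone rule spanning the 3–5 range) — and 3
  negative points from the ring. An empty ring falls back to a 5-px
  dilation band outside the mask.
- **Matching:** a candidate is selected iff it contains ≥1 positive and no
  negative (negatives veto). Selected candidates merge by pixelwise union,
  which makes the output monotone in the candidate set.
- Panicle and tag instances are fused independently (per-instance derived
  seeds) and OR-ed, since both objects must survive into the 3D scene. The
  fused mask becomes the alpha channel of the frame's RGBA output.

The veto rule is the strictest reading of positive/negative prompting; a
down-weighting alternative was not implemented because union merging has
no score to down-weight.

## Segmentation metrics

Precision, recall, F1 and IoU come from exact pixel confusion counts.
Boundary overlap (BO) is the Jaccard index of edge-pixel sets, where a
foreground pixel is an edge pixel iff a 4-neighbor is background or
out-of-frame (8-connectivity available via a flag); no distance tolerance
is applied — the definition is pure set intersection over union. When a
metric's denominator is zero it scores 0, except two empty masks, which
score 1.0 with a warning so batch evaluation never aborts. `F1 =
2·IoU/(1+IoU)` holds as an algebraic identity and is exercised in the
tests. Dataset aggregation is an unweighted mean over images. Trait
agreement uses `R² = 1 − SS_res/SS_tot` against the identity line (not a
refitted regression), RMSE, and `rRMSE = RMSE / mean(measured) × 100 %`.

## Density grid to point cloud

The radiance field's exported density grid (`values`, `origin`, scalar
`spacing`; index `(i,j,k)` maps to `origin + spacing·(i,j,k)`) is
isosurfaced with lookup-table marching cubes (scikit-image) and the mesh
vertices, deduplicated, form the working cloud. The iso level defaults to
the midpoint of the value range — a reasonable default for uncalibrated
density exports, configurable when the field's scale is known. An iso
outside the value range returns an empty mesh with a warning rather than
raising, so iso sweeps are cheap. On an analytic signed-distance sphere at
64³ the vertices lie within 0.005 grid spacings of the true surface.

## Cloud semantics and calibration

- **Clustering:** DBSCAN (scikit-learn) with `min_pts = 10`. The default
  radius is adaptive: 4× the median nearest-neighbor distance. For a
  Poisson-like cloud the expected neighbor count within `f` median-NN radii
  is `(4/3)π(0.554 f)³` in a volume and `π(0.47 f)²` on a surface —
  independent of density — so `f = 4` gives ≈45 and ≈11 expected neighbors
  respectively, comfortably above `min_pts`, whereas `f = 2` gives ≈6 and
  ≈3 and fragments everything. Clusters under 100 points (inclusive keep at
  ≥) are relabelled noise.
- **Tag vs panicle:** per-cluster planarity `1 − λ₃/λ₂` from the covariance
  eigenvalues (λ₁ ≥ λ₂ ≥ λ₃). A flat tag scores ≈1, a volumetric panicle
  much lower; the most planar cluster becomes the tag, ties break toward
  the thinner cluster. This is the eigenvalue form of a normal-vector
  feature: cheaper and deterministic compared to per-point normal
  estimation.
- **Tag length X1:** a PCA-aligned oriented bounding box is computed, with
  the two in-plane axes refined by a minimum-area enclosing rectangle
  (shapely rotating calipers) of the in-plane projection — necessary
  because a near-square tag makes the in-plane eigenvalues degenerate and
  the raw PCA axes arbitrary. The points are then projected onto the plane
  of the box face with the median area (for a thin slab: the
  length×thickness side face), a minimum-area rectangle is fitted to the
  projection, and X1 is its longer side. A collinear projection
  (zero-thickness tag) falls back to the maximum spread, which is the same
  length.
- **Calibration:** `scale = X / X1` cm per scene unit, with X = 7.5 cm the
  tag's printed length. For volume extraction the cloud is additionally
  rescaled by `1/X1` so the tag has unit length ("label units") — the
  frame in which the 0.01-unit voxel grid is defined. This normalization is
  what makes the volume formula below dimensionally consistent.

## Trait extraction

**Length.** The panicle cluster is voxel-grid downsampled (leaf = 1/100 of
its bounding-box diagonal by default; one centroid per occupied cell). The
downsampled cloud is contracted by Laplacian-based contraction: per
iteration, each coordinate solves

    (w_L² LᵀL + w_H² I) P' = w_H² P

with `L = I − D⁻¹A` the umbrella Laplacian of the symmetrized 16-NN graph,
`w_L` starting at 1 and doubling per iteration (max 10), `w_H = 1`, and
stopping when the mean displacement falls below 1e-4 of the bounding-box
diagonal. A disconnected k-NN graph doubles k once, then errors. The leaf
default is a compromise measured on the synthetic scenes: 1/200 of the
diagonal quadruples the solve cost for no accuracy gain once terminal
extension (below) is applied.

The contracted cloud is summarized by farthest-point-sampled nodes (~1 per
2 leaf lengths) joined by a Euclidean minimum spanning tree; endpoints are
degree-1 nodes. Among all endpoint pairs, the unique tree path is
*admissible* if every turning angle along it is within `angle_limit`
(default 45°), where the tangents at a node are taken over a 3-node window
on each side — the multi-tangent form. The window matters: single-step
angles on contracted skeletons carry 40–100° one-node jitter at branch
junctions, while sustained turns into a lateral branch survive windowing.
The longest admissible path wins, which is what rejects branch tips as
endpoints; if no path is admissible (e.g. a symmetric star), the path
minimizing the maximum turning angle is returned with a warning.

Contraction systematically pulls the terminal nodes inward from the organ
tips (the smoothing term has no data beyond a tip to balance it; the bias
was ~10–20 % of length on synthetic tubes). Each end of the selected path
is therefore extended along its terminal tangent to the 99th-percentile
projection of the cloud points lying beyond it within a cylinder of radius
`max(1.5 r̂, 2 leaf)`, capped at `5 r̂`, where `r̂ = 1.4 × median
contraction displacement` estimates the local organ radius (for a uniform
disk cross-section the median radial distance is ≈0.71 r). The cap
prevents a branch lying beyond a tip from dragging the extension past the
organ boundary.

The path nodes are fitted with a cubic spline parameterized by cumulative
chord length (interpolating by default; a smoothing parameter is exposed
for noisier skeletons) and the in-scene length `L1` is its arc length by
adaptive quadrature (relative tolerance 1e-6). Fewer than 4 distinct nodes
fall back to the polyline length. The metric length is

    L = L1 × X / X1   (cm).

**Volume.** The panicle cloud in label units is voxelized at 0.01 units,
anchored at the cloud's own minimum corner (making the count
translation-invariant; anchoring at a world origin would shift counts by
±1 cell per axis). With `Num` occupied cells,

    V = Num × 0.01³ × X³   (cm³).

Both traits are invariant under rigid transformation and under rescaling
the scene when the calibration is recomputed (tested at scale factors 0.5,
2 and 10).

## Synthetic study conditions

The scene generator emulates the *geometry* a radiance-field export
produces, with analytic ground truth; it does not model photometry,
occlusion, wind motion, or learned-segmentation failure modes, so green
tests certify the geometric processing, not image understanding.

- **Panicle surrogate:** a solid tube of radius 0.75 cm around a drooping
  spline ~23.8 cm long (mature rice panicle scale), sampled uniformly in
  arc length × uniform disk. Ground-truth arc length is computed by
  quadrature (tol 1e-9); the solid volume is `πr² × arc length`, exact for
  a normal-disk sweep. Optional lateral spurs (default two, 6 cm × 0.35 cm
  radius, leaving at 55°) attach along the middle half of the stem; spurs
  much under ~5 cm are absorbed by the contraction and exercise nothing,
  and a spur at a stem end would model a forked tip, not a branch. Spur
  volume adds `πr_s²(L_s − s₀)` with `s₀ = r/sin α` the run needed to clear
  the stem surface.
- **Tag surrogate:** a 7.5 × 2.5 cm planar rectangle (3:1, only the
  7.5-cm length is normative), offset 8 cm from the stem, randomly tilted.
- **Density:** 400,000 panicle points ≈ 4 per trait voxel (the tube spans
  ~10⁵ voxels of 0.075 cm), matching the density of marching-cubes vertex
  exports; voxel counting needs multiple points per cell or occupancy
  undercounts (at 160,000 points the volume bias was −19 %).
- **Noise:** isotropic Gaussian, σ = 0.02 cm, a small fraction of the tube
  radius — reconstruction surface fuzz, not outlier structure.
- The camera-rig generator tilts exactly-aimed directions by prescribed
  angles about a perpendicular axis, so the assigned tilt *is* the view
  angle — an analytic oracle for the filter. The mask fixture splits a
  known silhouette into a dominant part plus small peripheral slices
  (capped at 4 % of area) with off-target distractors and
  deliberately weak candidates, and degrades a 12-px dilation of the truth
  into the rough mask with ≤4-px boundary bites, keeping the eroded inner
  region a superset of the truth.

All generators are bit-reproducible for a fixed seed; the pipeline fans a
single config seed out to per-stage seeds by stable hashing, so adding a
stage never perturbs another stage's randomness.

## Measured behavior (recomputed by `scripts/acceptance.py` and the test suite)

On the default study conditions: calibration scale error ≈1 %
(dominated by the minimum-rectangle fit over noisy extremes); end-to-end
panicle length within ~1–3 % and volume within ~3–5 % of analytic truth;
quarter-circle arc length within 1 %; DBSCAN identical to an O(N²)
density-reachability oracle on all random instances tried; mask-fusion
IoU ≥ 0.95 on every fixture seed.

## Known limitations

- The stem/branch discrimination assumes branches are shorter than the
  stem and leave it at a sustained angle; a branch longer than the
  remaining stem, or one grafted at a tip, can win the longest-admissible
  rule (the fallback then minimizes the maximum turn, which may still
  choose it).
- Volume counts occupied voxels of a *filled* cloud; hollow or
  surface-only reconstructions undercount interiors, and internal gaps in
  real panicles are treated as solid by dense reconstructions — a bias
  inherent to the voxel definition, not recoverable from geometry alone.
- The PCA box is not the exact minimum-volume box; the in-plane
  rectangle refinement corrects the axis where it matters (tag length),
  but strongly non-rectangular tags would need a different fit.
- Metrics treat empty-vs-empty masks as vacuously perfect (warned), which
  inflates averages if many empty frames are evaluated.
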