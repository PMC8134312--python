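# Methods

## Scope and conventions

The package implements the data-generation, labeling, pose-recovery and
evaluation machinery of a markerless hand-tool 6D pose system, excluding the
neural networks that would consume the data. Conventions, fixed once in
`drillpose.geometry` and inherited everywhere: camera frame x-right, y-down,
z-forward; pixels 0-based with centers at integer coordinates; lengths in
meters internally (metrics convert to mm/px/deg at the evaluation boundary);
SE(3) poses serialize as 4×4 row-major matrices.

## The stand-in hand model

The hand uses the MANO parameter layout — 18 pose parameters (3 global
axis-angle + 15 PCA coefficients mapped to 45 per-joint axis-angles) and 10
shape coefficients — but with self-contained procedural assets, since the
original assets are licensed and cannot be redistributed. The stand-in is a
308-vertex surface (subdivided palm box + 15 capped finger-segment
cylinders) over a 16-joint skeleton with 5 fingertip sites (21 reported
joints). Its pose basis is a 15×45 row-orthonormal matrix whose five leading
rows are per-finger curl directions (equal flexion of a finger's three
joints about the palm-plane axis), completed by QR from a seeded random
matrix: leading coefficients therefore produce anatomically sensible closing
motions while the basis remains orthonormal and generic. Shape modes are
explicit linear displacement fields (global scale, palm width, per-finger
length, thickness, spread, palm length). Joint positions are regressed from
the skinned surface by affine weight rows constructed to reproduce the rest
skeleton exactly, which makes the regressed joints equivariant under rigid
motion and consistent with the surface under pose and shape.

Consequences for interpretation: geometry, parameter counts, skinning, and
every downstream algorithm (grasping, fitting, propagation) exercise the
real contracts; what the stand-in does *not* emulate is the statistical
realism of human hand shape/pose spaces, so quantitative hand-fit accuracy
on real MANO data may differ. Real assets can be loaded through
`HandModelAssets` via the same npz schema.

## Grasp templates and augmentation

Seven wrap-grasp templates around the drill's pistol grip are authored
programmatically: the hand, fingers curled (leading PCA coefficients ≈ 1.6–
1.8, thumb at 60 %), is slid along an approach ray toward the grip in a
coarse-to-fine scan; the placement maximizing fingertip contacts subject to
the penetration tolerance is kept. The plausibility screen — the paper-side
procedure is unspecified, so this one is a declared, configurable stand-in —
requires (a) every implied joint axis-angle component within ±π/2, (b) max
hand-vertex penetration ≤ 5 mm (signed distance via generalized winding
number + closest-point query), and (c) ≥ 2 fingertip sites within 5 mm of
the tool surface. Dataset diversity comes from Gaussian augmentation of the
PCA pose (σ = 0.01) and shape (σ = 0.05) coefficients; the placement and
global rotation belong to the template and are not perturbed, since the
grasp's relation to the tool is what the template defines.

## Scene synthesis

The toy drill (body cylinder r = 25 mm × 180 mm, bit r = 4 mm × 100 mm with
the `tip` landmark and `bit_axis` along +x, pistol grip r = 20 mm × 110 mm)
is a union of closed cylinders, watertight in the edge-manifold sense. The
egocentric camera starts at a nominal head position, gets U(−0.1, 0.1) m
noise per axis (hand: U(−0.02, 0.02) m — the intervals are stated unitless
at the source; meters is the only reading consistent with a 30–50 cm working
distance), looks at the augmented hand with a fixed world-up (deterministic
fallback when parallel), and is then slid along its optical axis until the
camera–drill distance equals a U(0.30, 0.50) m draw — sliding preserves the
sampled viewing direction while honoring the stated distance distribution.

Rendering is flat-shaded z-buffer rasterization (perspective-correct via
screen-linear 1/z) at 512×512 with focal 420 px — chosen so the 0.28 m drill
at 0.3–0.5 m fills a 256-patch the way the intended imagery does; no path
tracing, textures, or GPU. Labels are {0 background, 1 body+hand, 2 tool},
plus a tool-alone render giving the unoccluded mask. Filters, applied at
full resolution before cropping: reject if hand or tool covers < 100 px, or
if visible-tool ÷ unoccluded-tool pixels < 0.40 (the pixel ratio is the only
visibility notion computable from rendered masks). Patches are 256×256
crops at the tool's 2D bounding-box center jittered by radius U(0, 64) px in
a uniform direction (the source fixes only the 64 px bound), with the image
conceptually rescaled by target/source focal first and the principal point
shifted by the integer crop origin; patches showing < 40 % of the projected
tool vertices are discarded. Every emitted sample stores pose, 21 hand
joints (camera frame), 9 keypoints in 2D/3D and patch intrinsics, and
reprojects its keypoints exactly; generation is bit-reproducible per seed.

## Labeling pipeline

Trimmed ICP keeps the best 80 % of nearest-neighbor pairs per iteration
(trim default 0.8 — standard robust-registration practice covering the
partial tool surfaces) and updates by closed-form weighted rigid fit; the
trimmed MSE is non-increasing and iteration stops at relative change < 1e-8.
Sequence tracking initializes each frame from the previous accepted pose;
a trimmed RMS above τ_div = 10 mm (the order of the drill's surface detail;
configurable) triggers 20 multi-start perturbations (≤ 15°, ≤ 30 mm) of the
last good pose — an automated stand-in for the manual re-initialization and
sighting of an interactive workflow — with still-divergent frames flagged
`discarded` and excluded from label propagation. The joint hand–tool cloud
(tool vertices ∪ segmented hand points, origin-tagged) is what makes
tracking robust to the 60 % tool-surface dropout: tool-only registration
drifts > 5 mm on the same fixtures.

The hand fit minimizes Σᵢ ‖H(vᵢ(θ)) − pᵢ‖² + λ‖θ‖² over a rigid H and the
15 PCA coefficients (shape fixed at the average hand, global rotation folded
into H) by alternating the closed-form rigid fit with damped least squares
on θ; the objective decreases monotonically and λ→∞ recovers the rigid-only
fit with θ→0. The fit is performed in the tool-model frame — the only frame
in which the propagation `H_hand^t = H_tool^t · H_hand^0` is exact, a choice
the formula itself forces even though the source leaves the frame implicit.

## Pose recovery

Keypoints: greedy farthest point sampling over mesh vertices (seeded at the
vertex farthest from the centroid, ties to the lowest index — fixed for
determinism) plus the 3D bounding-box center as the ninth point. Voting:
hypotheses intersect the voting lines of two random mask pixels
(|sin| < 1e-6 pairs resampled); inliers are pixels whose vector agrees with
the direction to the hypothesis above cosine 0.99; 128 hypotheses per
keypoint (both defaults follow the reference voting scheme). The
uncertainty PnP whitens per-keypoint residuals by the Cholesky factor of
Σ_k⁻¹ (Σ_k + 1e-9·I regularization for degenerate single-hypothesis
fields) and runs Levenberg–Marquardt over axis-angle + translation,
initialized by EPnP on the four keypoints with the smallest trace(Σ) —
trace being the simplest rotation-invariant uncertainty scalar. EPnP is
implemented from the control-point formulation with the N = 1 and N = 2
kernel cases and a 3-control-point planar branch; exact-correspondence
inputs are solved exactly by N = 1, and the refinement makes higher beta
cases unnecessary in this role. The translation recovery implements the
standard un-projection consistent with the forward focal-normalized depth
definition (whose printed inverse mixes symbols; the inverse used here is
the algebraic one), assuming the principal point at the image center.

## Numerical and degenerate-input choices

Rigid fits reject < 3 points, collinear configurations (second singular
value < 1e-12 of the first), and all-zero weights, and enforce det(R) = +1.
Projection raises on non-positive depth, naming the offending index.
Rasterization skips faces behind a 1 mm near plane (scenes keep geometry in
front); edge pixels follow an inclusive convention with z-buffer
tie-breaking. Voting resamples parallel pairs up to 100× the hypothesis
budget before failing. The outlier discard keeps poses at exactly the 10³ m
boundary (strictly-greater reading). Cross-validation shuffles units under
the seed and assigns every sample its unit's fold, so grasp- or
recording-level leakage is structurally impossible.

## Problem sizes and what the tests show

The test and acceptance runs use: 1000 rigid-fit oracle sets; 100 ICP trials
at 2000 surface points with 20 % outliers and inits within 10°/2 cm;
50-frame tracking with ≤ 2°/5 mm per-frame motion, 1 mm sensor noise, 60 %
directional tool dropout, ~8000 pre-dropout tool + 4000 hand samples per
frame (the density of a close-range fused two-view depth cloud), and one
injected corrupted frame; a 50-sample generation + voting + PnP loop; and
10⁵ augmentation draws for the σ moment check. Passing these demonstrates
the algorithmic contracts — exactness on clean data, robustness margins on
corrupted data, determinism, filter boundaries — on geometry-faithful
synthetic fixtures; it does not certify accuracy on real sensor data, whose
noise is non-Gaussian and whose hand/tool appearance the flat-shaded
renderer deliberately does not model.

## Known limitations

* The renderer produces label-consistent flat-shaded images, not
  photorealistic RGB; models trained on them would not transfer.
* The stand-in hand is geometrically, not statistically, MANO-like.
* Grasp templates are authored by contact search, not physics-based grasp
  synthesis.
* Point-to-point ICP only; no point-to-plane or color ICP.
* No lens distortion; pinhole cameras with centered principal points
  throughout.
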