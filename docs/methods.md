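# Methods

## Problem and model

The package estimates the 3-D positions of J hand keypoints (joint
centers and fingertips) from a single calibrated depth image, and
derives from estimated fingertip trajectories the kinematic quantities
used to score the finger-tapping test of neurological exams (distance,
velocity and acceleration of the thumb–index gap, and where in the
open/close cycle each frame falls).

A depth image is 2.5-D: every valid pixel corresponds to one surface
point `p` in camera coordinates. The estimator is detection-based: it
predicts, per keypoint `j` and per pixel, a *dense representation* of
the spatial relationship between the pixel and the keypoint, then
aggregates all pixels into one estimate.

The dense representation factors the 3-D offset `p − p_j` (zeroed
outside a support sphere of radius θ around the keypoint) into

- a spatial closeness heatmap `S_j(p) = (θ − ‖p − p_j‖)/θ ∈ [0, 1]`,
- a directional unit-vector map `V_j(p) = (p − p_j)/‖p − p_j‖`.

A third, unsupervised *geometry closeness* heatmap `G_j` lets the
network discover informative pixels that are not spatially close (e.g.
palm pixels that constrain an MCP joint better than the flexing finger
itself does). The two heatmaps are fused channel-wise with a learnable
weight α into the *shifted attention heatmap*
`H_j = α_j S̄_j + (1 − α_j) G_j`, and keypoints are decoded by
attention-weighted voting

    p̄_j = Σ_p ((θ·S̄_j(p) − θ)·V̄_j(p) + p) · H_j(p),

where H has been normalized to sum to one per channel. On ground-truth
inputs the vote of every supported pixel is exactly `p_j`, so decoding
inverts encoding whenever the attention mass stays on the support; this
algebraic identity is the package's master oracle test.

The network is two-stage: a 7×7 stride-2 stem produces C feature maps at
half the crop resolution; each stage runs an SE-Hourglass backbone
(an hourglass encoder-decoder whose residual blocks carry
squeeze-and-excitation channel gates) and a dense extraction head
(SE-residual block + 3×3 conv + BN + ReLU, then three parallel 1×1
branches for V̄ (3J channels, linear), S̄ and G (J channels each,
sigmoid)). A *soft input aggregation* module connects the stages:
`I₂ = conv_a(I₁) + conv_b(F₁) + conv_c(concat(V̄₁, H₁)) + β⊙I₁` with a
learnable channel-wise factor β. Dense supervision attaches to the
second stage; the first stage's heads train through the aggregation
path. Supervision is `L = σ·L_dense + (1−σ)·L_coord` with σ = 0.5,
both terms under the smooth-L1 penalty.

## Coordinate conventions and preprocessing

Pixels are 0-based, `(u, v) = (column, row)`, continuous pixel centers at
integer coordinates. The hand is localized (here: depth-window centroid
over [200, 1500] mm — a deliberately simple stand-in for a detector,
exact enough on single-hand scenes), then a cube of edge `cube_mm`
(default 250 mm) is cropped, resampled to `out_size²` with
nearest-neighbor lookup (bilinear interpolation would invent phantom
depths at silhouette edges) and depth-normalized affinely to [−1, 1]
with background and out-of-cube pixels at +1. The codec runs in
*normalized crop coordinates* — world offsets from the crop center
divided by `cube_mm/2` — on the half-resolution point grid; predictions
are denormalized through the exact inverse transform. θ defaults to
0.64 normalized units (≈80 mm for a 250 mm cube): large enough that
every keypoint keeps support pixels under self-occlusion, small enough
that supports stay local.

## Numerical and design choices

- α is stored as an unconstrained logit and squashed through a sigmoid,
  keeping the fusion a convex combination; each stage has its own α.
- Attention normalization is ReLU followed by masked sum-normalization
  (not softmax) so exact zeros outside the support stay exact zeros;
  the NumPy reference path divides exactly where mass exists (uniform
  fallback otherwise, error when no valid pixel), while the
  differentiable path adds ε = 1e-8 to the denominator for gradient
  stability.
- `V` is undefined at `p = p_j`; it is set to 0 there, which keeps the
  encoding total and the decoding identity exact (the zero offset vote
  degenerates to the pixel's own position, which *is* the keypoint).
- V̄ predictions enter the decoding raw (no per-pixel renormalization to
  unit length).
- Head initialization is prior-matched: most pixels lie outside any
  support sphere, so the offset branch starts at one tenth of the usual
  He scale (near its majority target of zero), the S̄/G logits start at
  −2.5 (low occupancy prior), and the fusion logits start at +2
  (α ≈ 0.88, toward the supervised heatmap — the geometry branch is
  uninformed until trained). β starts at 1 (identity-like aggregation).
- Loss reductions: mean over all map elements for the dense terms, sum
  over keypoints with mean over the three components for the coordinate
  term, all in normalized units — this keeps both terms O(1) so the
  default σ = 0.5 is meaningful.
- Augmentation (in-plane rotation [−180°, 180°], uniform 3-D scale
  [0.9, 1.1], in-plane translation [−10, 10] crop px) is applied
  exactly to the point grid and keypoints and by nearest-neighbor
  resampling to the raster; dense targets are re-encoded from the
  transformed geometry rather than warped, trading speed for exactness.
- Optimization: Adam, lr 1e-3, batch 20; the learning rate is
  multiplied by 0.7 when the epoch training loss has not decreased for
  3 consecutive epochs. Epoch presets: 25 for varied-pose data, 35 for
  cyclic tapping data.
- The network runs on an in-package NumPy reverse-mode autodiff engine
  (im2col convolutions, float32); training is CPU-sized by
  construction.

## The network as an estimator

Training and inference are exposed as a scikit-learn style regressor
(`HandPoseRegressor`) with `fit`/`predict`/`score` and
`get_params`/`set_params`, so the model composes with sklearn model
selection. `predict` returns normalized crop coordinates;
`predict_world` denormalizes through each crop's own geometry.

## Tapping kinematics

Velocity and acceleration are first and second finite differences of
the thumb–index distance per frame, the sampling interval deliberately
ignored. Dis/Vel/Acc errors compare the scalar distance-derivative
series of prediction and truth as mean ± sd of absolute deviations;
constant distance offsets therefore leave the derivative errors at
zero. Phase labeling removes rest (runs where the lightly smoothed
signal spans < 3 mm over a 9-frame window), bounds taps at local minima,
takes each segment's maximum as the apex and maps frames linearly
0→50 (opening) and 50→100 (closing), the apex frame shared between the
phases. The smoothing window (3), rest window (9) and rest threshold
(3 mm) are segmentation choices of this implementation; all are
configurable.

## Synthetic data

The generator renders an articulated toy hand — three thick palm
capsules, a two-segment thumb, a three-segment index finger — to
calibrated depth via analytic ray-capsule intersection with a z-buffer
(128², fx = fy = 200 px, hand at 450–650 mm; depth quantized to 1 mm
when written as 16-bit PNG). Pose mode samples flexions, in-plane
rotation and placement, with J = 6 exact keypoints. Tapping mode drives
a single opening fraction so that the fingertip distance follows
`amplitude·sin(π·phase)` per tap — solved per frame against the forward
kinematics by bracketed root finding, so the peak equals the amplitude
to solver precision — with optional closed-pose rest gaps and Gaussian
jitter of the opening fraction scaled to ≈`noise_sd` mm of distance
noise. The closed pose is calibrated in closed form so the tip centers
coincide, making every distance down to contact reachable and
reproducing the fingertip self-occlusion that makes contact frames the
hard case.

What the toy hand shares with real data: a single articulated surface
with exact 3-D annotations, perspective projection, quantized depth,
fingertip occlusion at contact. What it lacks: real hand shape,
sensor noise and holes, background clutter, inter-subject variation.
Passing tests therefore demonstrate the correctness of the pipeline and
its ability to learn pose from depth, not benchmark-level accuracy on
real sensors.

## Problem sizes

Tests and the acceptance script run a reduced configuration chosen to
exercise every architectural element at desk scale: C = 32 channels,
64² crops, hourglass depth 3, two stages, J = 6. The overfit check
trains 200 Adam steps on 8 frames; the generalization check trains 20
epochs on 300 frames and evaluates on 100 held-out frames against the
crop-center baseline (predicting the crop center for every keypoint).
Tapping metrics use 10-tap trials (2001 frames at 200 frames/tap for
the noise statistics). The full-size configuration (C = 128, 128²
crops, depth 4) is shape-checked and trainable through the same code
path.

## Known limitations

- The hand localizer is a depth-window centroid; cluttered scenes need
  a real detector in its place.
- BatchNorm uses running statistics at inference; very short trainings
  predict best in the regime they trained in.
- The renderer has no sensor noise model; robustness to real depth
  artifacts is untested by construction.
- Dataset adapters for public benchmark layouts are out of scope; the
  manifest format is the single ingestion path.
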