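# handpose

3-D hand pose estimation from single depth images, built for functional
hand assessment: the package estimates the positions of J hand
keypoints (fingertips, joint centers) in millimeters and turns
estimated thumb/index trajectories into the kinematic measures used to
score the finger-tapping test of neurological exams (inter-tip
distance, its per-frame velocity and acceleration, and the phase of
each frame within the open/close cycle). It is aimed at researchers in
movement analysis and rehabilitation who need markerless hand tracking
from a depth camera plus reproducible tapping metrics.

## Method

Each pixel of a calibrated depth crop corresponds to a 3-D surface
point `p`. For every keypoint `p_j` the network predicts a dense
representation of the pixel–keypoint relationship:

- spatial closeness `S_j(p) = (θ − ‖p − p_j‖)/θ` on a support sphere of
  radius θ (0 outside),
- directional unit vectors `V_j(p) = (p − p_j)/‖p − p_j‖`,
- an unsupervised geometry-closeness heatmap `G_j` that can promote
  distant but informative pixels (palm pixels constraining a knuckle).

`S̄` and `G` are fused channel-wise with a learnable weight,
`H_j = α_j S̄_j + (1−α_j) G_j` (the *shifted attention heatmap*), and the
keypoint estimate is the attention-weighted vote of all pixels:

    p̄_j = Σ_p ((θ·S̄_j(p) − θ)·V̄_j(p) + p) · H_j(p)

On ground-truth maps every supported pixel votes exactly `p_j`, so the
decoding inverts the encoding — the identity the test suite pins to
1e-9. The backbone is a two-stage SE-Hourglass (hourglass
encoder-decoder with squeeze-and-excitation residual blocks); the
stages are connected by a *soft input aggregation* module that sums
learned projections of the first stage's input, intermediate and output
features with a channel-scaled copy of the input. Training minimizes
`σ·L_dense + (1−σ)·L_coord` (smooth-L1, σ = 0.5) with Adam (lr 1e-3,
batch 20, plateau decay 0.7 after 3 stalled epochs).

The network runs on a compact NumPy reverse-mode autodiff engine that
ships with the package, so everything trains and evaluates on a CPU.
A synthetic articulated-hand renderer (capsule geometry, analytic
ray-casting, exact keypoint annotations, cyclic tapping motion with a
prescribed fingertip-distance profile) provides fully annotated data so
the entire pipeline is testable without any external dataset.

## Worked example

Train on synthetic poses and evaluate, all through the scikit-learn
style estimator:

```python
import numpy as np
from handpose import HandPoseRegressor, center_baseline_error, make_crop_dataset
from handpose.synthetic import make_hand_skeleton, generate_pose_dataset

frames = generate_pose_dataset(make_hand_skeleton(), 400, seed=20)
dataset = make_crop_dataset(frames, cube_mm=250.0, out_size=64)
train, test = dataset[:300], dataset[300:]

est = HandPoseRegressor(C=32, hourglass_depth=3, out_size=64,
                        epochs=20, batch_size=20, lr=1e-3, seed=0)
est.fit([c for c, _ in train], np.stack([k for _, k in train]))

err = est.mean_error_mm([c for c, _ in test], np.stack([k for _, k in test]))
base = center_baseline_error(test)
print(f"held-out mean error {err:.2f} mm vs center baseline {base:.2f} mm")
```

```
held-out mean error 2.88 mm vs center baseline 37.95 mm
```

The all-keypoint mean error is the mean Euclidean distance between
predicted and true keypoints over all held-out frames; the baseline is
the trivial predictor that places every keypoint at the crop center, so
at this desk-scale configuration the model removes over 90% of the
naive error.

Tapping metrics from fingertip trajectories:

```python
from handpose.synthetic import TapMotionConfig, generate_tap_sequence
from handpose.tapping import label_phases, tap_errors

skel = make_hand_skeleton()
_, truth = generate_tap_sequence(skel, TapMotionConfig(taps=10, amplitude=80.0),
                                 render=False)
labels = label_phases(truth.distances())
print(f"taps detected: {labels.n_taps}, peak opening {truth.distances().max():.1f} mm")
```

```
taps detected: 10, peak opening 80.0 mm
```

The same operations are available from the shell (`handpose synth`,
`handpose train`, `handpose predict`, `handpose evaluate`,
`handpose tap-metrics`); every subcommand takes `--seed` and datasets
travel as 16-bit millimeter depth PNGs plus a line-delimited manifest.

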