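"""Losses, geometric augmentation and the optimization loop.

Supervision is two-fold: a dense loss on the second stage's predicted
closeness heatmap and unit-vector map against their encoded ground
truth, and a coordinate loss on the integrated keypoints, both under the
smooth-L1 (Huber) penalty, combined as
``L = sigma * L_dense + (1 - sigma) * L_coord`` with sigma = 0.5.

Reductions keep the two terms O(1) so the default weighting is
meaningful: the dense terms average over all map elements, the
coordinate term sums over keypoints and averages over the three
components; everything is computed in normalized crop units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .codec import DenseTarget, encode_dense, DEFAULT_THETA
from .crop import CropSample
from .nn import Tensor, smooth_l1_elem, PoseNet, ModelConfig

__all__ = [
    "LossWeights",
    "AugmentParams",
    "TrainConfig",
    "smooth_l1",
    "dense_loss",
    "coord_loss",
    "total_loss",
    "augment_sample",
    "Adam",
    "PlateauScheduler",
    "train_model",
]


@dataclass(frozen=True)
class LossWeights:
    sigma: float = 0.5
    smooth_l1_delta: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError("sigma must lie in [0, 1]")


@dataclass(frozen=True)
class AugmentParams:
    """Geometric augmentation ranges: in-plane rotation (deg), 3-D scale,
    in-plane translation in crop pixels (at the crop's own resolution)."""

    rot_deg: tuple[float, float] = (-180.0, 180.0)
    scale: tuple[float, float] = (0.9, 1.1)
    trans: tuple[float, float] = (-10.0, 10.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.rot_deg, self.scale, self.trans):
            if lo > hi:
                raise ValueError("augmentation ranges must be ordered")


@dataclass
class TrainConfig:
    lr: float = 0.001
    batch: int = 20
    epochs: int = 25
    plateau_factor: float = 0.7
    plateau_patience: int = 3
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.batch < 1:
            raise ValueError("batch must be >= 1")


# ---------------------------------------------------------------------------
# losses


def _huber_np(x: np.ndarray, delta: float) -> np.ndarray:
    ax = np.abs(x)
    return np.where(ax < delta, 0.5 * x * x / delta, ax - 0.5 * delta)


def smooth_l1(residual, delta: float = 1.0):
    """Mean elementwise smooth-L1 penalty; works on arrays or graph Tensors."""
    if isinstance(residual, Tensor):
        return smooth_l1_elem(residual, delta).mean()
    return float(np.mean(_huber_np(np.asarray(residual, dtype=np.float64), delta)))


def dense_loss(S_pred, V_pred, target: DenseTarget, delta: float = 1.0):
    """Smooth-L1 of the closeness heatmap plus the unit-vector map residuals."""
    if isinstance(S_pred, Tensor):
        s_res = S_pred - Tensor(target.S)
        v_res = V_pred - Tensor(target.V)
        return smooth_l1(s_res, delta) + smooth_l1(v_res, delta)
    S_pred = np.asarray(S_pred, dtype=np.float64)
    V_pred = np.asarray(V_pred, dtype=np.float64)
    if S_pred.shape != target.S.shape or V_pred.shape != target.V.shape:
        raise ValueError("prediction shapes do not match the dense target")
    return smooth_l1(S_pred - target.S, delta) + smooth_l1(V_pred - target.V, delta)


def coord_loss(pred, truth, delta: float = 1.0):
    """Sum over keypoints of the smooth-L1 of each 3-vector residual
    (component-mean within a keypoint)."""
    if isinstance(pred, Tensor):
        res = pred - Tensor(np.asarray(truth))
        # mean over components and batch, sum over keypoints
        per = smooth_l1_elem(res, delta)
        if per.ndim == 3:
            return per.mean(axis=(0, 2)).sum()
        return per.mean(axis=-1).sum()
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError("keypoint count mismatch")
    per = _huber_np(pred - truth, delta)
    if per.ndim == 3:
        return float(per.mean(axis=(0, 2)).sum())
    return float(per.mean(axis=-1).sum())


def total_loss(dense, coord, w: LossWeights = LossWeights()):
    """Convex combination ``sigma * L_dense + (1 - sigma) * L_coord``."""
    return w.sigma * dense + (1.0 - w.sigma) * coord


# ---------------------------------------------------------------------------
# augmentation


def _draw(rng: np.random.Generator, params: AugmentParams):
    rot = np.deg2rad(rng.uniform(*params.rot_deg))
    scale = rng.uniform(*params.scale)
    trans = rng.uniform(params.trans[0], params.trans[1], size=2)
    return rot, scale, trans


def augment_sample(
    crop: CropSample,
    keys: np.ndarray,
    params: AugmentParams,
    rng: np.random.Generator,
    theta: float = DEFAULT_THETA,
    draw=None,
) -> tuple[CropSample, np.ndarray, DenseTarget]:
    """Apply one random similarity transform to a crop and its keypoints.

    The same in-plane rotation about the camera axis through the crop
    center, uniform 3-D scale and in-plane translation are applied to
    the point grid and keypoints exactly (point-set level) and to the
    image raster by nearest-neighbor resampling; the dense target is
    re-encoded from the transformed geometry rather than warped.  An
    identity draw returns the inputs unchanged.
    """
    rot, scale, trans = draw if draw is not None else _draw(rng, params)
    keys = np.asarray(keys, dtype=np.float64)
    out = crop.spec.out_size
    dxy = 2.0 * trans / out      # crop px -> normalized units

    if rot == 0.0 and scale == 1.0 and not np.any(trans):
        target = encode_dense(keys, crop.points, crop.valid_mask, theta)
        return crop, keys, target

    c, s = np.cos(rot), np.sin(rot)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def tf(p):
        q = scale * (p @ R.T)
        q[..., 0] += dxy[0]
        q[..., 1] += dxy[1]
        return q

    pts = tf(crop.points.reshape(-1, 3)).reshape(crop.points.shape)
    new_keys = tf(keys)
    mask = crop.valid_mask & np.all(np.abs(pts) <= 1 + 1e-9, axis=-1)
    pts = np.where(mask[..., None], pts, 0.0)

    # Image raster: the matching 2-D similarity about the image center,
    # nearest-neighbor, background kept at +1.  affine_transform works in
    # (row, col) = (y, x) order and pulls input coordinates from output
    # ones: in = Minv @ (out - center - t) + center.
    center = np.full(2, (out - 1) / 2.0)
    minv = np.array([[c, -s], [s, c]]) / scale       # inverse of the (y, x) map
    t_rc = np.array([trans[1], trans[0]])
    offset = center - minv @ (center + t_rc)
    img = ndimage.affine_transform(
        crop.image, minv, offset=offset, order=0, cval=1.0, mode="constant"
    )
    # Depth values scale with the cube; background +1 stays background.
    img = np.where(img >= 1.0, 1.0, np.clip(img * scale, -1.0, 1.0))
    new_crop = CropSample(image=img, spec=crop.spec, points=pts, valid_mask=mask)
    target = encode_dense(new_keys, pts, mask, theta)
    return new_crop, new_keys, target


# ---------------------------------------------------------------------------
# optimization


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params, lr: float = 0.001, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class PlateauScheduler:
    """Multiply the learning rate by ``factor`` when the monitored loss has
    not decreased for ``patience`` consecutive epochs."""

    def __init__(self, optimizer: Adam, factor: float = 0.7, patience: int = 3):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, loss: float) -> float:
        if loss < self.best:
            self.best = loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.opt.lr *= self.factor
                self.bad_epochs = 0
        return self.opt.lr


def train_model(
    dataset: list[tuple[CropSample, np.ndarray]],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig = TrainConfig(),
    loss_weights: LossWeights = LossWeights(),
    augment: AugmentParams | None = None,
    model: PoseNet | None = None,
    callback=None,
) -> tuple[PoseNet, list[dict]]:
    """Adam optimization of the total loss over a crop/keypoint dataset.

    ``dataset`` pairs CropSamples with keypoints in normalized crop
    coordinates.  Returns the trained network and a per-epoch log
    (epoch, lr, dense loss, coord loss, total).  Dense supervision
    attaches to the last stage only; earlier heads train through the
    aggregation path.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(train_cfg.seed)
    net = model or PoseNet(model_cfg, seed=train_cfg.seed)
    opt = Adam(net.parameters(), lr=train_cfg.lr)
    sched = PlateauScheduler(opt, train_cfg.plateau_factor, train_cfg.plateau_patience)
    theta = model_cfg.theta
    log: list[dict] = []
    n = len(dataset)
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        ep_dense = ep_coord = 0.0
        n_batches = 0
        for start in range(0, n, train_cfg.batch):
            idx = order[start : start + train_cfg.batch]
            imgs, pts, masks, keys_b, targets = [], [], [], [], []
            for i in idx:
                crop, keys = dataset[i]
                if augment is not None:
                    crop, keys, tgt = augment_sample(crop, keys, augment, rng, theta)
                else:
                    tgt = encode_dense(keys, crop.points, crop.valid_mask, theta)
                imgs.append(crop.image)
                pts.append(crop.points.reshape(-1, 3))
                masks.append(crop.valid_mask.reshape(-1))
                keys_b.append(keys)
                targets.append(tgt)
            S_t = np.stack([t.S for t in targets])
            V_t = np.stack([t.V for t in targets])           # (B, J, P, 3)
            out = net(np.stack(imgs), np.stack(pts), np.stack(masks))
            last = out.stages[-1]
            b, j, p = S_t.shape
            s_pred = last.S.reshape(b, j, p)
            v_pred = last.V.reshape(b, j, 3, p)
            v_tgt = Tensor(np.transpose(V_t, (0, 1, 3, 2)).astype(np.float32))
            l_dense = smooth_l1(s_pred - Tensor(S_t.astype(np.float32)), loss_weights.smooth_l1_delta) \
                + smooth_l1(v_pred - v_tgt, loss_weights.smooth_l1_delta)
            l_coord = coord_loss(out.keypoints, np.stack(keys_b).astype(np.float32),
                                 loss_weights.smooth_l1_delta)
            loss = total_loss(l_dense, l_coord, loss_weights)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: dense={l_dense.data}, coord={l_coord.data}"
                )
            net.zero_grad()
            loss.backward()
            opt.step()
            ep_dense += float(l_dense.data)
            ep_coord += float(l_coord.data)
            n_batches += 1
        ep_dense /= n_batches
        ep_coord /= n_batches
        ep_total = total_loss(ep_dense, ep_coord, loss_weights)
        lr_now = sched.step(ep_total)
        entry = {"epoch": epoch, "lr": lr_now, "dense": ep_dense, "coord": ep_coord, "total": ep_total}
        log.append(entry)
        if callback is not None:
            callback(net, entry)
    return net, log
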