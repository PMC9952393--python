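"""Scikit-learn style estimator over the dense-regression pose network.

``HandPoseRegressor.fit`` consumes normalized hand crops (CropSample)
and keypoints in normalized crop coordinates; ``predict`` returns
keypoints in the same coordinates and ``predict_world`` denormalizes
them to world millimeters through each crop's own geometry.  The class
composes with sklearn model selection through ``get_params`` /
``set_params``; fitted state lives in trailing-underscore attributes.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .camera import DepthFrame
from .crop import CropSample, CropSpec, crop_and_normalize, normalize_keypoints, uncrop_keypoints
from .nn import ModelConfig, PoseNet
from .training import AugmentParams, LossWeights, TrainConfig, train_model

__all__ = ["HandPoseRegressor", "make_crop_dataset", "center_baseline_error"]


def make_crop_dataset(
    frames,
    cube_mm: float = 250.0,
    out_size: int = 64,
    centers: np.ndarray | None = None,
) -> list[tuple[CropSample, np.ndarray]]:
    """Crop synthetic (or real) annotated frames into training pairs.

    ``frames`` is a sequence of objects with ``frame`` (DepthFrame) and
    ``keys`` ((J, 3) world mm) attributes.  Crops are centered on the
    keypoint centroid unless explicit ``centers`` are given.
    """
    out = []
    for i, item in enumerate(frames):
        center = centers[i] if centers is not None else item.keys.mean(axis=0)
        spec = CropSpec(center=tuple(center), cube_mm=cube_mm, out_size=out_size)
        crop = crop_and_normalize(item.frame, spec)
        out.append((crop, normalize_keypoints(item.keys, spec)))
    return out


def center_baseline_error(dataset: list[tuple[CropSample, np.ndarray]]) -> float:
    """Mean error (mm) of the trivial predictor that places every keypoint
    at the crop center — the floor any learned model must beat."""
    errs = []
    for crop, keys in dataset:
        errs.append(np.linalg.norm(keys, axis=-1) * crop.spec.half_extent)
    return float(np.concatenate(errs).mean())


class HandPoseRegressor(RegressorMixin, BaseEstimator):
    """Two-stage dense-voting 3-D pose regressor on depth crops.

    Parameters mirror the architecture and schedule defaults: Adam at
    lr 1e-3, batch 20, plateau decay 0.7 with patience 3, loss weighting
    sigma = 0.5, codec radius theta in normalized crop units.
    """

    def __init__(
        self,
        C: int = 128,
        stages: int = 2,
        hourglass_depth: int = 4,
        se_ratio: int = 16,
        theta: float = 0.64,
        out_size: int = 128,
        lr: float = 1e-3,
        batch_size: int = 20,
        epochs: int = 25,
        plateau_factor: float = 0.7,
        plateau_patience: int = 3,
        sigma: float = 0.5,
        delta: float = 1.0,
        augment: bool = False,
        seed: int = 0,
    ):
        self.C = C
        self.stages = stages
        self.hourglass_depth = hourglass_depth
        self.se_ratio = se_ratio
        self.theta = theta
        self.out_size = out_size
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.plateau_factor = plateau_factor
        self.plateau_patience = plateau_patience
        self.sigma = sigma
        self.delta = delta
        self.augment = augment
        self.seed = seed

    # -- sklearn API ----------------------------------------------------------

    def fit(self, X: list[CropSample], y: np.ndarray) -> "HandPoseRegressor":
        y = np.asarray(y, dtype=np.float64)
        if y.ndim != 3 or y.shape[-1] != 3 or len(X) != y.shape[0]:
            raise ValueError("y must be (n_samples, J, 3) matching X")
        for crop in X:
            if crop.image.shape != (self.out_size, self.out_size):
                raise ValueError("crop resolution does not match out_size")
        self.config_ = ModelConfig(
            J=y.shape[1], C=self.C, stages=self.stages,
            hourglass_depth=self.hourglass_depth, se_ratio=self.se_ratio,
            theta=self.theta, out_size=self.out_size,
        )
        train_cfg = TrainConfig(
            lr=self.lr, batch=self.batch_size, epochs=self.epochs,
            plateau_factor=self.plateau_factor, plateau_patience=self.plateau_patience,
            seed=self.seed,
        )
        weights = LossWeights(sigma=self.sigma, smooth_l1_delta=self.delta)
        aug = AugmentParams() if self.augment is True else (self.augment or None)
        dataset = list(zip(X, y))
        self.model_, self.history_ = train_model(
            dataset, self.config_, train_cfg, weights, augment=aug
        )
        self.n_iter_ = len(self.history_)
        return self

    def predict(self, X: list[CropSample]) -> np.ndarray:
        """Keypoints in normalized crop coordinates, (n, J, 3)."""
        model: PoseNet = self.model_
        model.eval()
        try:
            preds = []
            for start in range(0, len(X), self.batch_size):
                chunk = X[start : start + self.batch_size]
                imgs = np.stack([c.image for c in chunk])
                pts = np.stack([c.points.reshape(-1, 3) for c in chunk])
                masks = np.stack([c.valid_mask.reshape(-1) for c in chunk])
                out = model(imgs, pts, masks)
                preds.append(out.keypoints.data.astype(np.float64))
        finally:
            model.train()
        return np.concatenate(preds, axis=0)

    def predict_world(self, X: list[CropSample]) -> np.ndarray:
        """Keypoints in world millimeters via each crop's inverse transform."""
        coords = self.predict(X)
        return np.stack([uncrop_keypoints(c, crop.spec) for c, crop in zip(coords, X)])

    def score(self, X: list[CropSample], y: np.ndarray) -> float:
        """Negative mean Euclidean keypoint error in normalized units."""
        pred = self.predict(X)
        return -float(np.linalg.norm(pred - np.asarray(y), axis=-1).mean())

    def mean_error_mm(self, X: list[CropSample], y: np.ndarray) -> float:
        """All-keypoint mean error in millimeters on crop-coordinate targets."""
        pred = self.predict(X)
        errs = [
            np.linalg.norm((p - t), axis=-1) * crop.spec.half_extent
            for p, t, crop in zip(pred, np.asarray(y), X)
        ]
        return float(np.concatenate(errs).mean())
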