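"""The two-stage dense-regression pose network.

Pipeline: a pre-processing stem halves the crop resolution into C
feature maps; each stage runs an SE-Hourglass backbone and a dense
extraction head predicting, per keypoint channel, a spatial-closeness
heatmap S, a directional unit-vector map V and an unsupervised geometry
heatmap G, fused into the shifted attention heatmap
``H = alpha * S + (1 - alpha) * G`` with a learnable per-channel,
per-stage weight.  A soft input aggregation module connects the stages
by summing projections of the first stage's input, intermediate and
output levels with a channel-scaled copy of the input.  The final
keypoints are the attention-weighted per-pixel votes of the last stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .tensor import Tensor, concat
from .layers import Module, Conv2d, BatchNorm2d, SEResidual, Hourglass

__all__ = [
    "ModelConfig",
    "StageOutput",
    "NetworkOutputs",
    "PoseNet",
    "save_checkpoint",
    "load_checkpoint",
]

_ATTN_EPS = 1e-8


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    ``theta`` is the codec support radius in normalized crop units;
    ``out_size`` is the crop resolution fed to the stem (the dense maps
    live at half that resolution).
    """

    J: int
    C: int = 128
    stages: int = 2
    hourglass_depth: int = 4
    se_ratio: int = 16
    theta: float = 0.64
    out_size: int = 128

    def __post_init__(self) -> None:
        if min(self.J, self.C, self.stages) < 1:
            raise ValueError("J, C and stages must be >= 1")
        if self.out_size % (2 ** (self.hourglass_depth + 1)):
            raise ValueError(
                f"out_size {self.out_size} must be divisible by 2^(hourglass_depth+1)"
            )
        if self.theta <= 0:
            raise ValueError("theta must be positive")

    @property
    def map_size(self) -> int:
        return self.out_size // 2


@dataclass
class StageOutput:
    """Everything one stage predicts, kept on the autodiff tape."""

    Q: Tensor            # backbone output features (N, C, Hd, Wd)
    F: Tensor            # head intermediate features (N, C, Hd, Wd)
    S: Tensor            # (N, J, Hd, Wd) in (0, 1)
    V: Tensor            # (N, 3J, Hd, Wd)
    G: Tensor            # (N, J, Hd, Wd) in (0, 1)
    H: Tensor            # fused shifted-attention heatmap (N, J, Hd, Wd)
    alpha: Tensor        # effective fusion weights, (J,)


@dataclass
class NetworkOutputs:
    stages: list[StageOutput]
    keypoints: Tensor    # (N, J, 3) in normalized crop coordinates


class Stem(Module):
    """7x7 stride-2 convolution + BN + ReLU + one SE-residual block."""

    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        self.conv = Conv2d(1, cfg.C, 7, stride=2, pad=3, rng=rng)
        self.bn = BatchNorm2d(cfg.C)
        self.res = SEResidual(cfg.C, cfg.se_ratio, rng)
        self.out_size = cfg.out_size

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[2] != self.out_size or x.shape[3] != self.out_size:
            raise ValueError(f"expected {self.out_size}x{self.out_size} input, got {x.shape[2:]}")
        return self.res(self.bn(self.conv(x)).relu())


class DenseExtraction(Module):
    """Feature head plus three parallel 1x1 branches (V, S, G) and the fusion."""

    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        self.res = SEResidual(cfg.C, cfg.se_ratio, rng)
        self.conv = Conv2d(cfg.C, cfg.C, 3, pad=1, rng=rng)
        self.bn = BatchNorm2d(cfg.C)
        self.conv_v = Conv2d(cfg.C, 3 * cfg.J, 1, rng=rng)
        self.conv_s = Conv2d(cfg.C, cfg.J, 1, rng=rng)
        self.conv_g = Conv2d(cfg.C, cfg.J, 1, rng=rng)
        # Prior-matched head initialization: most pixels lie outside a
        # keypoint's support sphere, so the offset branch starts near its
        # majority target of zero and the heatmap logits near the low
        # occupancy prior; the fusion logits start toward the supervised
        # closeness heatmap (the geometry branch is uninformed early on).
        self.conv_v.weight.data *= 0.1
        self.conv_s.bias.data[:] = -2.5
        self.conv_g.bias.data[:] = -2.5
        self.register_param("alpha_raw", np.full(cfg.J, 2.0, dtype=np.float32))

    def forward(self, q: Tensor) -> tuple[Tensor, Tensor, Tensor, Tensor, Tensor, Tensor]:
        f = self.bn(self.conv(self.res(q))).relu()
        v = self.conv_v(f)
        s = self.conv_s(f).sigmoid()
        g = self.conv_g(f).sigmoid()
        alpha = self.alpha_raw.sigmoid()
        j = alpha.shape[0]
        a = alpha.reshape(1, j, 1, 1)
        h = a * s + (1.0 - a) * g
        return f, s, v, g, h, alpha


class SoftAggregation(Module):
    """Inter-stage connector: I2 = conv_a(I1) + conv_b(F1) + conv_c([V1, H1]) + beta * I1."""

    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        self.conv_a = Conv2d(cfg.C, cfg.C, 3, pad=1, rng=rng)
        self.conv_b = Conv2d(cfg.C, cfg.C, 3, pad=1, rng=rng)
        self.conv_c = Conv2d(4 * cfg.J, cfg.C, 3, pad=1, rng=rng)
        # Channel-wise input scale; identity-like start.
        self.register_param("beta", np.ones(cfg.C, dtype=np.float32))

    def forward(self, i1: Tensor, f1: Tensor, v1: Tensor, h1: Tensor) -> Tensor:
        c = self.beta.shape[0]
        scaled = i1 * self.beta.reshape(1, c, 1, 1)
        return self.conv_a(i1) + self.conv_b(f1) + self.conv_c(concat([v1, h1], axis=1)) + scaled


def normalize_attention_graph(h: Tensor, valid_mask: np.ndarray) -> Tensor:
    """ReLU + masked sum-normalization of attention, on the autodiff tape.

    ``h`` is (N, J, P); ``valid_mask`` (N, P).  Channels sum to one over
    valid pixels (up to the stabilizing epsilon).
    """
    mask = Tensor(valid_mask.astype(np.float32)[:, None, :])
    w = h.relu() * mask
    return w / (w.sum(axis=2, keepdims=True) + _ATTN_EPS)


def integrate_graph(
    s: Tensor, v: Tensor, h_norm: Tensor, points: np.ndarray, theta: float
) -> Tensor:
    """Differentiable per-pixel voting (the decoding sum) for a batch.

    ``s`` (N, J, P), ``v`` (N, 3J, P) or (N, J, 3, P), ``h_norm``
    (N, J, P) normalized, ``points`` (N, P, 3).  Returns (N, J, 3).
    """
    n, j, p = s.shape
    v = v.reshape(n, j, 3, p)
    pts = Tensor(np.transpose(points, (0, 2, 1))[:, None, :, :])    # (N, 1, 3, P)
    offsets = (s * theta - theta).reshape(n, j, 1, p)
    votes = offsets * v + pts
    return (votes * h_norm.reshape(n, j, 1, p)).sum(axis=3)


class PoseNet(Module):
    """The full two-stage network; ``stages=1`` drops the refinement stage."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.stem = Stem(cfg, rng)
        self.hg1 = Hourglass(cfg.C, cfg.hourglass_depth, cfg.se_ratio, rng)
        self.head1 = DenseExtraction(cfg, rng)
        if cfg.stages >= 2:
            self.agg = SoftAggregation(cfg, rng)
            self.hg2 = Hourglass(cfg.C, cfg.hourglass_depth, cfg.se_ratio, rng)
            self.head2 = DenseExtraction(cfg, rng)

    def forward(self, images: np.ndarray, points: np.ndarray, valid_mask: np.ndarray) -> NetworkOutputs:
        """Run the pipeline on a batch.

        ``images`` (N, out, out) normalized crops, ``points`` (N, P, 3)
        half-resolution point grids in normalized crop coordinates,
        ``valid_mask`` (N, P).
        """
        cfg = self.cfg
        x = Tensor(np.asarray(images, dtype=np.float32)[:, None, :, :])
        i1 = self.stem(x)
        q1 = self.hg1(i1)
        f1, s1, v1, g1, h1, a1 = self.head1(q1)
        stages = [StageOutput(Q=q1, F=f1, S=s1, V=v1, G=g1, H=h1, alpha=a1)]
        if cfg.stages >= 2:
            i2 = self.agg(i1, f1, v1, h1)
            q2 = self.hg2(i2)
            f2, s2, v2, g2, h2, a2 = self.head2(q2)
            stages.append(StageOutput(Q=q2, F=f2, S=s2, V=v2, G=g2, H=h2, alpha=a2))
        last = stages[-1]
        n = x.shape[0]
        p = cfg.map_size * cfg.map_size
        s_flat = last.S.reshape(n, cfg.J, p)
        v_flat = last.V.reshape(n, 3 * cfg.J, p)
        mask = np.asarray(valid_mask, dtype=bool).reshape(n, p)
        h_norm = normalize_attention_graph(last.H.reshape(n, cfg.J, p), mask)
        keypoints = integrate_graph(s_flat, v_flat, h_norm, np.asarray(points).reshape(n, p, 3), cfg.theta)
        return NetworkOutputs(stages=stages, keypoints=keypoints)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def save_checkpoint(path, model: PoseNet) -> None:
    """Write parameters, buffers and the config to an npz; bit-exact round trip."""
    state = model.named_state()
    np.savez(path, __config__=np.frombuffer(
        json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8
    ), **state)


def load_checkpoint(path) -> PoseNet:
    with np.load(path) as data:
        cfg = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
        model = PoseNet(cfg)
        model.load_state({k: data[k] for k in data.files if k != "__config__"})
    return model
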