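"""Dense 3-D offset representation of keypoints and its exact inverse.

A keypoint ``p_j`` is encoded, over a cloud of surface points ``p``, as

* a spatial closeness heatmap  ``S_j(p) = (theta - ||p - p_j||) / theta``
* a directional unit-vector map ``V_j(p) = (p - p_j) / ||p - p_j||``

both restricted to the support ``||p - p_j|| <= theta`` (a sphere of
radius theta around the keypoint) and zero elsewhere.  Together they
factor the 3-D offset map ``O_j(p) = p - p_j`` into magnitude and
direction.  The decoding direction weights per-point keypoint votes with
an attention heatmap ``H``:

    p_bar_j = sum_p ((theta * S_j(p) - theta) * V_j(p) + p) * H_j(p)

Because ``(theta*S - theta) * V = -(p - p_j)`` on the support, every
supported point votes exactly ``p_j``, so integration inverts encoding
whenever the attention mass stays on the support — the identity this
module's tests pin down.

All maps are stored flattened over points: ``S`` is (J, P), ``V`` is
(J, P, 3).  The codec is unit-agnostic; the pipeline runs it in
normalized crop coordinates with theta expressed in the same units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DenseTarget",
    "encode_dense",
    "fuse_heatmaps",
    "normalize_attention",
    "integrate_keypoints",
    "DEFAULT_THETA",
]

# Support radius in normalized crop units (~80 mm for a 250 mm cube).
DEFAULT_THETA = 0.64



@dataclass
class DenseTarget:
    """Ground-truth closeness heatmap, unit-vector map and their support."""

    S: np.ndarray          # (J, P) in [0, 1]
    V: np.ndarray          # (J, P, 3), unit vectors or zero
    support: np.ndarray    # (J, P) bool: within theta and valid
    theta: float


def _as_points(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=np.float64)
    if points.shape[-1] != 3:
        raise ValueError("points must have a trailing axis of length 3")
    return points.reshape(-1, 3)


def encode_dense(
    keys: np.ndarray,
    points: np.ndarray,
    valid_mask: np.ndarray | None = None,
    theta: float = DEFAULT_THETA,
) -> DenseTarget:
    """Encode J keypoints against a point cloud into (S, V) maps.

    ``keys`` is (J, 3) and ``points`` any array with trailing axis 3 (it
    is flattened to (P, 3)).  Points where ``valid_mask`` is False never
    enter the support.  A point coincident with its keypoint gets S = 1
    and V = 0 (the direction is undefined there; the zero vector keeps
    the decoding identity exact because its offset vote vanishes).
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    keys = np.asarray(keys, dtype=np.float64)
    if keys.ndim != 2 or keys.shape[1] != 3:
        raise ValueError("keys must be (J, 3)")
    pts = _as_points(points)
    P = pts.shape[0]
    if valid_mask is None:
        valid = np.ones(P, dtype=bool)
    else:
        valid = np.asarray(valid_mask, dtype=bool).reshape(-1)
        if valid.shape[0] != P:
            raise ValueError("valid_mask does not match points")

    diff = pts[None, :, :] - keys[:, None, :]          # (J, P, 3)
    dist = np.linalg.norm(diff, axis=-1)               # (J, P)
    support = (dist <= theta) & valid[None, :]
    S = np.where(support, (theta - dist) / theta, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        V = np.where((support & (dist > 0))[..., None], diff / np.where(dist > 0, dist, 1.0)[..., None], 0.0)
    return DenseTarget(S=S, V=V, support=support, theta=float(theta))


def fuse_heatmaps(S_pred: np.ndarray, G: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Channel-wise convex fusion ``H_j = alpha_j * S_j + (1 - alpha_j) * G_j``.

    ``alpha`` holds one effective weight in [0, 1] per keypoint channel;
    the result (the shifted attention heatmap) lies pointwise between the
    predicted closeness heatmap and the learned geometry heatmap.
    """
    S_pred = np.asarray(S_pred, dtype=np.float64)
    G = np.asarray(G, dtype=np.float64)
    if S_pred.shape != G.shape:
        raise ValueError(f"shape mismatch: {S_pred.shape} vs {G.shape}")
    alpha = np.asarray(alpha, dtype=np.float64).reshape(-1)
    if alpha.shape[0] != S_pred.shape[0]:
        raise ValueError("alpha must have one weight per keypoint channel")
    a = alpha.reshape(-1, *([1] * (S_pred.ndim - 1)))
    return a * S_pred + (1.0 - a) * G


def normalize_attention(H: np.ndarray, valid_mask: np.ndarray | None = None) -> np.ndarray:
    """Turn raw attention into per-channel weights that sum to one.

    Negative values are clamped to zero and invalid points zeroed before
    sum-normalization (chosen over softmax so exact zeros outside the
    support stay exact zeros).  A channel with no positive mass falls
    back to uniform weights over the valid points.
    """
    H = np.asarray(H, dtype=np.float64)
    flat = H.reshape(H.shape[0], -1)
    P = flat.shape[1]
    if valid_mask is None:
        valid = np.ones(P, dtype=bool)
    else:
        valid = np.asarray(valid_mask, dtype=bool).reshape(-1)
        if valid.shape[0] != P:
            raise ValueError("valid_mask does not match heatmap")
    if not np.any(valid):
        raise ValueError("no valid points to normalize attention over")
    W = np.clip(flat, 0.0, None) * valid[None, :]
    totals = W.sum(axis=1, keepdims=True)
    uniform = valid.astype(np.float64) / valid.sum()
    # Exact division where mass exists keeps the decoding identity exact;
    # channels with no positive mass fall back to uniform weights.
    W = np.where(totals > 0, W / np.where(totals > 0, totals, 1.0), uniform[None, :])
    return W.reshape(H.shape)


def integrate_keypoints(
    S_pred: np.ndarray,
    V_pred: np.ndarray,
    H_norm: np.ndarray,
    points: np.ndarray,
    theta: float = DEFAULT_THETA,
) -> np.ndarray:
    """Attention-weighted per-point voting: maps (S, V, H) back to J keypoints.

    Each point casts the vote ``(theta*S - theta) * V + p`` — its own
    position corrected by the predicted offset — and votes are averaged
    under the normalized attention ``H``.
    """
    S_pred = np.asarray(S_pred, dtype=np.float64)
    V_pred = np.asarray(V_pred, dtype=np.float64)
    H_norm = np.asarray(H_norm, dtype=np.float64)
    pts = _as_points(points)
    J = S_pred.shape[0]
    S = S_pred.reshape(J, -1)
    V = V_pred.reshape(J, -1, 3)
    H = H_norm.reshape(J, -1)
    P = pts.shape[0]
    if S.shape[1] != P or V.shape[1] != P or H.shape[1] != P:
        raise ValueError("S, V, H and points must agree on the number of points")
    votes = (theta * S - theta)[..., None] * V + pts[None, :, :]   # (J, P, 3)
    return np.einsum("jpk,jp->jk", votes, H)
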