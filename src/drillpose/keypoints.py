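"""Keypoint definition, vector-field encoding, and RANSAC hypothesis voting.

The object pose is represented indirectly through K = 8+1 keypoints: eight
surface points chosen by farthest point sampling over the mesh vertices plus
the 3D bounding-box center. On the image side each keypoint is encoded as a
dense field of unit vectors on the object mask pointing toward it; keypoints
are decoded by intersecting random vector pairs (hypotheses) and aggregating
them into a mean and covariance weighted by inlier counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ToolMesh

__all__ = ["KeypointSet3D", "VectorField", "KeypointDistribution",
           "define_keypoints", "encode_vector_field", "ransac_vote"]

K_SURFACE = 8
K_TOTAL = K_SURFACE + 1


@dataclass(frozen=True)
class KeypointSet3D:
    """K = 8+1 tool-frame keypoints: 8 surface points + bounding-box center
    (last)."""
    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, float).reshape(-1, 3)
        if len(pts) != K_TOTAL:
            raise ValueError(f"expected {K_TOTAL} keypoints, got {len(pts)}")
        object.__setattr__(self, "points", pts)


@dataclass
class VectorField:
    """Per-keypoint H x W x 2 unit-vector maps on the object mask."""
    vectors: np.ndarray       # (K, H, W, 2)
    mask: np.ndarray          # (H, W) bool

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        self.vectors = np.asarray(self.vectors, float)
        if self.vectors.shape[1:3] != self.mask.shape:
            raise ValueError("vector field / mask shape mismatch")


@dataclass(frozen=True)
class KeypointDistribution:
    """Voted keypoint estimate: inlier-weighted hypothesis mean (pixels) and
    covariance (pixels^2)."""
    mean: np.ndarray
    covariance: np.ndarray
    hypothesis_count: int
    total_inlier_weight: float

    def __post_init__(self):
        mu = np.asarray(self.mean, float).reshape(2)
        S = np.asarray(self.covariance, float).reshape(2, 2)
        if np.abs(S - S.T).max() > 1e-9:
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(S).min() < -1e-9:
            raise ValueError("covariance must be PSD")
        object.__setattr__(self, "mean", mu)
        object.__setattr__(self, "covariance", S)


def define_keypoints(mesh: ToolMesh, k_surface: int = K_SURFACE) -> KeypointSet3D:
    """Greedy farthest point sampling over mesh vertices plus the
    bounding-box center.

    Deterministic: seeded at the vertex farthest from the centroid, ties
    broken by lowest vertex index.
    """
    verts = np.asarray(mesh.vertices, float)
    if len(verts) < k_surface:
        raise ValueError(f"mesh has {len(verts)} vertices, need {k_surface}")
    centroid = verts.mean(axis=0)
    d0 = np.linalg.norm(verts - centroid, axis=1)
    chosen = [int(np.argmax(d0))]                 # argmax takes lowest index on ties
    min_d = np.linalg.norm(verts - verts[chosen[0]], axis=1)
    while len(chosen) < k_surface:
        nxt = int(np.argmax(min_d))
        chosen.append(nxt)
        min_d = np.minimum(min_d, np.linalg.norm(verts - verts[nxt], axis=1))
    bbox_center = 0.5 * (verts.min(axis=0) + verts.max(axis=0))
    return KeypointSet3D(np.vstack([verts[chosen], bbox_center]))


def encode_vector_field(keypoints_2d: np.ndarray, mask: np.ndarray) -> VectorField:
    """Ground-truth encoding: at every mask pixel p, the unit vector
    (k - p) / ||k - p|| toward each keypoint k (zero at p = k)."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    kps = np.asarray(keypoints_2d, float).reshape(-1, 2)
    H, W = mask.shape
    xs, ys = np.meshgrid(np.arange(W), np.arange(H))
    pix = np.stack([xs, ys], axis=-1).astype(float)         # (H, W, 2)
    vectors = np.zeros((len(kps), H, W, 2))
    for k, kp in enumerate(kps):
        diff = kp - pix
        norm = np.linalg.norm(diff, axis=-1)
        nz = (norm > 0) & mask
        vectors[k][nz] = diff[nz] / norm[nz][:, None]
    return VectorField(vectors, mask)


def _intersect_lines(p1, v1, p2, v2):
    """Intersection of {p1 + s v1} and {p2 + t v2}; None when near-parallel."""
    cross = v1[0] * v2[1] - v1[1] * v2[0]
    n1 = np.hypot(*v1)
    n2 = np.hypot(*v2)
    if n1 == 0 or n2 == 0 or abs(cross / (n1 * n2)) < 1e-6:
        return None
    dp = p2 - p1
    s = (dp[0] * v2[1] - dp[1] * v2[0]) / cross
    return p1 + s * v1


def ransac_vote(field: VectorField, n_hypotheses: int = 128,
                inlier_cos_threshold: float = 0.99,
                rng: np.random.Generator | int = 0) -> list:
    """Decode every keypoint of a vector field by RANSAC hypothesis voting.

    Each hypothesis intersects the voting lines of two random mask pixels
    (near-parallel pairs are resampled); a mask pixel is an inlier when the
    cosine between its stored vector and the direction to the hypothesis
    exceeds the threshold. Returns one :class:`KeypointDistribution` per
    keypoint with inlier-weighted mean and covariance of the hypotheses.
    """
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    ys, xs = np.nonzero(field.mask)
    n_pix = len(xs)
    if n_pix < 2:
        raise ValueError("mask must contain at least 2 pixels")
    if n_hypotheses < 1:
        raise ValueError("n_hypotheses must be >= 1")
    pix = np.column_stack([xs, ys]).astype(float)

    out = []
    for k in range(field.vectors.shape[0]):
        vecs = field.vectors[k][ys, xs]            # (n_pix, 2)
        hyps = []
        attempts = 0
        max_attempts = 100 * n_hypotheses
        while len(hyps) < n_hypotheses:
            if attempts >= max_attempts:
                if not hyps:
                    raise ValueError("all sampled vector pairs are parallel")
                break
            attempts += 1
            i, j = rng.integers(n_pix), rng.integers(n_pix)
            if i == j:
                continue
            h = _intersect_lines(pix[i], vecs[i], pix[j], vecs[j])
            if h is None:
                continue
            hyps.append(h)
        hyps = np.asarray(hyps)

        # inlier weight of each hypothesis = number of agreeing mask pixels
        diff = hyps[:, None, :] - pix[None, :, :]            # (h, n_pix, 2)
        dn = np.linalg.norm(diff, axis=-1)
        dn[dn == 0] = 1.0
        cosang = np.einsum("hpi,pi->hp", diff / dn[..., None], vecs)
        weights = (cosang > inlier_cos_threshold).sum(axis=1).astype(float)
        if weights.sum() == 0:
            weights = np.ones(len(hyps))
        w = weights / weights.sum()
        mu = w @ hyps
        centered = hyps - mu
        cov = (centered * w[:, None]).T @ centered
        cov = 0.5 * (cov + cov.T)
        out.append(KeypointDistribution(mu, cov, len(hyps),
                                        float(weights.sum())))
    return out
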