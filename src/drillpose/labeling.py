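"""Semi-automatic ground-truth labeling of multi-view point-cloud recordings.

The pipeline mirrors how ground truth is produced for real recordings of a
hand-held tool: per-frame clouds from stereo-calibrated views are fused into
the main-camera frame; the tool vertices, registered to frame 0, are merged
with manually segmented hand points into a joint hand-tool model; that joint
model is tracked through the sequence with trimmed ICP initialized from the
previous frame (with automated multi-start re-initialization when the
residual diverges); the hand pose is fitted once from 16 labeled vertex
correspondences at the average hand shape; and per-frame hand labels follow
rigidly from the tool track via  H_hand^t = H_tool^t  H_hand^0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .geometry import PointCloud, RigidTransform, fit_rigid
from .handmodel import (HandModelAssets, HandPose, synthesize_hand, N_PCA)

__all__ = ["Recording", "TrackedSequence", "HandCorrespondences",
           "fuse_views", "trimmed_icp", "build_joint_model",
           "track_tool_sequence", "fit_hand_pose", "propagate_hand_labels",
           "TrackingParams"]

N_CORRESPONDENCES = 16


@dataclass
class Recording:
    """An ordered sequence of fused point clouds in the main-camera frame."""
    frames: list
    extrinsics: list = field(default_factory=list)
    native_fps: float = 30.0

    def __post_init__(self):
        if not self.frames:
            raise ValueError("recording must contain at least one frame")


@dataclass
class TrackedSequence:
    """Per-frame tool poses with trimmed-RMS residuals and a status flag in
    {ok, reinitialized, discarded}."""
    tool_poses: list
    residuals: np.ndarray
    status: list

    def __post_init__(self):
        if not (len(self.tool_poses) == len(self.residuals) == len(self.status)):
            raise ValueError("per-frame lists must have equal length")


@dataclass(frozen=True)
class HandCorrespondences:
    """Exactly 16 pairs of (hand-model vertex index, 3D point), the points
    expressed in the tool-model frame."""
    vertex_indices: np.ndarray
    points: np.ndarray

    def __post_init__(self):
        vi = np.asarray(self.vertex_indices, int).reshape(-1)
        pts = np.asarray(self.points, float).reshape(-1, 3)
        if len(vi) != N_CORRESPONDENCES or len(pts) != N_CORRESPONDENCES:
            raise ValueError(f"need exactly {N_CORRESPONDENCES} correspondences")
        object.__setattr__(self, "vertex_indices", vi)
        object.__setattr__(self, "points", pts)

    def validate_for(self, assets: HandModelAssets) -> None:
        if self.vertex_indices.min() < 0 or \
                self.vertex_indices.max() >= assets.n_vertices:
            raise ValueError("correspondence vertex index out of range")


def fuse_views(clouds: list, extrinsics: list) -> PointCloud:
    """Transform per-view clouds into the main-camera frame and concatenate,
    preserving colors where every view carries them."""
    if len(clouds) != len(extrinsics):
        raise ValueError(f"{len(clouds)} clouds but {len(extrinsics)} extrinsics")
    pts = [T.apply(c.points) for c, T in zip(clouds, extrinsics)]
    colors = None
    if all(c.colors is not None for c in clouds):
        colors = np.vstack([c.colors for c in clouds])
    return PointCloud(np.vstack(pts), colors)


def trimmed_icp(source: PointCloud, target: PointCloud,
                init: RigidTransform = None, trim_fraction: float = 0.8,
                max_iter: int = 60, tol: float = 1e-8):
    """Trimmed iterative closest point: at each iteration match every source
    point to its nearest target neighbor, keep the best ``trim_fraction`` of
    matches by distance, and update the pose by weighted rigid fit; stop when
    the relative change of the trimmed MSE falls below ``tol``.

    Returns ``(pose, trimmed_rms, converged)``. The trimmed MSE is
    non-increasing across iterations.
    """
    src = np.asarray(source.points if isinstance(source, PointCloud)
                     else source, float)
    tgt = np.asarray(target.points if isinstance(target, PointCloud)
                     else target, float)
    if len(src) < 3 or len(tgt) < 3:
        raise ValueError("both clouds need at least 3 points")
    if not 0.0 < trim_fraction <= 1.0:
        raise ValueError("trim_fraction must be in (0, 1]")
    pose = RigidTransform.identity() if init is None else init
    n_keep = max(int(np.ceil(trim_fraction * len(src))), 3)
    tree = cKDTree(tgt)
    prev_mse = np.inf
    converged = False
    for _ in range(max_iter):
        moved = pose.apply(src)
        dist, idx = tree.query(moved)
        keep = np.argsort(dist)[:n_keep]
        mse = float(np.mean(dist[keep] ** 2))
        if np.isfinite(prev_mse) and prev_mse - mse <= tol * max(prev_mse, 1e-300):
            converged = True
            prev_mse = min(mse, prev_mse)
            break
        prev_mse = mse
        try:
            pose = fit_rigid(src[keep], tgt[idx[keep]])
        except ValueError:
            break
    moved = pose.apply(src)
    dist, _ = tree.query(moved)
    trimmed_rms = float(np.sqrt(np.mean(np.sort(dist)[:n_keep] ** 2)))
    return pose, trimmed_rms, converged


def build_joint_model(tool_vertices: np.ndarray,
                      hand_points: np.ndarray) -> tuple:
    """Union of the frame-0-registered tool vertices and the segmented hand
    points, with a per-point origin tag (``True`` for tool points)."""
    tv = np.asarray(tool_vertices, float).reshape(-1, 3)
    hp = np.asarray(hand_points, float).reshape(-1, 3)
    if len(tv) == 0 or len(hp) == 0:
        raise ValueError("joint model needs non-empty tool and hand points")
    cloud = PointCloud(np.vstack([tv, hp]))
    origin_is_tool = np.concatenate([np.ones(len(tv), bool),
                                     np.zeros(len(hp), bool)])
    return cloud, origin_is_tool


@dataclass(frozen=True)
class TrackingParams:
    trim_fraction: float = 0.8
    divergence_rms: float = 0.010          # m: trimmed RMS above this diverged
    n_restarts: int = 20
    restart_max_angle: float = np.radians(15.0)
    restart_max_translation: float = 0.030
    out_fps: float | None = 5.0
    max_iter: int = 60
    tol: float = 1e-8


def track_tool_sequence(joint_model: PointCloud, recording: Recording,
                        init_pose: RigidTransform,
                        params: TrackingParams = TrackingParams(),
                        seed: int = 0) -> TrackedSequence:
    """Track the joint hand-tool model through a recording.

    Frame t is initialized from the previous non-discarded pose. When the
    trimmed RMS exceeds the divergence threshold the frame is re-registered
    from multi-start perturbations of the last good pose (best residual
    wins, status ``reinitialized``); frames still above threshold are
    ``discarded`` and excluded from initialization. Optionally downsampled
    to ``out_fps`` afterwards.
    """
    rng = np.random.default_rng(seed)
    poses, residuals, status = [], [], []
    last_good = init_pose
    for t, frame in enumerate(recording.frames):
        pose, rms, _ = trimmed_icp(joint_model, frame, last_good,
                                   params.trim_fraction, params.max_iter,
                                   params.tol)
        st = "ok"
        if rms > params.divergence_rms:
            if t == 0:
                raise ValueError(
                    f"frame 0 registration RMS {rms * 1000:.1f} mm exceeds "
                    f"the divergence threshold: bad initial pose")
            best = (pose, rms)
            for _ in range(params.n_restarts):
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                angle = rng.uniform(0, params.restart_max_angle)
                dt = rng.uniform(-params.restart_max_translation,
                                 params.restart_max_translation, 3)
                perturbed = RigidTransform.from_rotvec(axis * angle, dt) \
                    @ last_good
                p2, r2, _ = trimmed_icp(joint_model, frame, perturbed,
                                        params.trim_fraction, params.max_iter,
                                        params.tol)
                if r2 < best[1]:
                    best = (p2, r2)
            pose, rms = best
            st = "reinitialized" if rms <= params.divergence_rms else "discarded"
        poses.append(pose)
        residuals.append(rms)
        if st != "discarded":
            last_good = pose
        status.append(st)
    seq = TrackedSequence(poses, np.asarray(residuals), status)
    if params.out_fps is not None and params.out_fps < recording.native_fps:
        step = int(round(recording.native_fps / params.out_fps))
        keep = list(range(0, len(poses), step))
        seq = TrackedSequence([poses[i] for i in keep], seq.residuals[keep],
                              [status[i] for i in keep])
    return seq


def fit_hand_pose(correspondences: HandCorrespondences,
                  assets: HandModelAssets, lam: float = 1e-4,
                  max_outer: int = 60, rel_tol: float = 1e-8):
    """Fit the hand placement and PCA pose from 16 labeled correspondences.

    Minimizes ``sum_i ||H(v_i(theta)) - p_i||^2 + lam * ||theta||^2`` over a
    rigid transform H and the 15 PCA coefficients, with shape fixed at the
    average hand (beta = 0) and the global rotation folded into H, by
    alternating a closed-form rigid fit with damped least squares on theta
    until the relative objective change drops below ``rel_tol``.

    Returns ``(H_hand0, hand_pose)`` with ``H_hand0`` in the frame of the
    correspondence points (the tool-model frame in the labeling pipeline).
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    correspondences.validate_for(assets)
    vi = correspondences.vertex_indices
    targets = correspondences.points
    sv = np.linalg.svd(targets - targets.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-12 * max(sv[0], 1e-300):
        raise ValueError("degenerate (collinear) correspondence targets")

    theta = np.zeros(N_PCA)

    def model_vertices(th):
        mesh, _ = synthesize_hand(assets, HandPose(pca_coeffs=th))
        return mesh.vertices[vi]

    def objective(H, th, verts=None):
        v = model_vertices(th) if verts is None else verts
        r = H.apply(v) - targets
        return float(np.sum(r * r) + lam * th @ th)

    H = fit_rigid(model_vertices(theta), targets)
    prev = objective(H, theta)
    sqrt_lam = np.sqrt(lam)
    for _ in range(max_outer):
        # theta step at fixed H (damped least squares, warm start)
        def residuals(th):
            r = (H.apply(model_vertices(th)) - targets).ravel()
            return np.concatenate([r, sqrt_lam * th])

        sol = least_squares(residuals, theta, method="lm", max_nfev=200)
        theta = sol.x
        # rigid step at fixed theta (global optimum)
        verts = model_vertices(theta)
        H = fit_rigid(verts, targets)
        cur = objective(H, theta, verts)
        if prev - cur <= rel_tol * max(prev, 1e-300):
            prev = min(cur, prev)
            break
        prev = cur
    return H, HandPose(pca_coeffs=theta)


def propagate_hand_labels(tracked: TrackedSequence, H_hand0: RigidTransform,
                          hand_pose: HandPose, assets: HandModelAssets):
    """Per-frame hand labels via ``H_hand^t = H_tool^t @ H_hand^0``.

    ``H_hand0`` must be expressed in the tool-model frame (the frame the
    hand was fitted in), which is what makes the composition exact. Returns
    a list with one ``{hand_pose_matrix, joints}`` dict per frame; discarded
    frames yield ``None``.
    """
    _, joints0 = synthesize_hand(assets, hand_pose)
    out = []
    for pose, st in zip(tracked.tool_poses, tracked.status):
        if st == "discarded":
            out.append(None)
            continue
        H_hand_t = pose @ H_hand0
        out.append({"hand_pose": H_hand_t,
                    "joints": H_hand_t.apply(joints0)})
    return out
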