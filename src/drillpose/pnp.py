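"""Pose from 2D-3D correspondences: EPnP, Mahalanobis (uncertainty) PnP,
and the focal-normalized translation recovery.

The uncertainty-driven PnP refines the pose (R, t) minimizing

    sum_k (x_k(R, t) - mu_k)^T  Sigma_k^{-1}  (x_k(R, t) - mu_k)

where x_k is the pinhole projection of the k-th 3D keypoint and
(mu_k, Sigma_k) are the voted keypoint distributions; it is initialized via
EPnP on the four keypoints with the lowest uncertainty (smallest covariance
trace). The translation recovery inverts the focal-normalized depth
parameterization d_f = (t_z - z0) / f around the image center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .geometry import CameraIntrinsics, RigidTransform, fit_rigid, project_points
from .keypoints import KeypointDistribution, KeypointSet3D

__all__ = ["epnp", "uncertainty_pnp", "TranslationEstimate",
           "recover_translation", "encode_translation"]

_DEFAULT_Z0 = 0.4


def _control_points(points: np.ndarray):
    """EPnP control points: centroid plus principal directions scaled by the
    data spread; 3 control points in the planar case."""
    c0 = points.mean(axis=0)
    centered = points - c0
    cov = centered.T @ centered / len(points)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] < 1e-18:
        raise ValueError("degenerate 3D point configuration")
    planar = evals[2] < 1e-10 * evals[0]
    n_dir = 2 if planar else 3
    ctrl = [c0] + [c0 + evecs[:, i] * np.sqrt(max(evals[i], 1e-16))
                   for i in range(n_dir)]
    return np.asarray(ctrl), planar


def _barycentric(points: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
    """Affine coordinates of each point w.r.t. the control points."""
    n_ctrl = len(ctrl)
    M = np.vstack([ctrl.T, np.ones(n_ctrl)])          # 4 x n_ctrl
    B = np.vstack([points.T, np.ones(len(points))])   # 4 x n
    alphas, *_ = np.linalg.lstsq(M, B, rcond=None)
    resid = M @ alphas - B
    if np.abs(resid).max() > 1e-8:
        raise ValueError("points not representable in control-point frame")
    return alphas.T                                    # n x n_ctrl


def _reprojection_rmse(pose, pts3d, pts2d, intr):
    cam = pose.apply(pts3d)
    if np.any(cam[:, 2] <= 0):
        return np.inf
    uv = project_points(cam, intr)
    return float(np.sqrt(np.mean(np.sum((uv - pts2d) ** 2, axis=1))))


def _pose_from_camera_points(pts3d, cam_pts):
    pose = fit_rigid(pts3d, cam_pts)
    return pose


def epnp(points3d: np.ndarray, points2d: np.ndarray,
         intr: CameraIntrinsics) -> RigidTransform:
    """EPnP: non-iterative pose from >= 4 correspondences.

    Unknown camera-frame control-point coordinates are expressed in the
    null space of the 2n x 3m projection constraint matrix; the beta
    combination is resolved for the 1- and 2-dimensional kernel cases by
    matching inter-control-point distances, cheirality is enforced by sign,
    and the final pose is the rigid fit between world points and their
    reconstructed camera-frame positions (best reprojection wins).
    """
    pts3d = np.asarray(points3d, float).reshape(-1, 3)
    pts2d = np.asarray(points2d, float).reshape(-1, 2)
    if len(pts3d) != len(pts2d):
        raise ValueError("points3d/points2d length mismatch")
    n = len(pts3d)
    if n < 4:
        raise ValueError(f"EPnP needs at least 4 points, got {n}")
    sv = np.linalg.svd(pts3d - pts3d.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-12 * max(sv[0], 1e-300):
        raise ValueError("collinear 3D points")

    ctrl, planar = _control_points(pts3d)
    alphas = _barycentric(pts3d, ctrl)                # n x m
    m = len(ctrl)

    f = intr.focal
    cx, cy = intr.principal_point
    u = pts2d[:, 0]
    v = pts2d[:, 1]
    M = np.zeros((2 * n, 3 * m))
    for j in range(m):
        M[0::2, 3 * j + 0] = alphas[:, j] * f
        M[0::2, 3 * j + 2] = alphas[:, j] * (cx - u)
        M[1::2, 3 * j + 1] = alphas[:, j] * f
        M[1::2, 3 * j + 2] = alphas[:, j] * (cy - v)

    _, _, Vt = np.linalg.svd(M)
    kernel = Vt[::-1]                                  # rows by ascending sv

    d_world = np.linalg.norm(ctrl[:, None, :] - ctrl[None, :, :], axis=-1)
    iu = np.triu_indices(m, 1)
    dw = d_world[iu]

    def pose_from_x(x):
        cam_ctrl = x.reshape(m, 3)
        cam_pts = alphas @ cam_ctrl
        if cam_pts[:, 2].mean() < 0:                  # cheirality by sign flip
            cam_pts = -cam_pts
        if np.any(cam_pts[:, 2] <= 0):
            return None
        try:
            return _pose_from_camera_points(pts3d, cam_pts)
        except ValueError:
            return None

    candidates = []
    # N = 1: single kernel vector, scale from control-point distances
    v1 = kernel[0]
    dv = np.linalg.norm(v1.reshape(m, 3)[:, None] - v1.reshape(m, 3)[None],
                        axis=-1)[iu]
    denom = dv @ dv
    if denom > 0:
        beta = (dv @ dw) / denom
        p = pose_from_x(beta * v1)
        if p is not None:
            candidates.append(p)
    # N = 2: solve the quadratic distance system for (b11, b12, b22)
    if len(kernel) > 1:
        v2 = kernel[1]
        r1 = v1.reshape(m, 3)
        r2 = v2.reshape(m, 3)
        d1 = r1[iu[0]] - r1[iu[1]]
        d2 = r2[iu[0]] - r2[iu[1]]
        A = np.column_stack([np.sum(d1 * d1, axis=1),
                             2 * np.sum(d1 * d2, axis=1),
                             np.sum(d2 * d2, axis=1)])
        sol, *_ = np.linalg.lstsq(A, dw ** 2, rcond=None)
        b11, b12, b22 = sol
        if b11 > 0:
            b1 = np.sqrt(b11)
            b2 = b12 / b1
            p = pose_from_x(b1 * v1 + b2 * v2)
            if p is not None:
                candidates.append(p)
        if b22 > 0:
            b2 = np.sqrt(b22)
            b1 = b12 / b2
            p = pose_from_x(b1 * v1 + b2 * v2)
            if p is not None:
                candidates.append(p)
    if not candidates:
        raise ValueError("EPnP failed to produce a cheirality-consistent pose")
    errs = [_reprojection_rmse(p, pts3d, pts2d, intr) for p in candidates]
    return candidates[int(np.argmin(errs))]


def uncertainty_pnp(dists: list, kp3d: KeypointSet3D,
                    intr: CameraIntrinsics,
                    cov_regularization: float = 1e-9) -> RigidTransform:
    """Minimize the summed Mahalanobis reprojection distance over SE(3).

    Damped least squares on an axis-angle + translation parameterization,
    initialized from EPnP on the four keypoints with the smallest covariance
    trace. Each covariance is regularized by ``+ eps I`` before inversion so
    degenerate single-hypothesis distributions stay usable.
    """
    mus = np.asarray([d.mean for d in dists])
    covs = np.asarray([d.covariance for d in dists])
    pts3d = kp3d.points
    if len(mus) != len(pts3d):
        raise ValueError("keypoint count mismatch")

    covs = covs + cov_regularization * np.eye(2)
    # whitening matrices: residual r_k = L_k (x_k - mu_k), L_k^T L_k = Sigma^-1
    Ls = np.linalg.cholesky(np.linalg.inv(covs))

    traces = covs[:, 0, 0] + covs[:, 1, 1]
    init_idx = np.argsort(traces)[:4]
    try:
        init = epnp(pts3d[init_idx], mus[init_idx], intr)
    except ValueError:
        init = RigidTransform(np.eye(3), np.array([0.0, 0.0, _DEFAULT_Z0]))

    x0 = np.concatenate([init.rotvec(), init.translation])

    def residuals(x):
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        cam = pts3d @ R.T + x[3:]
        z = cam[:, 2]
        if np.any(z <= 1e-6):
            return np.full(2 * len(pts3d), 1e6)
        uv = cam[:, :2] / z[:, None] * intr.focal + intr.principal_point
        diff = uv - mus
        # L^T (x - mu): whitened residuals per keypoint
        return np.einsum("kab,ka->kb", Ls, diff).ravel()

    res = least_squares(residuals, x0, method="lm", xtol=1e-15, ftol=1e-15,
                        gtol=1e-15, max_nfev=2000)
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError(f"uncertainty PnP diverged (final cost {res.cost})")
    return RigidTransform(Rotation.from_rotvec(res.x[:3]).as_matrix(),
                          res.x[3:])


@dataclass(frozen=True)
class TranslationEstimate:
    """Regressed 2D translation (pixels, image coordinates) and
    focal-normalized depth offset, with the depth anchor z0 (meters)."""
    t2d: np.ndarray
    depth_offset_norm: float
    z0: float = _DEFAULT_Z0

    def __post_init__(self):
        object.__setattr__(self, "t2d", np.asarray(self.t2d, float).reshape(2))


def recover_translation(est: TranslationEstimate,
                        intr: CameraIntrinsics) -> np.ndarray:
    """Recover the 3D translation from the focal-normalized parameterization
    (principal point assumed at the image center):

        t_z = f * d_f + z0,   t_xy = t2d * t_z / f
    """
    tz = intr.focal * est.depth_offset_norm + est.z0
    if tz <= 0:
        raise ValueError(f"recovered depth {tz:.6g} is not positive")
    return np.array([est.t2d[0] * tz / intr.focal,
                     est.t2d[1] * tz / intr.focal, tz])


def encode_translation(t: np.ndarray, intr: CameraIntrinsics,
                       z0: float = _DEFAULT_Z0) -> TranslationEstimate:
    """Forward relations: the (t2d, d_f) pair that recovers ``t`` exactly."""
    t = np.asarray(t, float).reshape(3)
    if t[2] <= 0:
        raise ValueError("translation must have positive depth")
    d_f = (t[2] - z0) / intr.focal
    t2d = t[:2] * intr.focal / t[2]
    return TranslationEstimate(t2d, float(d_f), z0)
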