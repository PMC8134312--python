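"""Rigid-geometry, pinhole-camera, and mesh/point-cloud primitives.

Conventions used throughout the package:

* camera frame: x right, y down, z forward (optical axis);
* pixel coordinates are 0-based with pixel centers at integer coordinates;
* all lengths are meters internally — millimeters appear only in the
  evaluation layer;
* an SE(3) pose serializes as a 4x4 row-major homogeneous matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "CameraIntrinsics",
    "ToolMesh",
    "PointCloud",
    "project_points",
    "back_project",
    "fit_rigid",
    "angle_between",
    "signed_distance",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """An SE(3) transform: ``x -> R @ x + t`` with lengths in meters."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {R.shape}")
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("non-finite rigid transform")
        err = np.abs(R.T @ R - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation is not orthonormal (|R^T R - I| = {err:.2e})")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has negative determinant (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, H: np.ndarray) -> "RigidTransform":
        H = np.asarray(H, dtype=float)
        if H.shape != (4, 4):
            raise ValueError(f"expected 4x4 matrix, got {H.shape}")
        return cls(H[:3, :3], H[:3, 3])

    @classmethod
    def from_rotvec(cls, rotvec, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(Rotation.from_rotvec(np.asarray(rotvec, float)).as_matrix(),
                   np.asarray(translation, float))

    @classmethod
    def random(cls, rng: np.random.Generator, max_angle: float = np.pi,
               max_translation: float = 1.0) -> "RigidTransform":
        """A uniformly random rotation (scaled to ``max_angle``) and a
        translation uniform in a cube of half-width ``max_translation``."""
        rv = Rotation.random(random_state=rng).as_rotvec()
        angle = np.linalg.norm(rv)
        if angle > 0 and max_angle < np.pi:
            rv = rv / angle * (angle * max_angle / np.pi)
        t = rng.uniform(-max_translation, max_translation, 3)
        return cls(Rotation.from_rotvec(rv).as_matrix(), t)

    def as_matrix(self) -> np.ndarray:
        H = np.eye(4)
        H[:3, :3] = self.rotation
        H[:3, 3] = self.translation
        return H

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.rotation.T + self.translation
        return out[0] if single else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self @ other``: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotvec(self) -> np.ndarray:
        return Rotation.from_matrix(self.rotation).as_rotvec()


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics: focal length in pixels, principal point in pixels,
    image size as (width, height)."""

    focal: float
    principal_point: np.ndarray
    image_size: tuple

    def __post_init__(self):
        if not self.focal > 0:
            raise ValueError(f"focal must be positive, got {self.focal}")
        pp = np.asarray(self.principal_point, dtype=float).reshape(2)
        object.__setattr__(self, "principal_point", pp)
        w, h = self.image_size
        object.__setattr__(self, "image_size", (int(w), int(h)))

    @classmethod
    def centered(cls, focal: float, image_size) -> "CameraIntrinsics":
        """Intrinsics with the principal point at the image center, the
        assumption under which the depth un-projection formulas hold."""
        w, h = image_size
        return cls(focal, ((w - 1) / 2.0, (h - 1) / 2.0), (w, h))

    def matrix(self) -> np.ndarray:
        K = np.eye(3)
        K[0, 0] = K[1, 1] = self.focal
        K[:2, 2] = self.principal_point
        return K

    def to_dict(self) -> dict:
        return {"focal": float(self.focal),
                "principal_point": [float(v) for v in self.principal_point],
                "image_size": list(self.image_size)}

    @classmethod
    def from_dict(cls, d: dict) -> "CameraIntrinsics":
        return cls(d["focal"], d["principal_point"], tuple(d["image_size"]))


@dataclass
class ToolMesh:
    """A triangle mesh with named landmark points (at least ``tip``) and named
    unit axes (at least ``bit_axis``), all expressed in the tool frame."""

    vertices: np.ndarray
    faces: np.ndarray
    landmarks: dict = field(default_factory=dict)
    axes: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        n = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise ValueError("face indices out of range")
        self.landmarks = {k: np.asarray(v, float).reshape(3)
                          for k, v in self.landmarks.items()}
        axes = {}
        for k, v in self.axes.items():
            v = np.asarray(v, float).reshape(3)
            nrm = np.linalg.norm(v)
            if abs(nrm - 1.0) > 1e-6:
                raise ValueError(f"axis {k!r} is not unit-norm ({nrm})")
            axes[k] = v / nrm
        self.axes = axes

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @property
    def tip(self) -> np.ndarray:
        return self.landmarks["tip"]

    @property
    def bit_axis(self) -> np.ndarray:
        return self.axes["bit_axis"]

    def bounding_box_center(self) -> np.ndarray:
        return 0.5 * (self.vertices.min(axis=0) + self.vertices.max(axis=0))

    # --- I/O: mesh via trimesh (OBJ / ascii+binary PLY), landmarks sidecar ---
    def save(self, path) -> None:
        path = Path(path)
        self.as_trimesh().export(path)
        sidecar = {"landmarks": {k: v.tolist() for k, v in self.landmarks.items()},
                   "axes": {k: v.tolist() for k, v in self.axes.items()}}
        path.with_suffix(path.suffix + ".landmarks.json").write_text(
            json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "ToolMesh":
        path = Path(path)
        tm = trimesh.load_mesh(path, process=False)
        landmarks, axes = {}, {}
        sidecar = path.with_suffix(path.suffix + ".landmarks.json")
        if sidecar.exists():
            d = json.loads(sidecar.read_text())
            landmarks = d.get("landmarks", {})
            axes = d.get("axes", {})
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), landmarks, axes)


@dataclass
class PointCloud:
    """N x 3 points in meters with optional per-point RGB colors in [0, 1]."""

    points: np.ndarray
    colors: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point cloud contains non-finite coordinates")
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=float).reshape(-1, 3)
            if len(self.colors) != len(self.points):
                raise ValueError("colors length mismatch")

    def __len__(self) -> int:
        return len(self.points)

    def transformed(self, T: RigidTransform) -> "PointCloud":
        return PointCloud(T.apply(self.points), self.colors)

    def save(self, path) -> None:
        pc = trimesh.PointCloud(self.points,
                                colors=None if self.colors is None
                                else (self.colors * 255).astype(np.uint8))
        pc.export(Path(path))

    @classmethod
    def load(cls, path) -> "PointCloud":
        pc = trimesh.load(Path(path))
        colors = None
        if isinstance(pc, trimesh.PointCloud) and pc.colors is not None and len(pc.colors):
            colors = np.asarray(pc.colors, dtype=float)[:, :3] / 255.0
        return cls(np.asarray(pc.vertices, dtype=float), colors)


def project_points(points: np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    """Pinhole projection of camera-frame points (meters) to pixels.

    Raises if any point has non-positive depth, naming the first offender.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    z = pts[:, 2]
    bad = np.flatnonzero(z <= 0)
    if bad.size:
        raise ValueError(f"point {bad[0]} has non-positive depth z={z[bad[0]]:.6g}")
    uv = pts[:, :2] / z[:, None] * intr.focal + intr.principal_point
    return uv if np.asarray(points).ndim > 1 else uv[0]


def back_project(pixels: np.ndarray, depths: np.ndarray,
                 intr: CameraIntrinsics) -> np.ndarray:
    """Inverse of :func:`project_points` at known depth (meters)."""
    px = np.atleast_2d(np.asarray(pixels, dtype=float))
    z = np.atleast_1d(np.asarray(depths, dtype=float))
    xy = (px - intr.principal_point) * z[:, None] / intr.focal
    out = np.column_stack([xy, z])
    return out if np.asarray(pixels).ndim > 1 else out[0]


def fit_rigid(source: np.ndarray, target: np.ndarray,
              weights: np.ndarray | None = None) -> RigidTransform:
    """Weighted least-squares rigid alignment (Kabsch/Umeyama without scale).

    Returns the transform T minimizing ``sum_i w_i ||T(s_i) - t_i||^2`` with
    ``det(R) = +1`` enforced (reflections rejected via sign correction).
    """
    src = np.asarray(source, dtype=float).reshape(-1, 3)
    tgt = np.asarray(target, dtype=float).reshape(-1, 3)
    if src.shape != tgt.shape:
        raise ValueError("source/target shape mismatch")
    n = len(src)
    if n < 3:
        raise ValueError(f"need at least 3 correspondences, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float).reshape(n)
        if np.any(w < 0):
            raise ValueError("negative weights")
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("weights sum to zero")
    w = w / wsum
    mu_s = w @ src
    mu_t = w @ tgt
    S = (src - mu_s).T @ ((tgt - mu_t) * w[:, None])
    # rank < 2 means the weighted points are collinear: rotation ill-determined
    sv = np.linalg.svd(S, compute_uv=False)
    if sv[1] < 1e-12 * max(sv[0], 1e-300):
        raise ValueError("degenerate (collinear) point configuration")
    U, _, Vt = np.linalg.svd(S)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_t - R @ mu_s
    return RigidTransform(R, t)


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two 3-vectors in degrees, in [0, 180]."""
    u = np.asarray(u, dtype=float).reshape(3)
    v = np.asarray(v, dtype=float).reshape(3)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero-norm vector")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def _closest_point_distance(mesh: trimesh.Trimesh, points: np.ndarray) -> np.ndarray:
    from trimesh.proximity import closest_point_naive
    _, dist, _ = closest_point_naive(mesh, np.atleast_2d(points))
    return dist


def _winding_number(mesh: trimesh.Trimesh, points: np.ndarray) -> np.ndarray:
    """Generalized winding number of each query point, vectorized over
    triangles (van Oosterom & Strackee solid angle). ~0 outside, ~1 inside."""
    pts = np.atleast_2d(points)
    tri = mesh.triangles  # (F, 3, 3)
    wn = np.zeros(len(pts))
    # chunk the point axis so the (chunk, F) broadcast stays in cache
    chunk = max(1, int(2e6 / max(len(tri), 1)))
    for lo in range(0, len(pts), chunk):
        p = pts[lo:lo + chunk][:, None, :]          # (c, 1, 3)
        a = tri[None, :, 0] - p                     # (c, F, 3)
        b = tri[None, :, 1] - p
        c = tri[None, :, 2] - p
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        num = np.einsum("cfi,cfi->cf", a, np.cross(b, c))
        den = (la * lb * lc + np.einsum("cfi,cfi->cf", a, b) * lc
               + np.einsum("cfi,cfi->cf", b, c) * la
               + np.einsum("cfi,cfi->cf", a, c) * lb)
        wn[lo:lo + chunk] = np.arctan2(num, den).sum(axis=1) / (2.0 * np.pi)
    return wn


def signed_distance(mesh: trimesh.Trimesh, points: np.ndarray) -> np.ndarray:
    """Signed distance to a watertight mesh: positive inside, negative outside.

    Raises for non-watertight meshes, where the sign is undefined.
    """
    if not mesh.is_watertight:
        raise ValueError("signed distance requires a watertight mesh")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = _closest_point_distance(mesh, pts)
    inside = _winding_number(mesh, pts) > 0.5
    return np.where(inside, d, -d)
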