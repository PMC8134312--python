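"""Articulated parametric hand with a MANO-compatible parameter layout.

The hand is controlled by 18 pose parameters — a 3-vector global (wrist)
rotation plus 15 PCA coefficients mapped through an orthonormal pose basis to
the 45 per-joint axis-angles of the 15 articulated finger joints — and 10
shape coefficients scaling linear displacement modes, the same layout as the
licensed MANO model. The licensed assets themselves are not shipped; a
deterministic procedural stand-in (palm box plus five three-segment fingers,
16 skeleton joints and 5 fingertip sites for 21 reported joint positions) is
generated from a fixed seed and exposed through the same asset schema, so
real MANO arrays can be loaded interchangeably.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

from .geometry import ToolMesh

__all__ = ["HandPose", "HandModelAssets", "build_standin_assets",
           "synthesize_hand", "save_assets", "load_assets",
           "N_PCA", "N_SHAPE", "N_JOINTS", "N_REPORTED_JOINTS"]

N_PCA = 15          # pose PCA coefficients
N_SHAPE = 10        # shape coefficients
N_JOINTS = 16       # skeleton: wrist + 3 per finger
N_TIPS = 5
N_REPORTED_JOINTS = N_JOINTS + N_TIPS  # 21

FINGERS = ("thumb", "index", "middle", "ring", "pinky")


@dataclass(frozen=True)
class HandPose:
    """18 pose parameters (3 global axis-angle + 15 PCA) and 10 shape
    coefficients. The parameter counts are part of the contract and cannot
    be constructed otherwise."""

    global_rot: np.ndarray = field(default_factory=lambda: np.zeros(3))
    pca_coeffs: np.ndarray = field(default_factory=lambda: np.zeros(N_PCA))
    shape_coeffs: np.ndarray = field(default_factory=lambda: np.zeros(N_SHAPE))

    def __post_init__(self):
        g = np.asarray(self.global_rot, dtype=float).reshape(-1)
        p = np.asarray(self.pca_coeffs, dtype=float).reshape(-1)
        s = np.asarray(self.shape_coeffs, dtype=float).reshape(-1)
        if g.shape != (3,):
            raise ValueError(f"global_rot must have 3 entries, got {g.shape}")
        if p.shape != (N_PCA,):
            raise ValueError(f"pca_coeffs must have {N_PCA} entries, got {p.shape}")
        if s.shape != (N_SHAPE,):
            raise ValueError(f"shape_coeffs must have {N_SHAPE} entries, got {s.shape}")
        if not (np.all(np.isfinite(g)) and np.all(np.isfinite(p))
                and np.all(np.isfinite(s))):
            raise ValueError("non-finite hand parameters")
        object.__setattr__(self, "global_rot", g)
        object.__setattr__(self, "pca_coeffs", p)
        object.__setattr__(self, "shape_coeffs", s)

    def to_dict(self) -> dict:
        return {"global_rot": self.global_rot.tolist(),
                "pca_coeffs": self.pca_coeffs.tolist(),
                "shape_coeffs": self.shape_coeffs.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "HandPose":
        return cls(d["global_rot"], d["pca_coeffs"], d["shape_coeffs"])


@dataclass
class HandModelAssets:
    """Arrays defining the hand: template vertices/faces, kinematic tree,
    rest joints, skinning weights, pose basis (PCA -> joint axis-angles),
    shape displacement modes and the 21-point joint regressor."""

    template_vertices: np.ndarray      # (V, 3)
    faces: np.ndarray                  # (F, 3)
    parents: np.ndarray                # (N_JOINTS,), parent index, -1 for wrist
    rest_joints: np.ndarray            # (N_JOINTS, 3)
    skinning_weights: np.ndarray       # (V, N_JOINTS), rows sum to 1
    pose_basis: np.ndarray             # (N_PCA, 3*(N_JOINTS-1)) orthonormal rows
    shape_modes: np.ndarray            # (N_SHAPE, V, 3)
    joint_regressor: np.ndarray        # (N_REPORTED_JOINTS, V), rows sum to 1
    fingertip_vertex_hint: np.ndarray | None = None  # (N_TIPS,) nearest-vertex ids

    def __post_init__(self):
        self.template_vertices = np.asarray(self.template_vertices, float)
        self.faces = np.asarray(self.faces, int)
        V = len(self.template_vertices)
        w = np.asarray(self.skinning_weights, float)
        if w.shape != (V, N_JOINTS):
            raise ValueError("skinning weight shape mismatch")
        if np.abs(w.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError("skinning weight rows must sum to 1")
        B = np.asarray(self.pose_basis, float)
        if B.shape != (N_PCA, 3 * (N_JOINTS - 1)):
            raise ValueError("pose basis shape mismatch")
        G = B @ B.T
        if np.abs(G - np.diag(np.diag(G))).max() > 1e-9:
            raise ValueError("pose basis rows must be mutually orthogonal")
        if np.asarray(self.shape_modes, float).shape != (N_SHAPE, V, 3):
            raise ValueError("shape mode shape mismatch")
        A = np.asarray(self.joint_regressor, float)
        if A.shape != (N_REPORTED_JOINTS, V):
            raise ValueError("joint regressor shape mismatch")

    @property
    def n_vertices(self) -> int:
        return len(self.template_vertices)


# ---------------------------------------------------------------------------
# procedural stand-in construction

# rest-pose skeleton (meters): wrist at origin, palm in the xy-plane with
# fingers along +y, palm normal (grasping side) along +z
_FINGER_ROOT = {
    "thumb": np.array([-0.042, 0.022, 0.0]),
    "index": np.array([-0.028, 0.088, 0.0]),
    "middle": np.array([-0.009, 0.092, 0.0]),
    "ring": np.array([0.010, 0.089, 0.0]),
    "pinky": np.array([0.029, 0.082, 0.0]),
}
_FINGER_DIR = {
    "thumb": np.array([-0.60, 0.80, 0.0]),
    "index": np.array([0.0, 1.0, 0.0]),
    "middle": np.array([0.0, 1.0, 0.0]),
    "ring": np.array([0.0, 1.0, 0.0]),
    "pinky": np.array([0.05, 1.0, 0.0]),
}
_SEGMENT_LENGTHS = {
    "thumb": (0.036, 0.030, 0.026),
    "index": (0.040, 0.026, 0.022),
    "middle": (0.044, 0.029, 0.024),
    "ring": (0.040, 0.026, 0.022),
    "pinky": (0.030, 0.021, 0.019),
}
_FINGER_RADIUS = 0.0085
_PALM_SIZE = np.array([0.082, 0.095, 0.026])   # width, length, thickness
_PALM_CENTER = np.array([0.0, 0.045, 0.0])


def _skeleton():
    """Rest joints, parents, and per-finger joint index lists."""
    joints = [np.zeros(3)]          # 0: wrist
    parents = [-1]
    finger_joints = {}
    tips = []
    for f in FINGERS:
        d = _FINGER_DIR[f] / np.linalg.norm(_FINGER_DIR[f])
        p = _FINGER_ROOT[f].copy()
        idxs = []
        parent = 0
        for seg_len in _SEGMENT_LENGTHS[f]:
            joints.append(p.copy())
            parents.append(parent)
            parent = len(joints) - 1
            idxs.append(parent)
            p = p + d * seg_len
        finger_joints[f] = idxs
        # fingertip pad site: distal end, offset to the palm-side surface
        tips.append(p + np.array([0.0, 0.0, _FINGER_RADIUS]) * 0.9)
    return np.array(joints), np.array(parents, int), finger_joints, np.array(tips)


def _segment_mesh(p0, p1, radius, sections=6):
    return trimesh.creation.cylinder(radius=radius, segment=[p0, p1],
                                     sections=sections)


def _exact_affine_regressor(template: np.ndarray, targets: np.ndarray,
                            k0: int = 16) -> np.ndarray:
    """Rows of affine weights (summing to 1) over template vertices that
    reproduce each target point exactly at rest: minimal-norm solution of the
    4 affine constraints over the k nearest vertices."""
    V = len(template)
    A = np.zeros((len(targets), V))
    for j, tgt in enumerate(targets):
        k = k0
        while True:
            near = np.argsort(np.linalg.norm(template - tgt, axis=1))[:k]
            M = np.vstack([template[near].T, np.ones(k)])       # 4 x k
            b = np.append(tgt, 1.0)
            w, *_ = np.linalg.lstsq(M, b, rcond=None)
            if np.linalg.norm(M @ w - b) < 1e-10 or k >= min(4 * k0, V):
                break
            k = min(2 * k, V)
        A[j, near] = w
    return A


def build_standin_assets(seed: int = 20230) -> HandModelAssets:
    """Deterministic procedural hand assets.

    The pose basis is an orthonormal 15x45 matrix whose leading rows are
    dominated by per-finger curl directions (equal flexion of the three
    finger joints about the palm-plane axis), so small leading PCA
    coefficients produce anatomically sensible closing motions; the remaining
    rows complete the basis from a seeded random matrix via QR.
    """
    rng = np.random.default_rng(seed)
    rest_joints, parents, finger_joints, tips = _skeleton()

    parts = []
    part_joint = []
    palm = trimesh.creation.box(extents=_PALM_SIZE,
                                transform=trimesh.transformations.translation_matrix(
                                    _PALM_CENTER))
    palm = palm.subdivide().subdivide()
    parts.append(palm)
    part_joint.append(np.full(len(palm.vertices), 0))
    for f in FINGERS:
        d = _FINGER_DIR[f] / np.linalg.norm(_FINGER_DIR[f])
        for seg_i, jidx in enumerate(finger_joints[f]):
            p0 = rest_joints[jidx]
            p1 = p0 + d * _SEGMENT_LENGTHS[f][seg_i]
            seg = _segment_mesh(p0, p1, _FINGER_RADIUS * (1.0 - 0.12 * seg_i))
            parts.append(seg)
            part_joint.append(np.full(len(seg.vertices), jidx))

    vertices = np.vstack([p.vertices for p in parts])
    offsets = np.cumsum([0] + [len(p.vertices) for p in parts[:-1]])
    faces = np.vstack([p.faces + o for p, o in zip(parts, offsets)])
    joint_of_vertex = np.concatenate(part_joint)

    V = len(vertices)
    weights = np.zeros((V, N_JOINTS))
    weights[np.arange(V), joint_of_vertex] = 1.0

    # pose basis: finger-curl directions first, random completion, QR rows
    n_art = N_JOINTS - 1
    curls = np.zeros((len(FINGERS), 3 * n_art))
    for fi, f in enumerate(FINGERS):
        d = _FINGER_DIR[f] / np.linalg.norm(_FINGER_DIR[f])
        flex_axis = np.cross(d, [0.0, 0.0, 1.0])   # curl toward the palm side
        for jidx in finger_joints[f]:
            curls[fi, 3 * (jidx - 1):3 * jidx] = flex_axis
    raw = np.vstack([curls, rng.standard_normal((N_PCA - len(FINGERS), 3 * n_art))])
    Q, _ = np.linalg.qr(raw.T)
    pose_basis = Q.T[:N_PCA]
    # fix signs so leading rows curl toward the palm
    for fi in range(len(FINGERS)):
        if np.dot(pose_basis[fi], curls[fi]) < 0:
            pose_basis[fi] = -pose_basis[fi]

    # shape displacement modes
    modes = np.zeros((N_SHAPE, V, 3))
    modes[0] = vertices * 0.1                                    # global scale
    modes[1][:, 0] = vertices[:, 0] * 0.1                        # palm width
    for fi, f in enumerate(FINGERS):                             # finger lengths
        sel = np.isin(joint_of_vertex, finger_joints[f])
        d = _FINGER_DIR[f] / np.linalg.norm(_FINGER_DIR[f])
        along = (vertices[sel] - _FINGER_ROOT[f]) @ d
        modes[2 + fi][sel] = np.clip(along, 0, None)[:, None] * d * 0.1
    modes[7][:, 2] = vertices[:, 2] * 0.15                       # thickness
    modes[8][:, 0] = np.sign(vertices[:, 0]) * np.clip(vertices[:, 1], 0, None) * 0.05
    modes[9][:, 1] = np.clip(vertices[:, 1], 0, _PALM_SIZE[1]) * 0.08  # palm length

    targets = np.vstack([rest_joints, tips])
    regressor = _exact_affine_regressor(vertices, targets)
    tip_hint = np.array([int(np.argmin(np.linalg.norm(vertices - t, axis=1)))
                         for t in tips])

    return HandModelAssets(vertices, faces, parents, rest_joints, weights,
                           pose_basis, modes, regressor, tip_hint)


# ---------------------------------------------------------------------------
# synthesis

def _forward_kinematics(rest_joints, parents, local_rots):
    """World transforms per joint from per-joint local rotations."""
    n = len(rest_joints)
    world = np.zeros((n, 4, 4))
    for j in range(n):
        L = np.eye(4)
        L[:3, :3] = local_rots[j]
        p = parents[j]
        L[:3, 3] = rest_joints[j] - (rest_joints[p] if p >= 0 else 0.0)
        world[j] = L if p < 0 else world[p] @ L
    return world


def synthesize_hand(assets: HandModelAssets, pose: HandPose,
                    shape_override: np.ndarray | None = None):
    """Skin the hand for the given parameters.

    Pipeline: shape blendshapes -> PCA pose to per-joint axis-angles ->
    linear blend skinning -> global (wrist) rotation. Returns the surface as
    a :class:`~drillpose.geometry.ToolMesh` (no landmarks) together with the
    21 regressed joint/fingertip positions.
    """
    shape = pose.shape_coeffs if shape_override is None else \
        np.asarray(shape_override, float).reshape(N_SHAPE)
    verts0 = assets.template_vertices + np.einsum(
        "s,svx->vx", shape, assets.shape_modes)
    rest_joints = assets.joint_regressor[:N_JOINTS] @ verts0

    angles = (pose.pca_coeffs @ assets.pose_basis).reshape(N_JOINTS - 1, 3)
    local_rots = np.zeros((N_JOINTS, 3, 3))
    local_rots[0] = Rotation.from_rotvec(pose.global_rot).as_matrix()
    local_rots[1:] = Rotation.from_rotvec(angles).as_matrix()

    world = _forward_kinematics(rest_joints, assets.parents, local_rots)
    # skinning matrices: world transform relative to the rest configuration
    skin = world.copy()
    skin[:, :3, 3] -= np.einsum("jab,jb->ja", world[:, :3, :3], rest_joints)

    W = assets.skinning_weights
    blended = np.einsum("vj,jab->vab", W, skin)
    verts = np.einsum("vab,vb->va", blended[:, :3, :3], verts0) + blended[:, :3, 3]

    joints = assets.joint_regressor @ verts
    mesh = ToolMesh(verts, assets.faces)
    return mesh, joints


# ---------------------------------------------------------------------------
# asset archive I/O: npz container + JSON manifest

_ARRAY_KEYS = ("template_vertices", "faces", "parents", "rest_joints",
               "skinning_weights", "pose_basis", "shape_modes",
               "joint_regressor", "fingertip_vertex_hint")


def save_assets(assets: HandModelAssets, path) -> None:
    path = Path(path)
    np.savez_compressed(path, **{k: getattr(assets, k) for k in _ARRAY_KEYS
                                 if getattr(assets, k) is not None})
    manifest = {"schema": "drillpose-hand-assets-v1",
                "n_vertices": assets.n_vertices, "n_joints": N_JOINTS,
                "n_pca": N_PCA, "n_shape": N_SHAPE}
    path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=1))


def load_assets(path) -> HandModelAssets:
    with np.load(Path(path)) as z:
        kw = {k: z[k] for k in _ARRAY_KEYS if k in z}
    return HandModelAssets(**kw)
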