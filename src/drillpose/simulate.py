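"""Synthetic sensor-data simulation for exercising the labeling pipeline.

Emulates what the two-camera capture rig actually delivers to the labeling
stage: per-frame fused point clouds of a moving hand-tool assembly with
partial tool-surface dropout (the drill's matt plastic returns poor depth),
Gaussian sensor noise, and optional fully corrupted frames. Also provides
simulated hand-fitting correspondences from a known ground-truth hand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

from .fixtures import ToyAssets
from .geometry import PointCloud, RigidTransform
from .grasps import Grasp
from .handmodel import HandPose, synthesize_hand
from .labeling import HandCorrespondences, Recording, build_joint_model

__all__ = ["TrackingSimConfig", "simulate_tracking_sequence",
           "random_smooth_trajectory", "select_spread_vertices",
           "simulate_hand_correspondences"]


@dataclass(frozen=True)
class TrackingSimConfig:
    """Conditions of the simulated recording."""
    n_frames: int = 50
    max_angle_per_frame: float = 2.0      # degrees
    max_translation_per_frame: float = 0.005   # m
    sensor_noise: float = 0.001           # m, isotropic Gaussian
    tool_dropout: float = 0.60            # fraction of tool surface missing
    n_tool_samples: int = 8000            # pre-dropout surface samples
    n_hand_samples: int = 4000
    corrupt_frames: tuple = ()            # frame indices replaced by junk
    native_fps: float = 30.0


def random_smooth_trajectory(n_frames: int, max_angle_deg: float,
                             max_step: float,
                             rng: np.random.Generator) -> list:
    """Identity-starting rigid trajectory with bounded per-frame motion."""
    poses = [RigidTransform.identity()]
    for _ in range(n_frames - 1):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.radians(rng.uniform(0.5, 1.0) * max_angle_deg)
        dt = rng.uniform(-max_step, max_step, 3)
        poses.append(RigidTransform.from_rotvec(axis * angle, dt)
                     @ poses[-1])
    return poses


def simulate_tracking_sequence(assets: ToyAssets, grasp: Grasp,
                               config: TrackingSimConfig = TrackingSimConfig(),
                               seed: int = 0):
    """Build a synthetic recording of the grasped tool moving rigidly.

    Each frame samples the tool surface, drops the fraction of samples on
    one side of the tool (directional dropout emulating the poorly
    reflective tool surface), samples the hand surface, applies the frame's
    rigid motion and adds sensor noise. Frames listed in
    ``config.corrupt_frames`` are replaced by uniform junk points.

    Returns ``(recording, true_poses, joint_cloud)`` where ``joint_cloud``
    is the tool-vertex + hand-point joint model in the frame-0 (= tool)
    frame, ready for :func:`drillpose.labeling.track_tool_sequence`.
    """
    rng = np.random.default_rng(seed)
    tm = assets.tool.as_trimesh()
    hand_mesh, _ = synthesize_hand(assets.hand_assets, grasp.hand_pose)
    hand_tool_frame = grasp.hand_to_tool.apply(hand_mesh.vertices)
    hm = trimesh.Trimesh(hand_tool_frame, assets.hand_assets.faces,
                         process=False)
    joint_cloud, _ = build_joint_model(assets.tool.vertices, hand_tool_frame)

    poses = random_smooth_trajectory(config.n_frames,
                                     config.max_angle_per_frame,
                                     config.max_translation_per_frame, rng)
    frames = []
    for t, G in enumerate(poses):
        if t in config.corrupt_frames:
            junk = rng.uniform(-0.5, 0.5, (2000, 3))
            frames.append(PointCloud(junk))
            continue
        tool_pts, _ = trimesh.sample.sample_surface(
            tm, config.n_tool_samples, seed=int(rng.integers(2 ** 31)))
        tool_pts = np.asarray(tool_pts)
        if config.tool_dropout > 0:
            thresh = np.quantile(tool_pts[:, 1], config.tool_dropout)
            tool_pts = tool_pts[tool_pts[:, 1] > thresh]
        hand_pts, _ = trimesh.sample.sample_surface(
            hm, config.n_hand_samples, seed=int(rng.integers(2 ** 31)))
        cloud = np.vstack([tool_pts, np.asarray(hand_pts)])
        cloud = G.apply(cloud)
        if config.sensor_noise > 0:
            cloud = cloud + rng.normal(0.0, config.sensor_noise, cloud.shape)
        frames.append(PointCloud(cloud))
    return Recording(frames, native_fps=config.native_fps), poses, joint_cloud


def select_spread_vertices(vertices: np.ndarray, k: int,
                           preferred: np.ndarray | None = None) -> np.ndarray:
    """Deterministic spread vertex selection (greedy farthest point),
    optionally seeded with preferred indices (e.g. fingertip vertices)."""
    verts = np.asarray(vertices, float)
    chosen = list(np.asarray(preferred, int)) if preferred is not None else []
    if not chosen:
        centroid = verts.mean(axis=0)
        chosen = [int(np.argmax(np.linalg.norm(verts - centroid, axis=1)))]
    min_d = np.min([np.linalg.norm(verts - verts[c], axis=1) for c in chosen],
                   axis=0)
    while len(chosen) < k:
        nxt = int(np.argmax(min_d))
        chosen.append(nxt)
        min_d = np.minimum(min_d, np.linalg.norm(verts - verts[nxt], axis=1))
    return np.asarray(chosen[:k], int)


def simulate_hand_correspondences(assets, true_pose: HandPose,
                                  true_placement: RigidTransform,
                                  noise: float = 0.001, seed: int = 0):
    """16 labeled correspondences from a known hand configuration.

    Vertices are the fingertip-hint vertices plus a farthest-point spread
    over the rest of the hand; target points are their true posed positions
    plus isotropic Gaussian noise. Returns ``(correspondences, truth)``
    where ``truth`` carries the generating 21 joint positions.
    """
    rng = np.random.default_rng(seed)
    hand_assets = assets.hand_assets if isinstance(assets, ToyAssets) else assets
    # the fitting model folds global rotation into the rigid transform
    mesh, joints = synthesize_hand(
        hand_assets, HandPose(pca_coeffs=true_pose.pca_coeffs))
    idx = select_spread_vertices(hand_assets.template_vertices, 16,
                                 hand_assets.fingertip_vertex_hint)
    pts = true_placement.apply(mesh.vertices[idx])
    if noise > 0:
        pts = pts + rng.normal(0.0, noise, pts.shape)
    corr = HandCorrespondences(idx, pts)
    truth = {"joints": true_placement.apply(joints),
             "vertices": true_placement.apply(mesh.vertices)}
    return corr, truth
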