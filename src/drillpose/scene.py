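"""Egocentric scene sampling, visibility filtering, patch extraction, and
dataset assembly.

The generator emulates the study conditions of a surgeon-held power drill
viewed from the operator's head: the virtual camera sits on the (augmented)
head position, looks at the (augmented) hand position, and is slid along its
optical axis until the camera-to-drill distance matches a draw from
U(0.30, 0.50) m. Samples failing the visibility rules (fewer than 100 hand
or tool pixels, or less than 40 % of the tool visible) are rejected and
resampled; accepted renders are cropped to 256x256 patches around the
jittered 2D bounding-box center of the tool, and patches showing fewer than
40 % of the tool's projected vertices are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fixtures import ToyAssets
from .geometry import CameraIntrinsics, RigidTransform, project_points
from .grasps import Grasp, augment_grasps
from .handmodel import synthesize_hand
from .keypoints import define_keypoints
from .rendering import (LABEL_BODY_HAND, LABEL_TOOL, LabelMasks, SceneObject,
                        render_scene)

__all__ = ["ScenePlacement", "SyntheticSample", "GenerationConfig",
           "sample_camera_pose", "visibility_filter", "crop_patch",
           "generate_dataset", "GenerationReport"]

_WORLD_UP = np.array([0.0, 0.0, 1.0])
_FALLBACK_UP = np.array([0.0, 1.0, 0.0])


@dataclass(frozen=True)
class ScenePlacement:
    head_position: np.ndarray
    hand_position: np.ndarray
    tool_pose: RigidTransform          # tool -> world
    camera_pose: RigidTransform        # world -> camera
    distance: float                    # camera center to tool center (m)


@dataclass
class SyntheticSample:
    """One generated 256x256 training sample with its full ground truth."""
    image: np.ndarray                  # (H, W, 3) uint8
    masks: LabelMasks                  # cropped to the patch
    tool_pose: RigidTransform          # tool -> camera
    hand_joints: np.ndarray            # (21, 3) camera frame, meters
    keypoints_2d: np.ndarray           # (9, 2) patch pixels
    keypoints_3d: np.ndarray           # (9, 3) tool frame, meters
    patch_intrinsics: CameraIntrinsics
    grasp_id: int
    template_id: int


def _look_at_rotation(eye: np.ndarray, target: np.ndarray) -> np.ndarray:
    """World->camera rotation for a camera at ``eye`` looking at ``target``
    (x right, y down, z forward). Falls back to a fixed alternative up-vector
    when the view direction is parallel to the world up."""
    z = target - eye
    nz = np.linalg.norm(z)
    if nz < 1e-12:
        raise ValueError("eye and target coincide")
    z = z / nz
    up = _WORLD_UP
    x = np.cross(z, up)
    if np.linalg.norm(x) < 1e-8:
        x = np.cross(z, _FALLBACK_UP)
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    return np.vstack([x, y, z])        # rows = camera axes in world coords


def sample_camera_pose(head: np.ndarray, hand: np.ndarray,
                       tool_center: np.ndarray, rng: np.random.Generator,
                       tool_pose: RigidTransform = None,
                       head_noise: float = 0.1, hand_noise: float = 0.02,
                       distance_range: tuple = (0.30, 0.50)) -> ScenePlacement:
    """Sample an egocentric camera: perturb head and hand positions with
    uniform noise, aim the camera from the head at the hand, then slide it
    along its optical axis until the camera-drill distance matches a uniform
    draw from ``distance_range``.

    Raises when the requested distance cannot be reached because the tool
    center lies farther from the viewing ray than the sampled distance.
    """
    head = np.asarray(head, float) + rng.uniform(-head_noise, head_noise, 3)
    hand = np.asarray(hand, float) + rng.uniform(-hand_noise, hand_noise, 3)
    if np.linalg.norm(hand - head) < 1e-9:
        raise ValueError("head and hand positions coincide")
    R = _look_at_rotation(head, hand)
    z_world = R[2]
    d = rng.uniform(*distance_range)
    p = np.asarray(tool_center, float) - head
    along = p @ z_world
    lateral_sq = p @ p - along ** 2
    if lateral_sq > d ** 2:
        raise ValueError("tool lies farther from the viewing ray than the "
                         "sampled camera distance")
    s = along - np.sqrt(d ** 2 - lateral_sq)
    eye = head + z_world * s
    camera_pose = RigidTransform(R, -R @ eye)
    if tool_pose is None:
        tool_pose = RigidTransform.identity()
    return ScenePlacement(head, hand, tool_pose, camera_pose, float(d))


def visibility_filter(masks: LabelMasks, min_pixels: int = 100,
                      min_visible_fraction: float = 0.40):
    """Accept/reject a rendering on the paper's visibility rules.

    Rejects when fewer than ``min_pixels`` pixels belong to the hand or to
    the tool, or when the visible-tool fraction (tool pixels over
    unoccluded-tool pixels) is below ``min_visible_fraction``.
    Returns ``(accept, reason)`` with ``reason`` naming the failed rule.
    """
    unoccluded = int(masks.unoccluded_tool.sum())
    if unoccluded == 0:
        return False, "tool out of view"
    hand_px = int(masks.hand_mask.sum())
    if hand_px < min_pixels:
        return False, f"hand pixels {hand_px} < {min_pixels}"
    tool_px = int(masks.tool_mask.sum())
    if tool_px < min_pixels:
        return False, f"tool pixels {tool_px} < {min_pixels}"
    frac = tool_px / unoccluded
    if frac < min_visible_fraction:
        return False, (f"visible tool fraction {frac:.3f} < "
                       f"{min_visible_fraction}")
    return True, "ok"


def _resize_nearest(arr: np.ndarray, scale: float) -> np.ndarray:
    h, w = arr.shape[:2]
    nh, nw = int(round(h * scale)), int(round(w * scale))
    yi = np.clip(np.round(np.arange(nh) / scale).astype(int), 0, h - 1)
    xi = np.clip(np.round(np.arange(nw) / scale).astype(int), 0, w - 1)
    return arr[np.ix_(yi, xi)]


def crop_patch(image: np.ndarray, masks: LabelMasks, tool_uv: np.ndarray,
               intr: CameraIntrinsics, rng: np.random.Generator,
               patch_size: int = 256, jitter_radius: float = 64.0,
               target_focal: float = None,
               min_vertex_fraction: float = 0.40):
    """Extract a focal-normalized, jittered patch around the tool.

    The image is conceptually rescaled by ``target_focal / intr.focal``
    before cropping (identity when focal lengths already agree); the crop
    center is the tool's 2D bounding-box center displaced by a uniform
    random direction and radius up to ``jitter_radius`` pixels. Returns
    ``(patch_image, patch_masks, patch_intrinsics, uv_transform)`` or
    ``(None, None, None, reason)`` when fewer than ``min_vertex_fraction``
    of the projected tool vertices land inside the patch. ``uv_transform``
    maps full-image pixel coordinates to patch coordinates.
    """
    tool_uv = np.asarray(tool_uv, float)
    if len(tool_uv) == 0:
        raise ValueError("tool has no projected vertices")
    scale = 1.0 if target_focal is None else target_focal / intr.focal
    if scale != 1.0:
        image = _resize_nearest(image, scale)
        masks = LabelMasks(_resize_nearest(masks.labels, scale),
                           _resize_nearest(masks.unoccluded_tool, scale))
        tool_uv = tool_uv * scale

    bbox_center = 0.5 * (tool_uv.min(axis=0) + tool_uv.max(axis=0))
    r = rng.uniform(0.0, jitter_radius)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    center = bbox_center + r * np.array([np.cos(phi), np.sin(phi)])
    # integer patch origin keeps pixel centers aligned between crop and source
    origin = np.round(center).astype(int) - patch_size // 2

    inside = np.all((tool_uv >= origin) & (tool_uv <= origin + patch_size - 1),
                    axis=1)
    frac = inside.mean()
    if frac < min_vertex_fraction:
        return None, None, None, (f"projected-vertex fraction {frac:.3f} < "
                                  f"{min_vertex_fraction}")

    H, W = masks.labels.shape
    patch_img = np.zeros((patch_size, patch_size) + image.shape[2:],
                         dtype=image.dtype)
    patch_labels = np.zeros((patch_size, patch_size), dtype=masks.labels.dtype)
    patch_unocc = np.zeros((patch_size, patch_size), dtype=bool)
    x0, y0 = origin
    sx0, sx1 = max(x0, 0), min(x0 + patch_size, W)
    sy0, sy1 = max(y0, 0), min(y0 + patch_size, H)
    if sx0 < sx1 and sy0 < sy1:
        patch_img[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = image[sy0:sy1, sx0:sx1]
        patch_labels[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = \
            masks.labels[sy0:sy1, sx0:sx1]
        patch_unocc[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = \
            masks.unoccluded_tool[sy0:sy1, sx0:sx1]

    patch_intr = CameraIntrinsics(
        intr.focal * scale, intr.principal_point * scale - origin,
        (patch_size, patch_size))

    def uv_transform(uv):
        return np.asarray(uv, float) * scale - origin

    return patch_img, LabelMasks(patch_labels, patch_unocc), patch_intr, \
        uv_transform


@dataclass
class GenerationConfig:
    """Study-condition defaults of the synthetic pipeline."""
    n_samples: int = 50
    n_augmented_grasps: int = 210
    sigma_pose: float = 0.01
    sigma_shape: float = 0.05
    render_size: int = 512
    focal: float = 420.0
    patch_size: int = 256
    jitter_radius: float = 64.0
    head_offset: tuple = (0.0, -0.32, 0.28)     # nominal head relative to tool
    head_noise: float = 0.1
    hand_noise: float = 0.02
    distance_range: tuple = (0.30, 0.50)
    min_mask_pixels: int = 100
    min_visible_fraction: float = 0.40
    min_vertex_fraction: float = 0.40
    max_attempts_per_sample: int = 40
    min_acceptance_rate: float = 0.02


@dataclass
class GenerationReport:
    attempted: int = 0
    emitted: int = 0
    rejections: dict = field(default_factory=dict)

    def reject(self, reason: str) -> None:
        key = reason.split("<")[0].strip() if "<" in reason else reason
        self.rejections[key] = self.rejections.get(key, 0) + 1

    @property
    def rejected(self) -> int:
        return sum(self.rejections.values())


def _attempt_sample(assets: ToyAssets, grasps: list, grasp_id: int,
                    kp3d: np.ndarray, config: GenerationConfig,
                    rng: np.random.Generator, report: GenerationReport):
    grasp = grasps[grasp_id]
    intr = CameraIntrinsics.centered(config.focal,
                                     (config.render_size, config.render_size))
    # tool placed at the world origin in a random attitude
    tool_pose_w = RigidTransform(
        RigidTransform.random(rng, max_translation=0.0).rotation, np.zeros(3))

    hand_mesh, joints = synthesize_hand(assets.hand_assets, grasp.hand_pose)
    hand_to_world = tool_pose_w @ grasp.hand_to_tool
    hand_world = hand_to_world.apply(hand_mesh.vertices)
    joints_world = hand_to_world.apply(joints)

    head = tool_pose_w.translation + np.asarray(config.head_offset, float)
    hand_center = joints_world.mean(axis=0)
    try:
        placement = sample_camera_pose(
            head, hand_center, tool_pose_w.translation, rng,
            tool_pose=tool_pose_w, head_noise=config.head_noise,
            hand_noise=config.hand_noise,
            distance_range=config.distance_range)
    except ValueError as e:
        report.reject(f"camera sampling: {e}")
        return None

    cam = placement.camera_pose
    objects = [
        SceneObject(hand_world, assets.hand_assets.faces, LABEL_BODY_HAND),
        SceneObject(hand_to_world.apply(assets.body_proxy.vertices),
                    assets.body_proxy.faces, LABEL_BODY_HAND),
    ]
    tool_obj = SceneObject(tool_pose_w.apply(assets.tool.vertices),
                           assets.tool.faces, LABEL_TOOL)
    image, labels, _ = render_scene(objects + [tool_obj], cam, intr)
    _, tool_only, _ = render_scene([tool_obj], cam, intr)
    masks = LabelMasks(labels, tool_only == LABEL_TOOL)

    ok, reason = visibility_filter(masks, config.min_mask_pixels,
                                   config.min_visible_fraction)
    if not ok:
        report.reject(reason)
        return None

    tool_cam_pose = cam @ tool_pose_w
    verts_cam = tool_cam_pose.apply(assets.tool.vertices)
    if np.any(verts_cam[:, 2] <= 0):
        report.reject("tool behind camera")
        return None
    tool_uv = project_points(verts_cam, intr)
    patch_img, patch_masks, patch_intr, uv_tf = crop_patch(
        image, masks, tool_uv, intr, rng, config.patch_size,
        config.jitter_radius, min_vertex_fraction=config.min_vertex_fraction)
    if patch_img is None:
        report.reject(uv_tf)
        return None

    kp_cam = tool_cam_pose.apply(kp3d)
    keypoints_2d = project_points(kp_cam, patch_intr)
    hand_joints_cam = cam.apply(joints_world)
    return SyntheticSample(patch_img, patch_masks, tool_cam_pose,
                           hand_joints_cam, keypoints_2d, kp3d, patch_intr,
                           grasp_id, grasp.template_id)


def generate_dataset(assets: ToyAssets, templates: list,
                     config: GenerationConfig = GenerationConfig(),
                     seed: int = 0):
    """Run the full synthetic pipeline: augment grasps, then per sample
    draw grasp -> place tool and hand -> sample camera -> render -> apply
    visibility filters -> crop patch; rejected draws are resampled and
    counted. Bit-reproducible for a fixed seed.

    Returns ``(samples, report)``. Raises when the acceptance rate falls
    below the configured floor, reporting the rejection breakdown.
    """
    rng = np.random.default_rng(seed)
    grasps = augment_grasps(templates, config.n_augmented_grasps,
                            config.sigma_pose, config.sigma_shape, rng)
    kp3d = define_keypoints(assets.tool).points
    report = GenerationReport()
    samples = []
    max_attempts = config.n_samples * config.max_attempts_per_sample
    while len(samples) < config.n_samples:
        if report.attempted >= max_attempts:
            raise RuntimeError(
                f"acceptance rate {len(samples) / max(report.attempted, 1):.3f}"
                f" below floor after {report.attempted} attempts; rejections: "
                f"{report.rejections}")
        report.attempted += 1
        grasp_id = int(rng.integers(len(grasps)))
        sample = _attempt_sample(assets, grasps, grasp_id, kp3d, config,
                                 rng, report)
        if sample is not None:
            samples.append(sample)
            report.emitted += 1
    return samples, report
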