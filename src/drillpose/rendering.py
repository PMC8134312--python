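"""Flat-shaded z-buffer rasterization of labeled triangle meshes.

A small software renderer sufficient for label-consistent synthetic data:
per-pixel nearest-surface label masks and a Lambertian flat-shaded image.
No lighting models beyond a single directional light, no textures, no
anti-aliasing — the geometric contract (which surface wins each pixel) is
the tested behavior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CameraIntrinsics, RigidTransform, project_points

__all__ = ["LabelMasks", "SceneObject", "render_scene", "render_label_masks",
           "LABEL_BACKGROUND", "LABEL_BODY_HAND", "LABEL_TOOL"]

LABEL_BACKGROUND = 0
LABEL_BODY_HAND = 1
LABEL_TOOL = 2

_LABEL_COLORS = {
    LABEL_BODY_HAND: np.array([205, 170, 140], float),   # skin-ish
    LABEL_TOOL: np.array([90, 110, 200], float),          # tool blue
}
_NEAR_PLANE = 1e-3
_LIGHT_DIR = np.array([0.3, -0.5, 0.8])
_LIGHT_DIR = _LIGHT_DIR / np.linalg.norm(_LIGHT_DIR)


@dataclass
class LabelMasks:
    """Per-pixel labels {0 background, 1 body+hand, 2 tool} and the binary
    mask of the tool rendered alone (no occluders)."""

    labels: np.ndarray
    unoccluded_tool: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.unoccluded_tool = np.asarray(self.unoccluded_tool).astype(bool)
        if self.labels.shape != self.unoccluded_tool.shape:
            raise ValueError("mask shape mismatch")

    @property
    def tool_mask(self) -> np.ndarray:
        return self.labels == LABEL_TOOL

    @property
    def hand_mask(self) -> np.ndarray:
        return self.labels == LABEL_BODY_HAND


@dataclass
class SceneObject:
    """World-frame triangle geometry carrying a semantic label."""
    vertices: np.ndarray      # (V, 3) world meters
    faces: np.ndarray         # (F, 3)
    label: int

    def transformed(self, T: RigidTransform) -> "SceneObject":
        return SceneObject(T.apply(self.vertices), self.faces, self.label)


def _rasterize(verts_cam: np.ndarray, faces: np.ndarray, intr: CameraIntrinsics,
               depth: np.ndarray, label_buf: np.ndarray, shade_buf: np.ndarray,
               label: int) -> None:
    """Rasterize one mesh into the shared z/label/shading buffers.

    Perspective-correct depth via screen-space linear interpolation of 1/z.
    Faces with any vertex behind the near plane are skipped (no clipping);
    scenes in this package keep their geometry in front of the camera.
    """
    W, H = intr.image_size
    ok = np.all(verts_cam[faces][:, :, 2] > _NEAR_PLANE, axis=1)
    faces = faces[ok]
    if len(faces) == 0:
        return
    uv = (verts_cam[:, :2] / verts_cam[:, 2:3]) * intr.focal + intr.principal_point
    inv_z = 1.0 / verts_cam[:, 2]

    tri_uv = uv[faces]            # (F, 3, 2)
    tri_iz = inv_z[faces]         # (F, 3)

    # flat shading from the camera-frame face normal
    t3 = verts_cam[faces]
    n = np.cross(t3[:, 1] - t3[:, 0], t3[:, 2] - t3[:, 0])
    nn = np.linalg.norm(n, axis=1)
    nn[nn == 0] = 1.0
    n = n / nn[:, None]
    lam = np.abs(n @ _LIGHT_DIR)
    intensity = 0.35 + 0.65 * lam

    for f in range(len(faces)):
        (x0, y0), (x1, y1), (x2, y2) = tri_uv[f]
        area = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
        if area == 0:
            continue
        xmin = max(int(np.ceil(min(x0, x1, x2))), 0)
        xmax = min(int(np.floor(max(x0, x1, x2))), W - 1)
        ymin = max(int(np.ceil(min(y0, y1, y2))), 0)
        ymax = min(int(np.floor(max(y0, y1, y2))), H - 1)
        if xmin > xmax or ymin > ymax:
            continue
        xs = np.arange(xmin, xmax + 1)
        ys = np.arange(ymin, ymax + 1)
        gx, gy = np.meshgrid(xs, ys)
        w0 = ((x1 - x0) * (gy - y0) - (gx - x0) * (y1 - y0)) / area
        w1 = ((gx - x0) * (y2 - y0) - (x2 - x0) * (gy - y0)) / area
        # inside test inclusive of edges; ties between abutting faces are
        # resolved by the z-buffer
        inside = (w0 >= 0) & (w1 >= 0) & (w0 + w1 <= 1)
        if not inside.any():
            continue
        iz = (tri_iz[f, 0] * (1 - w0 - w1) + tri_iz[f, 1] * w1
              + tri_iz[f, 2] * w0)
        z = 1.0 / iz
        yy, xx = gy[inside], gx[inside]
        zz = z[inside]
        closer = zz < depth[yy, xx]
        yy, xx, zz = yy[closer], xx[closer], zz[closer]
        depth[yy, xx] = zz
        label_buf[yy, xx] = label
        shade_buf[yy, xx] = intensity[f]


def render_scene(objects: list, camera_pose: RigidTransform,
                 intr: CameraIntrinsics):
    """Render world-frame objects seen by ``camera_pose`` (world -> camera).

    Returns ``(image, labels, depth)``: an RGB uint8 flat-shaded image, the
    per-pixel semantic label map, and the depth buffer (inf on background).
    """
    W, H = intr.image_size
    depth = np.full((H, W), np.inf)
    labels = np.zeros((H, W), dtype=np.uint8)
    shade = np.zeros((H, W))
    for obj in objects:
        verts_cam = camera_pose.apply(obj.vertices)
        _rasterize(verts_cam, np.asarray(obj.faces, int), intr,
                   depth, labels, shade, obj.label)
    image = np.zeros((H, W, 3), dtype=np.uint8)
    for lab, color in _LABEL_COLORS.items():
        sel = labels == lab
        image[sel] = np.clip(color * shade[sel, None], 0, 255).astype(np.uint8)
    return image, labels, depth


def render_label_masks(body_hand_objects: list, tool_object: SceneObject,
                       camera_pose: RigidTransform,
                       intr: CameraIntrinsics) -> LabelMasks:
    """Label masks of the full scene plus the tool rendered alone.

    The unoccluded-tool mask is the denominator of the visibility ratio:
    what the tool would cover had nothing occluded it.
    """
    _, labels, _ = render_scene(list(body_hand_objects) + [tool_object],
                                camera_pose, intr)
    _, tool_only, _ = render_scene([tool_object], camera_pose, intr)
    return LabelMasks(labels, tool_only == LABEL_TOOL)
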