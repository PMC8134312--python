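"""Grasp templates, Gaussian grasp augmentation, and plausibility checks.

A grasp is a hand configuration plus a rigid placement of the hand in the
tool's coordinate frame. Template grasps are authored (here: constructed
programmatically against the tool surface); dataset diversity comes from
resampling templates with Gaussian noise on the PCA pose coefficients
(sigma = 0.01) and shape coefficients (sigma = 0.05).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .geometry import (RigidTransform, ToolMesh, signed_distance,
                       _closest_point_distance)
from .handmodel import (HandModelAssets, HandPose, synthesize_hand,
                        N_JOINTS, N_REPORTED_JOINTS)

__all__ = ["Grasp", "augment_grasps", "check_grasp_plausibility",
           "PlausibilityLimits", "author_grasp_template",
           "save_grasp_templates", "load_grasp_templates",
           "SIGMA_POSE", "SIGMA_SHAPE"]

SIGMA_POSE = 0.01
SIGMA_SHAPE = 0.05


@dataclass(frozen=True)
class Grasp:
    template_id: int
    hand_pose: HandPose
    hand_to_tool: RigidTransform
    plausible: bool = True

    def to_dict(self) -> dict:
        return {"template_id": int(self.template_id),
                "global_rot": self.hand_pose.global_rot.tolist(),
                "pca_coeffs": self.hand_pose.pca_coeffs.tolist(),
                "shape_coeffs": self.hand_pose.shape_coeffs.tolist(),
                "hand_to_tool": self.hand_to_tool.as_matrix().tolist(),
                "plausible": bool(self.plausible)}

    @classmethod
    def from_dict(cls, d: dict) -> "Grasp":
        return cls(d["template_id"],
                   HandPose(d["global_rot"], d["pca_coeffs"], d["shape_coeffs"]),
                   RigidTransform.from_matrix(np.asarray(d["hand_to_tool"])),
                   d.get("plausible", True))


def augment_grasps(templates: list, n: int, sigma_pose: float = SIGMA_POSE,
                   sigma_shape: float = SIGMA_SHAPE,
                   seed: int | np.random.Generator = 0) -> list:
    """Draw ``n`` augmented grasps by resampling templates uniformly and
    perturbing PCA pose and shape coefficients with i.i.d. Gaussian noise.

    The placement (``hand_to_tool``) and global rotation belong to the
    template and are copied unchanged. Deterministic under a fixed seed.
    """
    if not templates:
        raise ValueError("need at least one grasp template")
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma_pose < 0 or sigma_shape < 0:
        raise ValueError("sigmas must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    out = []
    for _ in range(n):
        tpl = templates[rng.integers(len(templates))]
        pose = HandPose(
            tpl.hand_pose.global_rot,
            tpl.hand_pose.pca_coeffs + rng.normal(0.0, sigma_pose, 15)
            if sigma_pose > 0 else tpl.hand_pose.pca_coeffs,
            tpl.hand_pose.shape_coeffs + rng.normal(0.0, sigma_shape, 10)
            if sigma_shape > 0 else tpl.hand_pose.shape_coeffs)
        out.append(replace(tpl, hand_pose=pose))
    return out


@dataclass(frozen=True)
class PlausibilityLimits:
    """Thresholds for the physical/biomechanical grasp checks."""
    joint_angle_limit: float = np.pi / 2    # rad, per axis-angle component
    penetration_tolerance: float = 0.005    # m, max hand-vertex penetration
    contact_distance: float = 0.005         # m, fingertip-to-surface
    min_fingertips_in_contact: int = 2


def check_grasp_plausibility(grasp: Grasp, tool_mesh: ToolMesh,
                             assets: HandModelAssets,
                             limits: PlausibilityLimits = PlausibilityLimits()):
    """Physical/biomechanical screen of a grasp against the tool surface.

    A grasp passes when (a) every implied per-joint axis-angle component is
    within the anatomical limit, (b) no hand vertex penetrates the tool
    deeper than the tolerance, and (c) at least the required number of
    fingertip sites lies within contact distance of the tool surface.
    Returns ``(flag, diagnostics)`` with per-check details.
    """
    tm = tool_mesh.as_trimesh()
    if not tm.is_watertight:
        raise ValueError("tool mesh must be watertight for penetration checks")

    angles = (grasp.hand_pose.pca_coeffs @ assets.pose_basis)
    angles_ok = bool(np.all(np.abs(angles) <= limits.joint_angle_limit))

    hand_mesh, joints = synthesize_hand(assets, grasp.hand_pose)
    verts_tool = grasp.hand_to_tool.apply(hand_mesh.vertices)
    sd = signed_distance(tm, verts_tool)
    penetration = float(max(sd.max(), 0.0))
    penetration_ok = penetration <= limits.penetration_tolerance

    tips_tool = grasp.hand_to_tool.apply(joints[N_JOINTS:N_REPORTED_JOINTS])
    tip_dist = _closest_point_distance(tm, tips_tool)
    n_contact = int(np.sum(tip_dist <= limits.contact_distance))
    contact_ok = n_contact >= limits.min_fingertips_in_contact

    flag = angles_ok and penetration_ok and contact_ok
    diagnostics = {
        "joint_angles_ok": angles_ok,
        "max_abs_joint_angle": float(np.abs(angles).max()),
        "penetration_ok": penetration_ok,
        "max_penetration": penetration,
        "contact_ok": contact_ok,
        "fingertips_in_contact": n_contact,
        "fingertip_distances": tip_dist.tolist(),
    }
    return flag, diagnostics


def author_grasp_template(template_id: int, assets: HandModelAssets,
                          tool_mesh: ToolMesh, site_point: np.ndarray,
                          site_axis: np.ndarray, approach: np.ndarray,
                          pca_coeffs: np.ndarray | None = None,
                          along_offset: float = -0.055,
                          limits: PlausibilityLimits = PlausibilityLimits()) -> Grasp:
    """Construct a plausible grasp by sliding the hand toward a grasp site.

    The hand is oriented with its fingers along ``site_axis`` and its palm
    normal facing the surface along ``approach`` (a unit vector pointing
    from free space toward the site). Starting clear of the surface, the
    wrist is advanced along the approach in 0.5 mm steps; the placement
    maximizing fingertip contacts subject to the penetration tolerance is
    kept. Raises if no placement passes the plausibility screen.
    """
    a = np.asarray(approach, float)
    a = a / np.linalg.norm(a)
    h = np.asarray(site_axis, float)
    h = h - a * (a @ h)
    h = h / np.linalg.norm(h)
    x = np.cross(h, a)
    # hand axes in the tool frame: x = palm width, y = fingers, z = palm normal
    R = np.column_stack([x, h, a])
    pose = HandPose(pca_coeffs=np.zeros(15) if pca_coeffs is None
                    else pca_coeffs)

    angles = pose.pca_coeffs @ assets.pose_basis
    if np.abs(angles).max() > limits.joint_angle_limit:
        raise ValueError("requested finger curl exceeds the joint-angle limit")
    # hand geometry is pose-constant across the slide: synthesize once
    hand_mesh, joints = synthesize_hand(assets, pose)
    tm = tool_mesh.as_trimesh()
    if not tm.is_watertight:
        raise ValueError("tool mesh must be watertight")

    def evaluate(s):
        wrist = (np.asarray(site_point, float) - a * (0.020 - s)
                 + h * along_offset)
        T = RigidTransform(R, wrist)
        sd = signed_distance(tm, T.apply(hand_mesh.vertices))
        pen = float(max(sd.max(), 0.0))
        tip_dist = _closest_point_distance(
            tm, T.apply(joints[N_JOINTS:N_REPORTED_JOINTS]))
        n_contact = int(np.sum(tip_dist <= limits.contact_distance))
        return T, pen, n_contact

    def best_over(offsets, best=None):
        for s in offsets:
            T, pen, n_contact = evaluate(s)
            if pen <= limits.penetration_tolerance:
                score = (n_contact, -pen)
                if best is None or score > best[0]:
                    best = (score, T, s)
        return best

    best = best_over(np.arange(-0.040, 0.021, 0.002))
    if best is not None:
        s0 = best[2]
        best = best_over(np.arange(s0 - 0.002, s0 + 0.0021, 0.00025), best)
    if best is None or best[0][0] < limits.min_fingertips_in_contact:
        raise ValueError(f"could not author a plausible grasp at site "
                         f"{np.asarray(site_point).round(3).tolist()}")
    return Grasp(template_id, pose, best[1], plausible=True)


def save_grasp_templates(grasps: list, path) -> None:
    Path(path).write_text(json.dumps([g.to_dict() for g in grasps], indent=1))


def load_grasp_templates(path) -> list:
    return [Grasp.from_dict(d) for d in json.loads(Path(path).read_text())]
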