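"""Toy scene assets: a drill-shaped tool mesh with tip/bit-axis landmarks, a
forearm proxy standing in for the rendered body, a backdrop, and the seven
programmatically authored grasp templates for that tool.

These assets are synthetic stand-ins generated deterministically in code:
the drill emulates a hand-held surgical power drill (body cylinder, pistol
grip, thin bit) at realistic dimensions, and grasp templates are wrap grasps
around the grip authored by the contact/penetration search in
:mod:`drillpose.grasps`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import trimesh

from .geometry import ToolMesh
from .grasps import Grasp, PlausibilityLimits, author_grasp_template
from .handmodel import HandModelAssets, build_standin_assets

__all__ = ["ToyAssetParams", "ToyAssets", "make_toy_assets",
           "toy_grasp_templates", "default_toy_assets"]


@dataclass(frozen=True)
class ToyAssetParams:
    """Dimensions of the synthetic drill (meters)."""
    body_radius: float = 0.025
    body_length: float = 0.18
    bit_radius: float = 0.004
    bit_length: float = 0.10
    grip_radius: float = 0.020
    grip_length: float = 0.11
    grip_offset_x: float = -0.030   # grip position along the body
    sections: int = 24

    def validate(self):
        vals = [self.body_radius, self.body_length, self.bit_radius,
                self.bit_length, self.grip_radius, self.grip_length]
        if any(v <= 0 for v in vals):
            raise ValueError("all drill dimensions must be positive")
        if self.bit_radius >= self.body_radius:
            raise ValueError("bit must be thinner than the body")


@dataclass
class ToyAssets:
    tool: ToolMesh
    body_proxy: ToolMesh          # forearm proxy, in the hand frame
    backdrop: ToolMesh            # large quad, positioned per scene
    hand_assets: HandModelAssets
    grip_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    grip_axis: np.ndarray = field(default_factory=lambda: np.array([0., 0., -1.]))
    grip_radius: float = 0.020


def _capped_cylinder(radius, p0, p1, sections):
    return trimesh.creation.cylinder(radius=radius, segment=[p0, p1],
                                     sections=sections)


def make_toy_assets(params: ToyAssetParams = ToyAssetParams(),
                    rng: np.random.Generator | None = None) -> ToyAssets:
    """Build the synthetic drill (bit along +x, tip at the bit end, pistol
    grip along -z), a forearm proxy, and a backdrop quad.

    The tool mesh is a union of closed cylinders and is watertight in the
    every-edge-shared-by-two-faces sense required by the signed-distance
    queries. Deterministic for fixed parameters.
    """
    params.validate()
    s = params.sections
    half = params.body_length / 2.0
    body = _capped_cylinder(params.body_radius, [-half, 0, 0], [half, 0, 0], s)
    bit = _capped_cylinder(params.bit_radius, [half, 0, 0],
                           [half + params.bit_length, 0, 0], max(s // 2, 8))
    gx = params.grip_offset_x
    grip = _capped_cylinder(params.grip_radius, [gx, 0, -0.015],
                            [gx, 0, -0.015 - params.grip_length], s)
    tool_tm = trimesh.util.concatenate([body, bit, grip])
    tip = np.array([half + params.bit_length, 0.0, 0.0])
    tool = ToolMesh(np.asarray(tool_tm.vertices), np.asarray(tool_tm.faces),
                    landmarks={"tip": tip},
                    axes={"bit_axis": np.array([1.0, 0.0, 0.0])})

    # forearm proxy in the hand frame: fingers point along +y, so the arm
    # extends from the wrist along -y
    arm = _capped_cylinder(0.045, [0, 0.005, 0.005], [0, -0.45, 0.06], 12)
    body_proxy = ToolMesh(np.asarray(arm.vertices), np.asarray(arm.faces))

    quad_v = np.array([[-1.5, -1.5, 0], [1.5, -1.5, 0],
                       [1.5, 1.5, 0], [-1.5, 1.5, 0]], float)
    quad_f = np.array([[0, 1, 2], [0, 2, 3]])
    backdrop = ToolMesh(quad_v, quad_f)

    grip_center = np.array([gx, 0.0, -0.015 - params.grip_length / 2.0])
    return ToyAssets(tool, body_proxy, backdrop, build_standin_assets(),
                     grip_center=grip_center,
                     grip_axis=np.array([0.0, 0.0, -1.0]),
                     grip_radius=params.grip_radius)


def toy_grasp_templates(assets: ToyAssets, n_templates: int = 7,
                        limits: PlausibilityLimits = PlausibilityLimits()) -> list:
    """Author ``n_templates`` wrap grasps around the drill grip.

    Templates differ in approach azimuth around the grip, height along it,
    and finger-curl magnitude; each is slid into contact until it passes the
    plausibility screen. Deterministic.
    """
    axis = assets.grip_axis / np.linalg.norm(assets.grip_axis)
    # a pair of unit vectors orthogonal to the grip axis
    e1 = np.array([1.0, 0.0, 0.0])
    e1 = e1 - axis * (axis @ e1)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    templates = []
    azimuths = np.linspace(0.0, 2 * np.pi, n_templates, endpoint=False)
    # heights move the hand down the grip (axis points downward); upward
    # shifts would push the curled thumb into the grip cylinder
    heights = [0.0, 0.008, 0.004, 0.012, 0.002, 0.01, 0.006]
    curls = [1.7, 1.75, 1.65, 1.8, 1.7, 1.6, 1.75]
    for tid in range(n_templates):
        phi = azimuths[tid]
        radial = np.cos(phi) * e1 + np.sin(phi) * e2
        site = (assets.grip_center + axis * heights[tid % len(heights)]
                + radial * assets.grip_radius)
        approach = -radial
        pca = np.zeros(15)
        pca[:5] = curls[tid % len(curls)]
        pca[0] *= 0.6        # the thumb curls less than the fingers
        grasp = None
        for scale in (1.0, 0.95, 1.05, 0.9, 1.1):
            try:
                grasp = author_grasp_template(
                    tid, assets.hand_assets, assets.tool, site,
                    site_axis=np.cross(axis, approach), approach=approach,
                    pca_coeffs=pca * scale, limits=limits)
                break
            except ValueError:
                continue
        if grasp is None:
            raise ValueError(f"failed to author grasp template {tid}")
        templates.append(grasp)
    return templates


@lru_cache(maxsize=2)
def default_toy_assets(with_templates: bool = True):
    """Cached default assets and their grasp templates."""
    assets = make_toy_assets()
    templates = toy_grasp_templates(assets) if with_templates else []
    return assets, templates
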