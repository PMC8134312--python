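"""On-disk formats: schema-versioned JSON label records, PNG images and
label masks, vector-field archives, recording manifests, and run
configuration.

One JSON dialect covers all labels; masks are 8-bit PNGs with the literal
label values {0, 1, 2}; dense arrays (vector fields, hand assets) go into
compressed named-array containers (npz).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .geometry import CameraIntrinsics, RigidTransform
from .keypoints import VectorField
from .rendering import LabelMasks

__all__ = ["LabelRecord", "RunConfig", "write_labels", "read_labels",
           "save_mask_png", "load_mask_png", "save_image_png",
           "load_image_png", "save_vector_field", "load_vector_field",
           "write_dataset", "read_sample_record"]

SCHEMA_VERSION = "drillpose-labels-v1"


@dataclass
class LabelRecord:
    """One labeled frame: tool pose (camera frame), optional hand pose,
    joints, 2D keypoints, intrinsics, and a tracking status."""
    frame_id: int
    tool_pose: np.ndarray                      # 4x4 row-major, meters
    intrinsics: CameraIntrinsics
    hand_pose: np.ndarray | None = None
    hand_joints: np.ndarray | None = None      # (21, 3)
    keypoints_2d: np.ndarray | None = None     # (9, 2)
    status: str = "ok"

    def __post_init__(self):
        self.tool_pose = _validate_pose_block(self.tool_pose, "tool_pose")
        if self.hand_pose is not None:
            self.hand_pose = _validate_pose_block(self.hand_pose, "hand_pose")
        if self.hand_joints is not None:
            self.hand_joints = np.asarray(self.hand_joints, float).reshape(21, 3)
        if self.keypoints_2d is not None:
            self.keypoints_2d = np.asarray(self.keypoints_2d, float).reshape(9, 2)

    def to_dict(self) -> dict:
        d = {"frame_id": int(self.frame_id),
             "tool_pose": self.tool_pose.tolist(),
             "intrinsics": self.intrinsics.to_dict(),
             "status": self.status}
        if self.hand_pose is not None:
            d["hand_pose"] = self.hand_pose.tolist()
        if self.hand_joints is not None:
            d["hand_joints"] = self.hand_joints.tolist()
        if self.keypoints_2d is not None:
            d["keypoints_2d"] = self.keypoints_2d.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LabelRecord":
        for req in ("frame_id", "tool_pose", "intrinsics"):
            if req not in d:
                raise ValueError(f"label record missing field {req!r}")
        return cls(d["frame_id"], np.asarray(d["tool_pose"]),
                   CameraIntrinsics.from_dict(d["intrinsics"]),
                   np.asarray(d["hand_pose"]) if "hand_pose" in d else None,
                   np.asarray(d["hand_joints"]) if "hand_joints" in d else None,
                   np.asarray(d["keypoints_2d"]) if "keypoints_2d" in d else None,
                   d.get("status", "ok"))


def _validate_pose_block(H, name: str) -> np.ndarray:
    H = np.asarray(H, float)
    if H.shape != (4, 4):
        raise ValueError(f"{name} must be a 4x4 matrix")
    RigidTransform.from_matrix(H)   # raises on invalid rotation blocks
    return H


def write_labels(path, records: list) -> None:
    doc = {"schema": SCHEMA_VERSION,
           "records": [r.to_dict() for r in records]}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_labels(path) -> list:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != SCHEMA_VERSION:
        raise ValueError(f"unsupported label schema {doc.get('schema')!r}")
    return [LabelRecord.from_dict(d) for d in doc["records"]]


def save_mask_png(path, labels: np.ndarray) -> None:
    Image.fromarray(np.asarray(labels, dtype=np.uint8), mode="L").save(path)


def load_mask_png(path) -> np.ndarray:
    return np.asarray(Image.open(path))


def save_image_png(path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def load_image_png(path) -> np.ndarray:
    return np.asarray(Image.open(path))


def save_vector_field(path, field_: VectorField) -> None:
    np.savez_compressed(path, vectors=field_.vectors,
                        mask=field_.mask.astype(np.uint8))


def load_vector_field(path) -> VectorField:
    with np.load(path) as z:
        return VectorField(z["vectors"], z["mask"].astype(bool))


def write_dataset(out_dir, samples: list, report=None) -> None:
    """Persist generated samples: per-sample PNG image + PNG label mask +
    JSON label, plus a manifest tying them together."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"schema": SCHEMA_VERSION, "n_samples": len(samples),
                "samples": []}
    for i, s in enumerate(samples):
        stem = f"sample_{i:05d}"
        save_image_png(out / f"{stem}.png", s.image)
        save_mask_png(out / f"{stem}_labels.png", s.masks.labels)
        rec = {"frame_id": i,
               "tool_pose": s.tool_pose.as_matrix().tolist(),
               "hand_joints": s.hand_joints.tolist(),
               "keypoints_2d": s.keypoints_2d.tolist(),
               "keypoints_3d": s.keypoints_3d.tolist(),
               "intrinsics": s.patch_intrinsics.to_dict(),
               "grasp_id": int(s.grasp_id),
               "template_id": int(s.template_id)}
        (out / f"{stem}.json").write_text(json.dumps(rec, indent=1))
        manifest["samples"].append(stem)
    if report is not None:
        manifest["generation_report"] = {
            "attempted": report.attempted, "emitted": report.emitted,
            "rejections": report.rejections}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_sample_record(out_dir, stem: str) -> dict:
    rec = json.loads((Path(out_dir) / f"{stem}.json").read_text())
    rec["tool_pose"] = RigidTransform.from_matrix(np.asarray(rec["tool_pose"]))
    rec["hand_joints"] = np.asarray(rec["hand_joints"])
    rec["keypoints_2d"] = np.asarray(rec["keypoints_2d"])
    rec["keypoints_3d"] = np.asarray(rec["keypoints_3d"])
    rec["intrinsics"] = CameraIntrinsics.from_dict(rec["intrinsics"])
    return rec


@dataclass
class RunConfig:
    """All pipeline parameters with the study-condition defaults, loadable
    from YAML with flag overrides."""
    seed: int = 0
    sigma_pose: float = 0.01
    sigma_shape: float = 0.05
    min_mask_pixels: int = 100
    min_visible_fraction: float = 0.40
    min_vertex_fraction: float = 0.40
    patch_size: int = 256
    jitter_radius: float = 64.0
    distance_range: tuple = (0.30, 0.50)
    z0: float = 0.4
    k_surface_keypoints: int = 8
    out_fps: float = 5.0
    n_correspondences: int = 16
    outlier_max_distance: float = 1e3
    trim_fraction: float = 0.8
    divergence_rms: float = 0.010
    n_samples: int = 50
    n_augmented_grasps: int = 210
    render_size: int = 512
    focal: float = 420.0
    paths: dict = field(default_factory=dict)

    @classmethod
    def load(cls, path, **overrides) -> "RunConfig":
        data = {}
        if path is not None:
            data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f_.name for f_ in cls.__dataclass_fields__.values()}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "distance_range" in data:
            data["distance_range"] = tuple(data["distance_range"])
        return cls(**data)

    def dump(self, path) -> None:
        d = asdict(self)
        d["distance_range"] = list(d["distance_range"])
        Path(path).write_text(yaml.safe_dump(d))
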