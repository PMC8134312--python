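"""Pose evaluation: ADD / Proj2D / drill-tip / bit-direction metrics,
outlier discarding, accuracy-threshold curves, and grouped cross-validation
splits.

Metrics are reported in the units benchmarks print — millimeters, pixels,
degrees — while all inputs stay in meters; the conversion happens only here.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .geometry import (CameraIntrinsics, RigidTransform, ToolMesh,
                       angle_between, project_points)

__all__ = ["PoseErrors", "tool_metrics", "hand_metrics", "discard_outliers",
           "accuracy_threshold_curve", "make_cv_splits", "summarize_folds"]

M_TO_MM = 1000.0


@dataclass(frozen=True)
class PoseErrors:
    """Per-sample tool pose errors: ADD (mm), mean 2D projection error (px),
    drill-tip position error (mm), bit-direction angular error (deg)."""
    add: float
    proj2d: float
    tip: float
    direction: float

    def __post_init__(self):
        if min(self.add, self.proj2d, self.tip, self.direction) < 0:
            raise ValueError("errors must be nonnegative")
        if self.direction > 180:
            raise ValueError("direction error cannot exceed 180 degrees")

    def to_dict(self) -> dict:
        return asdict(self)


def tool_metrics(mesh: ToolMesh, gt_pose: RigidTransform,
                 pred_pose: RigidTransform,
                 intr: CameraIntrinsics) -> PoseErrors:
    """ADD, Proj2D, drill-tip and bit-direction errors of a predicted tool
    pose against ground truth.

    ADD is the mean distance between corresponding mesh vertices under the
    two poses; Proj2D the mean pixel distance of their projections; the tip
    error uses the ``tip`` landmark and the direction error the angle
    between the rotated ``bit_axis`` vectors.
    """
    if "tip" not in mesh.landmarks or "bit_axis" not in mesh.axes:
        raise ValueError("tool mesh must define a tip landmark and bit_axis")
    gt_v = gt_pose.apply(mesh.vertices)
    pr_v = pred_pose.apply(mesh.vertices)
    add = float(np.mean(np.linalg.norm(gt_v - pr_v, axis=1))) * M_TO_MM
    proj = float(np.mean(np.linalg.norm(
        project_points(gt_v, intr) - project_points(pr_v, intr), axis=1)))
    tip = float(np.linalg.norm(gt_pose.apply(mesh.tip)
                               - pred_pose.apply(mesh.tip))) * M_TO_MM
    direction = angle_between(gt_pose.rotation @ mesh.bit_axis,
                              pred_pose.rotation @ mesh.bit_axis)
    return PoseErrors(add, proj, tip, direction)


def hand_metrics(gt_joints: np.ndarray, pred_joints: np.ndarray,
                 intr: CameraIntrinsics):
    """Mean 3D (mm) and mean projected 2D (px) hand-joint errors."""
    gt = np.asarray(gt_joints, float).reshape(-1, 3)
    pr = np.asarray(pred_joints, float).reshape(-1, 3)
    if gt.shape != pr.shape:
        raise ValueError("joint count mismatch")
    add = float(np.mean(np.linalg.norm(gt - pr, axis=1))) * M_TO_MM
    proj = float(np.mean(np.linalg.norm(
        project_points(gt, intr) - project_points(pr, intr), axis=1)))
    return add, proj


def discard_outliers(pred_poses: list, max_distance: float = 1e3):
    """Drop predictions farther than ``max_distance`` meters from the camera
    (strictly greater; the Euclidean norm of the translation), preserving
    order. Returns ``(kept, discarded_count)``."""
    kept = [p for p in pred_poses
            if np.linalg.norm(p.translation) <= max_distance]
    return kept, len(pred_poses) - len(kept)


def accuracy_threshold_curve(errors, thresholds):
    """Fraction of samples with error <= threshold, per threshold.

    Thresholds must be sorted ascending; the curve is non-decreasing and
    reaches 1 once the threshold passes the maximum error.
    """
    errors = np.asarray(errors, float)
    if errors.size == 0:
        raise ValueError("empty error list")
    thresholds = np.asarray(thresholds, float)
    if np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be sorted ascending")
    return np.array([(errors <= t).mean() for t in thresholds])


def make_cv_splits(unit_ids, k: int = 5, seed: int = 0):
    """Grouped k-fold partitions at the unit level (augmented grasps for the
    synthetic set, recordings for the real one), so no unit leaks between
    train and test of a fold.

    ``unit_ids`` is the per-sample unit label. Units are shuffled under the
    seed and split into k folds whose sizes differ by at most one. Returns a
    list of ``(train_indices, test_indices)`` pairs over samples.
    """
    unit_ids = np.asarray(unit_ids)
    units = np.unique(unit_ids)
    if len(units) < k:
        raise ValueError(f"need at least {k} distinct units, got {len(units)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(units))
    folds = np.array_split(units[order], k)
    splits = []
    for fold_units in folds:
        test = np.flatnonzero(np.isin(unit_ids, fold_units))
        train = np.flatnonzero(~np.isin(unit_ids, fold_units))
        splits.append((train, test))
    return splits


def summarize_folds(per_sample_errors: np.ndarray, splits: list) -> dict:
    """Benchmark-style aggregation: mean and SD within each test fold, then
    averaged across folds."""
    errs = np.asarray(per_sample_errors, float)
    means, sds = [], []
    for _, test in splits:
        means.append(errs[test].mean())
        sds.append(errs[test].std(ddof=0))
    return {"mean": float(np.mean(means)), "sd": float(np.mean(sds))}
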