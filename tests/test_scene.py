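"""Rendering, camera sampling, visibility filtering, patch cropping, and
dataset generation."""

import numpy as np
import pytest
from scipy.stats import kstest

from drillpose.fixtures import ToyAssetParams, make_toy_assets
from drillpose.geometry import CameraIntrinsics, RigidTransform, project_points
from drillpose.rendering import (LABEL_BODY_HAND, LABEL_TOOL, LabelMasks,
                                 SceneObject, render_label_masks, render_scene)
from drillpose.scene import (GenerationConfig, crop_patch, generate_dataset,
                             sample_camera_pose, visibility_filter)

INTR = CameraIntrinsics.centered(300.0, (128, 128))


def _identity_cam():
    return RigidTransform.identity()


class TestRasterizer:
    def test_single_triangle_matches_halfspace_oracle(self):
        verts = np.array([[-0.05, -0.05, 0.5], [0.08, -0.02, 0.5],
                          [0.0, 0.09, 0.5]])
        obj = SceneObject(verts, [[0, 1, 2]], LABEL_TOOL)
        _, labels, _ = render_scene([obj], _identity_cam(), INTR)
        uv = project_points(verts, INTR)
        xs, ys = np.meshgrid(np.arange(128), np.arange(128))

        def edge(a, b):
            return ((b[0] - a[0]) * (ys - a[1]) - (xs - a[0]) * (b[1] - a[1]))

        e0, e1, e2 = edge(uv[0], uv[1]), edge(uv[1], uv[2]), edge(uv[2], uv[0])
        inside = ((e0 >= 0) & (e1 >= 0) & (e2 >= 0)) | \
                 ((e0 <= 0) & (e1 <= 0) & (e2 <= 0))
        got = labels == LABEL_TOOL
        # boundary pixels may differ by the inclusive-edge convention
        disagreement = np.sum(got != inside)
        assert disagreement <= 0.02 * inside.sum() + 4
        interior = inside & (np.abs(e0) > 60) & (np.abs(e1) > 60) & \
            (np.abs(e2) > 60)
        assert np.all(got[interior])

    def test_empty_view_is_background(self):
        obj = SceneObject(np.array([[0, 0, -1.0], [0.1, 0, -1.0],
                                    [0, 0.1, -1.0]]), [[0, 1, 2]], LABEL_TOOL)
        _, labels, depth = render_scene([obj], _identity_cam(), INTR)
        assert (labels == 0).all()
        assert np.isinf(depth).all()

    def test_occluded_tool_has_empty_label_but_nonempty_unoccluded(self):
        tool = SceneObject(np.array([[-0.03, -0.03, 0.8], [0.03, -0.03, 0.8],
                                     [0.0, 0.03, 0.8]]), [[0, 1, 2]],
                           LABEL_TOOL)
        blocker = SceneObject(np.array([[-0.2, -0.2, 0.4], [0.2, -0.2, 0.4],
                                        [0.0, 0.3, 0.4]]), [[0, 1, 2]],
                              LABEL_BODY_HAND)
        masks = render_label_masks([blocker], tool, _identity_cam(), INTR)
        assert masks.tool_mask.sum() == 0
        assert masks.unoccluded_tool.sum() > 0
        # pixelwise: visible tool is always a subset of the unoccluded mask
        assert np.all(masks.unoccluded_tool | ~masks.tool_mask)

    def test_resolution_consistent_visibility_ratio(self, toy):
        assets, templates = toy
        tool_world = SceneObject(assets.tool.vertices, assets.tool.faces,
                                 LABEL_TOOL)
        cam = RigidTransform(np.eye(3), np.array([0.0, 0.0, 0.45]))
        ratios = []
        for size in (256, 512):
            intr = CameraIntrinsics.centered(420.0 * size / 512, (size, size))
            masks = render_label_masks([], tool_world, cam, intr)
            ratios.append(masks.tool_mask.sum() / masks.unoccluded_tool.sum())
        assert abs(ratios[0] - ratios[1]) < 0.02


class TestCameraSampling:
    HEAD = np.array([0.0, -0.3, 0.3])
    HAND = np.array([0.0, 0.0, 0.0])

    def test_zero_noise_places_camera_at_head(self, rng):
        p = sample_camera_pose(self.HEAD, self.HAND, self.HAND, rng,
                               head_noise=0.0, hand_noise=0.0,
                               distance_range=(0.42, 0.42))
        d = np.linalg.norm(self.HEAD - self.HAND)
        # camera slides along the optical axis to hit the requested distance
        cam_center = p.camera_pose.inverse().translation
        assert np.linalg.norm(cam_center - self.HAND) == pytest.approx(0.42,
                                                                       abs=1e-9)
        # optical axis passes through the hand
        z_world = p.camera_pose.rotation[2]
        off_axis = np.cross(z_world, self.HAND - cam_center)
        assert np.linalg.norm(off_axis) < 1e-9

    def test_distance_distribution_uniform(self):
        rng = np.random.default_rng(4)
        ds = [sample_camera_pose(self.HEAD, self.HAND, self.HAND, rng).distance
              for _ in range(1000)]
        ds = np.asarray(ds)
        assert ds.min() >= 0.30 and ds.max() <= 0.50
        stat = kstest(ds, "uniform", args=(0.30, 0.20))
        assert stat.pvalue > 0.01
        # realized camera-tool distances honor the draw
        p = sample_camera_pose(self.HEAD, self.HAND, self.HAND, rng)
        cam_center = p.camera_pose.inverse().translation
        assert np.linalg.norm(cam_center - self.HAND) == pytest.approx(
            p.distance, abs=1e-9)

    def test_fixed_seed_is_deterministic(self):
        a = sample_camera_pose(self.HEAD, self.HAND, self.HAND,
                               np.random.default_rng(77))
        b = sample_camera_pose(self.HEAD, self.HAND, self.HAND,
                               np.random.default_rng(77))
        assert np.array_equal(a.camera_pose.as_matrix(),
                              b.camera_pose.as_matrix())

    def test_vertical_view_uses_fallback_up(self, rng):
        p = sample_camera_pose(np.array([0.0, 0.0, 0.4]), self.HAND,
                               self.HAND, rng, head_noise=0.0, hand_noise=0.0)
        assert np.all(np.isfinite(p.camera_pose.as_matrix()))

    def test_coincident_head_hand_raises(self, rng):
        with pytest.raises(ValueError):
            sample_camera_pose(self.HAND, self.HAND, self.HAND, rng,
                               head_noise=0.0, hand_noise=0.0)


def _masks(hand_px, tool_px, unoccluded_px, size=512):
    labels = np.zeros((size, size), np.uint8)
    labels.flat[:hand_px] = LABEL_BODY_HAND
    labels.flat[hand_px:hand_px + tool_px] = LABEL_TOOL
    unocc = np.zeros((size, size), bool)
    unocc.flat[hand_px:hand_px + unoccluded_px] = True
    return LabelMasks(labels, unocc)


class TestVisibilityFilter:
    def test_hand_pixel_threshold_boundary(self):
        ok, reason = visibility_filter(_masks(99, 1000, 1000))
        assert not ok and "hand" in reason
        ok, _ = visibility_filter(_masks(100, 1000, 1000))
        assert ok

    def test_tool_pixel_threshold_boundary(self):
        ok, reason = visibility_filter(_masks(500, 99, 1000))
        assert not ok and "tool pixels" in reason

    def test_visible_fraction_boundary(self):
        ok, reason = visibility_filter(_masks(500, 390, 1000))
        assert not ok and "fraction" in reason
        ok, _ = visibility_filter(_masks(500, 410, 1000))
        assert ok

    def test_tool_out_of_view(self):
        ok, reason = visibility_filter(_masks(500, 0, 0))
        assert not ok and reason == "tool out of view"


class TestCropPatch:
    INTR = CameraIntrinsics.centered(420.0, (512, 512))

    def _scene(self):
        image = np.zeros((512, 512, 3), np.uint8)
        labels = np.zeros((512, 512), np.uint8)
        labels[200:300, 220:320] = LABEL_TOOL
        masks = LabelMasks(labels, labels == LABEL_TOOL)
        return image, masks

    def test_zero_jitter_centers_tool_bbox(self, rng):
        image, masks = self._scene()
        uv = np.array([[220.0, 200.0], [320.0, 300.0]])
        img, m, intr, tf = crop_patch(image, masks, uv, self.INTR, rng,
                                      jitter_radius=0.0)
        center = tf(0.5 * (uv.min(axis=0) + uv.max(axis=0)))
        assert np.abs(center - 128.0).max() <= 0.5   # integer-origin rounding

    def test_projection_crop_consistency(self, rng):
        image, masks = self._scene()
        uv = np.array([[220.0, 200.0], [320.0, 300.0]])
        pts3d = np.array([[0.02, -0.03, 0.4], [0.0, 0.0, 0.45],
                          [-0.01, 0.02, 0.5]])
        full_uv = project_points(pts3d, self.INTR)
        _, _, patch_intr, tf = crop_patch(image, masks, uv, self.INTR, rng)
        direct = project_points(pts3d, patch_intr)
        assert np.abs(direct - tf(full_uv)).max() < 1e-6

    def test_vertex_fraction_boundary(self, rng):
        image, masks = self._scene()
        # 100 vertices: some inside the eventual patch, some far outside
        def uv_for(n_in):
            # outliers at both corners keep the bbox center on the cluster
            n_out = 100 - n_in
            return np.vstack([np.full((n_in, 2), 256.0),
                              np.full((n_out // 2, 2), 0.0),
                              np.full((n_out - n_out // 2, 2), 512.0)])

        out = crop_patch(image, masks, uv_for(39), self.INTR,
                         np.random.default_rng(0), jitter_radius=0.0)
        assert out[0] is None and "fraction" in out[3]
        out = crop_patch(image, masks, uv_for(41), self.INTR,
                         np.random.default_rng(0), jitter_radius=0.0)
        assert out[0] is not None

    def test_out_of_image_crop_pads_background(self, rng):
        image, masks = self._scene()
        uv = np.array([[0.0, 0.0], [40.0, 40.0]])    # bbox near the corner
        img, m, intr, tf = crop_patch(image, masks, uv, self.INTR,
                                      np.random.default_rng(1),
                                      jitter_radius=0.0,
                                      min_vertex_fraction=0.0)
        assert img.shape[:2] == (256, 256)
        assert m.labels.shape == (256, 256)
        assert (m.labels[:50, :50] == 0).all()


class TestToyAssets:
    def test_tool_watertight_with_landmarks(self, toy):
        assets, _ = toy
        tm = assets.tool.as_trimesh()
        assert tm.is_watertight
        assert np.linalg.norm(assets.tool.bit_axis) == pytest.approx(1.0)
        # tip lies on the bit end cap
        tip = assets.tool.tip
        dists = np.linalg.norm(assets.tool.vertices - tip, axis=1)
        assert dists.min() < 0.005

    def test_degenerate_dimensions_raise(self):
        with pytest.raises(ValueError):
            make_toy_assets(ToyAssetParams(bit_radius=-1.0))
        with pytest.raises(ValueError):
            make_toy_assets(ToyAssetParams(bit_radius=0.05))


class TestGeneration:
    def test_small_run_emits_requested_samples(self, small_dataset):
        samples, report = small_dataset
        assert len(samples) == 8
        assert report.emitted == 8
        assert report.emitted + report.rejected == report.attempted

    def test_samples_are_self_consistent(self, small_dataset, toy):
        assets, _ = toy
        for s in small_dataset[0]:
            uv = project_points(s.tool_pose.apply(s.keypoints_3d),
                                s.patch_intrinsics)
            assert np.abs(uv - s.keypoints_2d).max() < 1e-6
            # >= 40% of projected tool vertices inside the patch
            tuv = project_points(s.tool_pose.apply(assets.tool.vertices),
                                 s.patch_intrinsics)
            inside = np.all((tuv >= 0) & (tuv <= 255), axis=1)
            assert inside.mean() >= 0.40
            assert s.image.shape == (256, 256, 3)
            assert s.masks.labels.shape == (256, 256)

    def test_same_seed_bit_reproducible(self, toy):
        assets, templates = toy
        cfg = GenerationConfig(n_samples=3)
        a, _ = generate_dataset(assets, templates, cfg, seed=21)
        b, _ = generate_dataset(assets, templates, cfg, seed=21)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.image, sb.image)
            assert np.array_equal(sa.tool_pose.as_matrix(),
                                  sb.tool_pose.as_matrix())
            assert np.array_equal(sa.keypoints_2d, sb.keypoints_2d)

    def test_filters_monotone_in_occluders(self, toy):
        """Deleting occluder geometry never turns an accepted view into a
        rejected one."""
        assets, templates = toy
        samples, _ = generate_dataset(assets, templates,
                                      GenerationConfig(n_samples=3), seed=33)
        # re-render each accepted sample's tool alone: the visible fraction
        # can only grow, so the visibility filter still accepts
        for s in samples:
            tool_obj = SceneObject(s.tool_pose.apply(assets.tool.vertices),
                                   assets.tool.faces, LABEL_TOOL)
            masks = render_label_masks([], tool_obj, RigidTransform.identity(),
                                       s.patch_intrinsics)
            frac_with = s.masks.tool_mask.sum() / max(
                s.masks.unoccluded_tool.sum(), 1)
            frac_without = masks.tool_mask.sum() / max(
                masks.unoccluded_tool.sum(), 1)
            assert frac_without >= frac_with - 1e-9
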