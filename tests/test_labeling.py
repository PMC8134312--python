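"""Multi-view fusion, trimmed ICP, sequence tracking, and hand fitting."""

import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

from drillpose.geometry import PointCloud, RigidTransform
from drillpose.handmodel import HandPose, synthesize_hand
from drillpose.labeling import (HandCorrespondences, Recording,
                                TrackingParams, build_joint_model,
                                fit_hand_pose, fuse_views,
                                propagate_hand_labels, track_tool_sequence,
                                trimmed_icp)
from drillpose.simulate import (TrackingSimConfig,
                                simulate_hand_correspondences,
                                simulate_tracking_sequence)


class TestFuseViews:
    def test_identity_extrinsics_concatenate(self, rng):
        a = PointCloud(rng.normal(size=(10, 3)))
        b = PointCloud(rng.normal(size=(7, 3)))
        I = RigidTransform.identity()
        fused = fuse_views([a, b], [I, I])
        assert np.array_equal(fused.points, np.vstack([a.points, b.points]))

    def test_round_trip_through_extrinsic(self, rng):
        cloud = PointCloud(rng.normal(size=(20, 3)))
        T = RigidTransform.random(rng)
        moved = cloud.transformed(T.inverse())
        fused = fuse_views([moved], [T])
        assert np.abs(fused.points - cloud.points).max() < 1e-9

    def test_single_view_unchanged(self, rng):
        cloud = PointCloud(rng.normal(size=(5, 3)),
                           colors=rng.random((5, 3)))
        fused = fuse_views([cloud], [RigidTransform.identity()])
        assert np.array_equal(fused.points, cloud.points)
        assert np.array_equal(fused.colors, cloud.colors)

    def test_count_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            fuse_views([PointCloud(rng.normal(size=(5, 3)))], [])


class TestTrimmedICP:
    def test_identity_on_identical_clouds(self, rng):
        pts = PointCloud(rng.normal(size=(100, 3)))
        pose, rms, converged = trimmed_icp(pts, pts)
        assert np.abs(pose.as_matrix() - np.eye(4)).max() < 1e-9
        assert rms < 1e-12
        assert converged

    def test_trim_one_is_classical_icp(self, toy, rng):
        assets, _ = toy
        src = PointCloud(assets.tool.vertices)
        G = RigidTransform.from_rotvec([0.05, 0.02, -0.03], [0.01, 0, 0.005])
        tgt = src.transformed(G)
        pose, rms, _ = trimmed_icp(src, tgt, trim_fraction=1.0)
        err = np.abs(pose.as_matrix() - G.as_matrix()).max()
        assert err < 1e-6
        assert rms < 1e-8

    def test_outlier_recovery_with_trimming(self, toy):
        assets, _ = toy
        tm = assets.tool.as_trimesh()
        rng = np.random.default_rng(42)
        pts, _ = trimesh.sample.sample_surface(tm, 2000, seed=7)
        pts = np.asarray(pts)
        G = RigidTransform.random(rng, max_translation=0.1)
        target = np.vstack([G.apply(pts),
                            rng.uniform(-0.15, 0.15, (400, 3))
                            + G.translation])
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        init = RigidTransform(
            Rotation.from_rotvec(axis * np.radians(10)).as_matrix()
            @ G.rotation, G.translation + rng.uniform(-0.011, 0.011, 3))
        pose, _, _ = trimmed_icp(PointCloud(pts), PointCloud(target), init,
                                 trim_fraction=0.8)
        err = np.mean(np.linalg.norm(pose.apply(assets.tool.vertices)
                                     - G.apply(assets.tool.vertices), axis=1))
        assert err < 1e-3

    def test_trimmed_mse_nonincreasing(self, toy):
        """The trimmed objective decreases monotonically with iterations."""
        assets, _ = toy
        rng = np.random.default_rng(5)
        src = PointCloud(assets.tool.vertices)
        G = RigidTransform.from_rotvec([0.1, -0.05, 0.08], [0.02, 0.01, 0])
        tgt = PointCloud(G.apply(src.points) + rng.normal(0, 5e-4, (126, 3)))
        rms_by_iter = [trimmed_icp(src, tgt, max_iter=k, tol=0.0)[1]
                       for k in range(1, 12)]
        diffs = np.diff(rms_by_iter)
        assert np.all(diffs <= 1e-12)

    def test_input_validation(self, rng):
        pts = PointCloud(rng.normal(size=(10, 3)))
        with pytest.raises(ValueError):
            trimmed_icp(PointCloud(np.zeros((0, 3))), pts)
        with pytest.raises(ValueError):
            trimmed_icp(pts, pts, trim_fraction=0.0)


class TestJointModel:
    def test_union_counts_and_tags(self, rng):
        tool = rng.normal(size=(30, 3))
        hand = rng.normal(size=(50, 3))
        cloud, is_tool = build_joint_model(tool, hand)
        assert len(cloud) == 80
        assert is_tool.sum() == 30
        assert np.array_equal(cloud.points[is_tool], tool)
        assert np.array_equal(cloud.points[~is_tool], hand)

    def test_empty_inputs_raise(self, rng):
        with pytest.raises(ValueError):
            build_joint_model(np.zeros((0, 3)), rng.normal(size=(5, 3)))

    def test_joint_model_survives_tool_dropout(self, toy):
        """With 60 % of the tool surface missing, registering the joint
        hand-tool model succeeds where the tool-only model drifts."""
        assets, templates = toy
        cfg = TrackingSimConfig(n_frames=1, tool_dropout=0.60)
        rec, poses, joint_cloud = simulate_tracking_sequence(
            assets, templates[0], cfg, seed=3)
        # single-frame registration from a deliberately offset init
        init = RigidTransform.from_rotvec([0.1, 0.05, -0.08],
                                          [0.015, -0.01, 0.01])
        frame = rec.frames[0]

        def vert_err(pose):
            diff = pose.apply(assets.tool.vertices) \
                - poses[0].apply(assets.tool.vertices)
            return np.mean(np.linalg.norm(diff, axis=1))

        joint_pose, _, _ = trimmed_icp(joint_cloud, frame, init, 0.8)
        tool_pose, _, _ = trimmed_icp(PointCloud(assets.tool.vertices),
                                      frame, init, 0.8)
        assert vert_err(joint_pose) < 2e-3
        assert vert_err(tool_pose) > 5e-3


class TestSequenceTracking:
    def test_static_sequence_all_ok(self, toy):
        assets, templates = toy
        cfg = TrackingSimConfig(n_frames=10, max_angle_per_frame=0.0,
                                max_translation_per_frame=0.0,
                                sensor_noise=0.0005)
        rec, poses, joint_cloud = simulate_tracking_sequence(
            assets, templates[0], cfg, seed=1)
        seq = track_tool_sequence(joint_cloud, rec,
                                  RigidTransform.identity(),
                                  TrackingParams(out_fps=None))
        assert all(s == "ok" for s in seq.status)
        for p in seq.tool_poses:
            err = np.mean(np.linalg.norm(
                p.apply(assets.tool.vertices) - assets.tool.vertices, axis=1))
            assert err < 2e-3

    def test_corrupted_frame_flagged_and_recovered(self, toy):
        assets, templates = toy
        cfg = TrackingSimConfig(n_frames=12, corrupt_frames=(6,))
        rec, poses, joint_cloud = simulate_tracking_sequence(
            assets, templates[0], cfg, seed=2)
        seq = track_tool_sequence(joint_cloud, rec,
                                  RigidTransform.identity(),
                                  TrackingParams(out_fps=None))
        assert seq.status[6] in ("reinitialized", "discarded")
        for t in (7, 8, 11):
            err = np.mean(np.linalg.norm(
                seq.tool_poses[t].apply(assets.tool.vertices)
                - poses[t].apply(assets.tool.vertices), axis=1))
            assert err < 2e-3

    def test_residual_invariant_ok_below_threshold(self, toy):
        assets, templates = toy
        cfg = TrackingSimConfig(n_frames=6)
        rec, _, joint_cloud = simulate_tracking_sequence(
            assets, templates[0], cfg, seed=4)
        params = TrackingParams(out_fps=None)
        seq = track_tool_sequence(joint_cloud, rec,
                                  RigidTransform.identity(), params)
        for rms, st in zip(seq.residuals, seq.status):
            if st == "ok":
                assert rms <= params.divergence_rms

    def test_fps_downsampling(self, toy):
        assets, templates = toy
        cfg = TrackingSimConfig(n_frames=12, native_fps=30.0)
        rec, _, joint_cloud = simulate_tracking_sequence(
            assets, templates[0], cfg, seed=5)
        seq = track_tool_sequence(joint_cloud, rec,
                                  RigidTransform.identity(),
                                  TrackingParams(out_fps=5.0))
        assert len(seq.tool_poses) == 2     # every 6th of 12 frames

    def test_bad_first_frame_raises(self, toy, rng):
        assets, templates = toy
        cfg = TrackingSimConfig(n_frames=2)
        rec, _, joint_cloud = simulate_tracking_sequence(
            assets, templates[0], cfg, seed=6)
        far = RigidTransform(np.eye(3), np.array([1.0, 1.0, 1.0]))
        with pytest.raises(ValueError, match="frame 0"):
            track_tool_sequence(joint_cloud, rec, far,
                                TrackingParams(out_fps=None, n_restarts=0))


class TestHandFit:
    def test_exact_configuration_zero_residual(self, toy, rng):
        assets, _ = toy
        H_true = RigidTransform.random(rng, max_translation=0.2)
        corr, truth = simulate_hand_correspondences(
            assets, HandPose(), H_true, noise=0.0, seed=0)
        H, pose = fit_hand_pose(corr, assets.hand_assets, lam=0.0)
        assert np.linalg.norm(pose.pca_coeffs) < 1e-8
        assert np.abs(H.as_matrix() - H_true.as_matrix()).max() < 1e-8

    def test_parameter_recovery_under_noise(self, toy):
        assets, _ = toy
        rng = np.random.default_rng(17)
        theta = rng.normal(0, 0.15, 15)
        H_true = RigidTransform.random(rng, max_translation=0.2)
        corr, truth = simulate_hand_correspondences(
            assets, HandPose(pca_coeffs=theta), H_true, noise=0.001, seed=8)
        H, pose = fit_hand_pose(corr, assets.hand_assets, lam=1e-4)
        _, joints = synthesize_hand(assets.hand_assets, pose)
        err = np.mean(np.linalg.norm(H.apply(joints) - truth["joints"],
                                     axis=1))
        assert err < 3e-3

    def test_large_lambda_drives_theta_to_zero(self, toy):
        assets, _ = toy
        rng = np.random.default_rng(9)
        corr, _ = simulate_hand_correspondences(
            assets, HandPose(pca_coeffs=rng.normal(0, 0.2, 15)),
            RigidTransform.random(rng, max_translation=0.1), noise=0.001,
            seed=2)
        H, pose = fit_hand_pose(corr, assets.hand_assets, lam=1e9)
        assert np.linalg.norm(pose.pca_coeffs) < 1e-6
        # with theta = 0, H must equal the rigid-only fit
        from drillpose.geometry import fit_rigid
        mesh0, _ = synthesize_hand(assets.hand_assets, HandPose())
        rigid = fit_rigid(mesh0.vertices[corr.vertex_indices], corr.points)
        assert np.abs(H.as_matrix() - rigid.as_matrix()).max() < 1e-6

    def test_collinear_targets_raise(self, toy):
        assets, _ = toy
        idx = np.arange(16)
        pts = np.outer(np.linspace(0, 1, 16), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            fit_hand_pose(HandCorrespondences(idx, pts), assets.hand_assets)

    def test_correspondence_count_enforced(self, toy, rng):
        with pytest.raises(ValueError):
            HandCorrespondences(np.arange(15), rng.normal(size=(15, 3)))


class TestPropagation:
    def _fit(self, toy):
        assets, _ = toy
        rng = np.random.default_rng(23)
        theta = rng.normal(0, 0.1, 15)
        H_true = RigidTransform.random(rng, max_translation=0.1)
        corr, truth = simulate_hand_correspondences(
            assets, HandPose(pca_coeffs=theta), H_true, noise=0.0005, seed=4)
        return fit_hand_pose(corr, assets.hand_assets), truth

    def test_identity_tool_track_preserves_hand(self, toy):
        assets, _ = toy
        (H0, pose), truth = self._fit(toy)
        from drillpose.labeling import TrackedSequence
        seq = TrackedSequence([RigidTransform.identity()], np.zeros(1), ["ok"])
        out = propagate_hand_labels(seq, H0, pose, assets.hand_assets)
        assert np.abs(out[0]["hand_pose"].as_matrix()
                      - H0.as_matrix()).max() < 1e-12

    def test_discarded_frames_yield_no_labels(self, toy, rng):
        assets, _ = toy
        (H0, pose), _ = self._fit(toy)
        from drillpose.labeling import TrackedSequence
        seq = TrackedSequence(
            [RigidTransform.identity(), RigidTransform.random(rng)],
            np.zeros(2), ["discarded", "ok"])
        out = propagate_hand_labels(seq, H0, pose, assets.hand_assets)
        assert out[0] is None and out[1] is not None

    def test_propagated_frame_matches_direct_fit(self, toy):
        """Composing the frame-0 hand fit with the tool track agrees with a
        direct hand fit performed at frame t."""
        assets, _ = toy
        rng = np.random.default_rng(31)
        theta = rng.normal(0, 0.1, 15)
        H0_true = RigidTransform.random(rng, max_translation=0.1)
        H_tool_t = RigidTransform.random(rng, max_translation=0.1)
        corr0, _ = simulate_hand_correspondences(
            assets, HandPose(pca_coeffs=theta), H0_true, noise=0.0003, seed=1)
        corr_t, _ = simulate_hand_correspondences(
            assets, HandPose(pca_coeffs=theta), H_tool_t @ H0_true,
            noise=0.0003, seed=2)
        H0, pose0 = fit_hand_pose(corr0, assets.hand_assets)
        Ht_direct, pose_t = fit_hand_pose(corr_t, assets.hand_assets)
        from drillpose.labeling import TrackedSequence
        seq = TrackedSequence([H_tool_t], np.zeros(1), ["ok"])
        out = propagate_hand_labels(seq, H0, pose0, assets.hand_assets)
        _, joints_direct = synthesize_hand(assets.hand_assets, pose_t)
        diff = np.mean(np.linalg.norm(
            out[0]["joints"] - Ht_direct.apply(joints_direct), axis=1))
        assert diff < 3e-3
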