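import numpy as np
import pytest

from skinfuse import (
    CameraSimSpec,
    LandmarkPair,
    RegistrationConfig,
    RigidTransform,
    TriangleMesh,
    VolumetricImage,
    apply_to_volume,
    best_rigid,
    coregister,
    icp,
    landmark_translate,
    pca_align,
    rotation_angle_deg,
    simulate_camera_surface,
    snap_to_surface,
    vertex_normals,
)


def _ellipsoid_cloud(semi_axes=(80.0, 40.0, 20.0), n=600, seed=0) -> TriangleMesh:
    rng = np.random.default_rng(seed)
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return TriangleMesh(vertices=d * np.asarray(semi_axes))


class TestPcaAlign:
    def test_self_alignment_is_identity(self):
        m = _ellipsoid_cloud()
        T = pca_align(m, m)
        assert rotation_angle_deg(T.rotation) < 1e-6
        np.testing.assert_allclose(T.translation, 0.0, atol=1e-9)

    def test_recovers_known_rotation(self):
        m = _ellipsoid_cloud(n=2000)
        gt = RigidTransform.from_axis_angle((0.2, 1.0, 0.4), 25.0, (7.0, -2.0, 3.0))
        moved = TriangleMesh(vertices=gt.apply(m.vertices))
        T = pca_align(m, moved)
        assert rotation_angle_deg(T.rotation, gt.rotation) < 0.5

    def test_sphere_cloud_is_ambiguous(self, icosphere):
        with pytest.raises(ValueError, match="ambiguous"):
            pca_align(icosphere, icosphere)


class TestLandmarkTranslate:
    def test_coincident_landmarks_keep_translation(self):
        m = _ellipsoid_cloud()
        R = RigidTransform.from_axis_angle((0, 0, 1), 15.0, (3.0, 4.0, 5.0))
        lm = m.vertices[0]
        pair = LandmarkPair(lm, R.apply(lm))
        out = landmark_translate(m, pair, R)
        np.testing.assert_allclose(out.translation, R.translation, atol=1e-9)

    def test_offset_appears_in_translation(self):
        m = _ellipsoid_cloud()
        lm = m.vertices[0]
        pair = LandmarkPair(lm, lm + [10.0, 0.0, 0.0])
        out = landmark_translate(m, pair, RigidTransform.identity())
        np.testing.assert_allclose(out.translation, [10.0, 0.0, 0.0], atol=1e-12)

    def test_landmark_residual_exactly_zero(self):
        rng = np.random.default_rng(3)
        m = _ellipsoid_cloud(seed=3)
        gt = RigidTransform.from_axis_angle(rng.normal(size=3), 18.0, rng.normal(size=3) * 20)
        lm = m.vertices[17]
        pair = LandmarkPair(lm, gt.apply(lm))
        R = RigidTransform(gt.rotation, rng.normal(size=3))  # wrong translation
        out = landmark_translate(m, pair, R)
        np.testing.assert_allclose(out.apply(lm), pair.on_camera, atol=1e-12)


class TestBestRigid:
    def test_exact_recovery_from_correspondences(self):
        rng = np.random.default_rng(5)
        P = rng.normal(size=(100, 3)) * 20
        gt = RigidTransform.from_axis_angle((1, -1, 2), 33.0, (4.0, 5.0, -6.0))
        T = best_rigid(P, gt.apply(P))
        assert rotation_angle_deg(T.rotation, gt.rotation) < 1e-9
        np.testing.assert_allclose(T.translation, gt.translation, atol=1e-9)


class TestIcp:
    def test_identical_clouds_converge_immediately(self):
        pts = _ellipsoid_cloud(n=200).vertices
        T, hist = icp(pts, pts, RigidTransform.identity())
        assert len(hist) == 1
        assert hist[0] <= 1e-12
        assert rotation_angle_deg(T.rotation) < 1e-5

    def test_noise_free_parameter_recovery(self):
        half = _ellipsoid_cloud(n=800, seed=7)
        half = TriangleMesh(vertices=half.vertices[half.vertices[:, 1] > 0])
        gt = RigidTransform.from_axis_angle((0, 0, 1), 10.0, (5.0, -3.0, 2.0))
        dst = gt.apply(half.vertices)
        T, hist = icp(half.vertices, dst, trim_fraction=1.0)
        assert rotation_angle_deg(T.rotation, gt.rotation) < 0.1
        assert np.linalg.norm(T.translation - gt.translation) < 0.1
        assert all(hist[i + 1] <= hist[i] + 1e-12 for i in range(len(hist) - 1))

    def test_trimming_rejects_outliers(self):
        rng = np.random.default_rng(9)
        half = _ellipsoid_cloud(n=800, seed=7)
        half = TriangleMesh(vertices=half.vertices[half.vertices[:, 1] > 0])
        gt = RigidTransform.from_axis_angle((0, 0, 1), 10.0, (5.0, -3.0, 2.0))
        dst = gt.apply(half.vertices)
        src = half.vertices.copy()
        n_out = len(src) // 10
        src[rng.choice(len(src), n_out, replace=False)] += rng.normal(
            size=(n_out, 3)
        ) * 100 + 300
        T_trim, _ = icp(src, dst, trim_fraction=0.8)
        assert rotation_angle_deg(T_trim.rotation, gt.rotation) < 0.5
        assert np.linalg.norm(T_trim.translation - gt.translation) < 0.5
        T_full, _ = icp(src, dst, trim_fraction=1.0)
        err_full = np.linalg.norm(T_full.translation - gt.translation)
        assert err_full > 0.5  # the untrimmed run is dragged off by outliers

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            icp(np.zeros((4, 3)), np.zeros((10, 3)))


@pytest.fixture(scope="module")
def default_camera(abdomen_skin, anterior_landmark):
    pose = RigidTransform.from_axis_angle((0.2, 0.3, 0.93), 15.0, (25.0, -10.0, 30.0))
    cam, gt = simulate_camera_surface(
        abdomen_skin, CameraSimSpec(pose=pose, coverage=0.6, noise_sigma=0.5, seed=21)
    )
    lm_cam = snap_to_surface(pose.apply(anterior_landmark), cam)
    return cam, gt, lm_cam


class TestCoregister:
    def test_self_registration_is_identity(self, abdomen_skin, anterior_landmark):
        cam, _ = simulate_camera_surface(
            abdomen_skin,
            CameraSimSpec(pose=RigidTransform.identity(), coverage=1.0,
                          noise_sigma=0.0, seed=0),
        )
        pair = LandmarkPair(anterior_landmark, snap_to_surface(anterior_landmark, cam))
        res = coregister(abdomen_skin, cam, pair)
        assert res.transform.angle_deg() < 1e-3
        assert np.linalg.norm(res.transform.translation) < 1e-3

    def test_ground_truth_pose_recovery(self, abdomen_skin, anterior_landmark,
                                        default_camera):
        cam, gt, lm_cam = default_camera
        res = coregister(abdomen_skin, cam, LandmarkPair(anterior_landmark, lm_cam))
        assert rotation_angle_deg(res.transform.rotation, gt.rotation) < 1.0
        assert np.linalg.norm(res.transform.translation - gt.translation) < 1.0

    def test_rms_trace_monotone_and_stages_recorded(self, abdomen_skin,
                                                    anterior_landmark, default_camera):
        cam, _, lm_cam = default_camera
        res = coregister(abdomen_skin, cam, LandmarkPair(anterior_landmark, lm_cam))
        assert len(res.per_stage_rms) == 3
        assert len(res.rms_history) == 2
        for hist in res.rms_history:
            assert all(hist[i + 1] <= hist[i] + 1e-9 for i in range(len(hist) - 1))

    def test_landmark_misplacement_leaves_rotation(self, abdomen_skin,
                                                   anterior_landmark, default_camera):
        cam, _, lm_cam = default_camera
        base = coregister(abdomen_skin, cam, LandmarkPair(anterior_landmark, lm_cam))
        d = 15.0
        for off in ([d, 0, 0], [0, 0, d], [d / np.sqrt(2), d / np.sqrt(2), 0]):
            shifted = snap_to_surface(lm_cam + np.asarray(off), cam)
            pert = coregister(abdomen_skin, cam, LandmarkPair(anterior_landmark, shifted))
            change = rotation_angle_deg(pert.transform.rotation, base.transform.rotation)
            assert change < 1.0

    def test_final_rms_reproducible_from_transform(self, abdomen_skin,
                                                   anterior_landmark, default_camera):
        from scipy.spatial import cKDTree

        from skinfuse.mesh import crop_roi
        from skinfuse.registration import _trimmed_plane_rms

        cam, _, lm_cam = default_camera
        cfg = RegistrationConfig()
        res = coregister(abdomen_skin, cam, LandmarkPair(anterior_landmark, lm_cam), cfg)
        front = res.roi_segmented
        cam_roi = crop_roi(cam, lm_cam, cfg.roi_radius)
        m = int(round(cfg.trim_fraction * cam_roi.n_vertices))
        rms = _trimmed_plane_rms(
            res.transform.inverse(), cam_roi.vertices, front.vertices,
            res.roi_normals, cKDTree(front.vertices), m,
        )
        assert rms == pytest.approx(res.per_stage_rms[-1], abs=1e-6)


class TestApplyToVolume:
    def test_identity_keeps_header(self):
        vol = VolumetricImage(data=np.zeros((4, 4, 4)), origin=(1.0, 2.0, 3.0))
        out = apply_to_volume(vol, RigidTransform.identity())
        np.testing.assert_array_equal(out.origin, vol.origin)
        np.testing.assert_array_equal(out.axes, vol.axes)

    def test_inverse_round_trip(self):
        vol = VolumetricImage(data=np.zeros((4, 4, 4)), origin=(5.0, -1.0, 2.0))
        T = RigidTransform.from_axis_angle((1, 2, -1), 40.0, (10.0, 0.0, -3.0))
        out = apply_to_volume(apply_to_volume(vol, T), T.inverse())
        np.testing.assert_allclose(out.origin, vol.origin, atol=1e-9)
        np.testing.assert_allclose(out.axes, vol.axes, atol=1e-9)

    def test_voxel_world_coordinates_transform_pointwise(self):
        rng = np.random.default_rng(8)
        vol = VolumetricImage(
            data=np.zeros((6, 5, 4)), spacing=(1.5, 2.0, 3.0), origin=(-4.0, 2.0, 7.0)
        )
        T = RigidTransform.from_axis_angle((0.1, 0.9, 0.2), 25.0, (3.0, -8.0, 1.0))
        out = apply_to_volume(vol, T)
        idx = rng.integers(0, (6, 5, 4), size=(10, 3))
        np.testing.assert_allclose(
            out.world_coords(idx), T.apply(vol.world_coords(idx)), atol=1e-9
        )

    def test_voxel_data_untouched(self):
        rng = np.random.default_rng(9)
        vol = VolumetricImage(data=rng.normal(size=(4, 4, 4)))
        out = apply_to_volume(vol, RigidTransform.from_axis_angle((0, 0, 1), 10.0))
        assert out.data is vol.data
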