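"""Phantom geometry, depth rendering, motion protocols, deformation, sessions."""

import numpy as np
import pytest

from surftrack.camera import DepthCamera, NoiseModel, default_cameras, render_depth
from surftrack.cloud import SurfaceCloud
from surftrack.motion import single_axis_protocol, smooth_trace
from surftrack.phantom import REGION_CODES, HeadPhantomParams, make_phantom
from surftrack.session import DeformationEvent, facial_deformation, simulate_session
from surftrack.transforms import RigidTransform


class TestPhantom:
    def test_deterministic_for_given_seed(self):
        a = make_phantom(seed=3)
        b = make_phantom(seed=3)
        assert a.vertices.tobytes() == b.vertices.tobytes()
        assert a.faces.tobytes() == b.faces.tobytes()
        c = make_phantom(seed=4)
        assert c.vertices.tobytes() != a.vertices.tobytes()

    def test_zero_nose_z_extent_matches_superellipsoid(self):
        # with the nose off (and no random relief) nothing protrudes past
        # the cranium's analytic anterior semi-axis
        p = HeadPhantomParams(nose_mm=0.0, roughness_mm=0.0)
        ph = make_phantom(p, seed=0)
        c = p.semi_axes[2]
        assert ph.vertices[:, 2].max() <= c + 1e-9
        assert ph.vertices[:, 2].max() > c - 0.05

    def test_area_plausibility_gate(self):
        ph = make_phantom(seed=0)
        assert 400.0 <= ph.area_cm2() <= 1200.0

    def test_within_bounding_sphere(self):
        ph = make_phantom(seed=0)
        assert np.linalg.norm(ph.vertices, axis=1).max() < 250.0

    def test_amplitude_validation(self):
        with pytest.raises(ValueError):
            make_phantom(HeadPhantomParams(nose_mm=60.0))

    def test_region_labels_cover_face(self):
        ph = make_phantom(seed=0)
        present = set(np.unique(ph.labels).tolist())
        for region in ("nose", "forehead", "cheek_left", "cheek_right",
                       "jaw", "brow", "larynx"):
            assert REGION_CODES[region] in present


def _frontal_camera(width=160, height=120):
    return DepthCamera.from_fov(width, height, 60.0, 45.0,
                                RigidTransform.identity())


class TestRenderDepth:
    def test_flat_plane_renders_exact_depth(self):
        # plane at 500 mm facing the camera: every hit pixel reads 500.000
        cam = _frontal_camera()
        v = np.array([[-1000.0, -1000, 500], [1000, -1000, 500],
                      [1000, 1000, 500], [-1000, 1000, 500]])
        f = np.array([[0, 1, 2], [0, 2, 3]])
        cloud, depth, _ = render_depth(v, f, cam, NoiseModel.noiseless(),
                                       return_buffers=True)
        assert np.isfinite(depth).all()
        assert np.allclose(depth, 500.0, atol=1e-9)
        assert np.allclose(cloud.points[:, 2], 500.0, atol=1e-9)

    def test_sphere_silhouette_matches_analytic_count(self):
        # visible pixel count of a sphere = area of the projected silhouette
        # ellipse pi * fx * fy * R^2 / (d^2 - R^2), to ~1%
        import trimesh

        cam = _frontal_camera(640, 480)
        R, d = 100.0, 400.0
        sphere = trimesh.creation.icosphere(subdivisions=5, radius=R)
        v = sphere.vertices + [0, 0, d]
        cloud = render_depth(v, sphere.faces, cam, NoiseModel.noiseless())
        expected = np.pi * cam.fx * cam.fy * R**2 / (d**2 - R**2)
        assert len(cloud) == pytest.approx(expected, rel=0.01)

    def test_rear_hemisphere_absent(self):
        import trimesh

        cam = _frontal_camera()
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=80.0)
        v = sphere.vertices + [0, 0, 400.0]
        cloud = render_depth(v, sphere.faces, cam, NoiseModel.noiseless())
        # all rendered points lie on the near hemisphere (z < center)
        assert cloud.points[:, 2].max() < 400.0 + 1.0

    def test_self_occlusion_matches_ray_casting_oracle(self, phantom_small):
        # rendered depth equals the FIRST ray/mesh intersection on 1000
        # random hit pixels; oracle is a brute-force Moller-Trumbore
        # ray/triangle intersection over every triangle
        cam = _frontal_camera(200, 150)
        v = phantom_small.vertices + [0, 0, 450.0]
        cloud, depth, _ = render_depth(v, phantom_small.faces, cam,
                                       NoiseModel.noiseless(),
                                       return_buffers=True)

        tri = v[phantom_small.faces]  # (F, 3, 3)
        e1 = tri[:, 1] - tri[:, 0]
        e2 = tri[:, 2] - tri[:, 0]

        def first_hit_z(direction):
            h = np.cross(direction, e2)
            a = np.einsum("ij,ij->i", e1, h)
            near_parallel = np.abs(a) < 1e-12
            a = np.where(near_parallel, 1.0, a)
            s = -tri[:, 0]
            u = np.einsum("ij,ij->i", s, h) / a
            q = np.cross(s, e1)
            w = np.dot(q, direction) / a
            t = np.einsum("ij,ij->i", e2, q) / a
            hit = (~near_parallel & (u >= -1e-9) & (w >= -1e-9)
                   & (u + w <= 1 + 1e-9) & (t > 0))
            return np.min(t[hit] * direction[2]) if hit.any() else np.inf

        rng = np.random.default_rng(0)
        ys, xs = np.nonzero(np.isfinite(depth))
        pick = rng.choice(len(ys), size=1000, replace=False)
        got = depth[ys[pick], xs[pick]]
        for i, k in enumerate(pick):
            d = np.array([(xs[k] - cam.cx) / cam.fx,
                          (ys[k] - cam.cy) / cam.fy, 1.0])
            z_first = first_hit_z(d)
            assert np.isfinite(z_first)
            assert got[i] == pytest.approx(z_first, abs=0.2)

    def test_lateral_cameras_see_their_own_cheek(self, phantom_small,
                                                 cams_small):
        counts = []
        for cam in cams_small:
            cloud = render_depth(phantom_small.vertices, phantom_small.faces,
                                 cam, NoiseModel.noiseless(),
                                 face_labels=phantom_small.face_labels)
            counts.append({
                "left": int(np.sum(cloud.labels == REGION_CODES["cheek_left"])),
                "right": int(np.sum(cloud.labels == REGION_CODES["cheek_right"])),
                "forehead": int(np.sum(cloud.labels == REGION_CODES["forehead"])),
            })
        # camera 0 sits on the patient-left (+x) side
        assert counts[0]["left"] > 5 * counts[0]["right"]
        assert counts[1]["right"] > 5 * counts[1]["left"]
        assert counts[0]["forehead"] > 0 and counts[1]["forehead"] > 0

    def test_empty_frustum_warns_and_returns_empty(self, phantom_small):
        cam = _frontal_camera()
        v = phantom_small.vertices + [0, 0, -5000.0]  # behind the camera
        with pytest.warns(UserWarning, match="frustum"):
            cloud = render_depth(v, phantom_small.faces, cam)
        assert len(cloud) == 0

    def test_noise_statistics(self):
        # >= 1e5 pixels on a flat plane: mean error within 3 standard errors
        # of zero, sample sigma within 5% of the configured value
        cam = _frontal_camera(640, 480)
        v = np.array([[-1000.0, -1000, 450], [1000, -1000, 450],
                      [1000, 1000, 450], [-1000, 1000, 450]])
        f = np.array([[0, 1, 2], [0, 2, 3]])
        noise = NoiseModel.from_sigma_at(1.0, quantization_mm=0.0)
        _, depth, _ = render_depth(v, f, cam, noise,
                                   np.random.default_rng(1),
                                   return_buffers=True)
        err = depth[np.isfinite(depth)] - 450.0
        assert err.size >= 1e5
        se = 1.0 / np.sqrt(err.size)
        assert abs(err.mean()) < 3 * se
        assert abs(err.std() - 1.0) < 0.05

    def test_quantization_and_dropout(self):
        cam = _frontal_camera()
        v = np.array([[-1000.0, -1000, 453.3], [1000, -1000, 453.3],
                      [1000, 1000, 453.3], [-1000, 1000, 453.3]])
        f = np.array([[0, 1, 2], [0, 2, 3]])
        noise = NoiseModel(0.0, 0.25, 0.1, seed=2)
        _, depth, _ = render_depth(v, f, cam, noise, return_buffers=True)
        hit = np.isfinite(depth)
        frac = hit.mean()
        assert 0.85 < frac < 0.95  # ~10% dropout
        steps = depth[hit] / 0.25
        assert np.allclose(steps, np.round(steps), atol=1e-9)


class TestProtocols:
    def test_staircase_visits_66_poses(self):
        trace = single_axis_protocol(dwell_frames=1)
        assert len(trace) == 66
        # extremes are exactly +-5 mm and +-5 deg
        assert trace.sixdof[:, :3].max() == 5.0
        assert trace.sixdof[:, :3].min() == -5.0
        assert trace.sixdof[:, 3:].max() == 5.0
        assert trace.sixdof[:, 3:].min() == -5.0
        # one axis nonzero at a time
        assert np.all((np.abs(trace.sixdof) > 0).sum(axis=1) <= 1)

    def test_dwell_repeats_each_pose(self):
        trace = single_axis_protocol(dwell_frames=5)
        assert len(trace) == 66 * 5
        assert np.array_equal(trace.sixdof[0], trace.sixdof[4])

    def test_zero_range_collapses_to_single_pose(self):
        trace = single_axis_protocol(range_mm=0.0, range_deg=0.0,
                                     dwell_frames=1)
        assert len(trace) == 1
        assert np.allclose(trace.sixdof, 0.0)

    def test_smooth_trace_amplitude_bound_and_start(self):
        tr = smooth_trace(30.0, 3.0, 2.0, seed=1)
        assert np.allclose(tr.sixdof[0], 0.0, atol=1e-12)
        peaks = np.abs(tr.sixdof).max(axis=0)
        assert np.allclose(peaks[:3], 3.0, atol=1e-9)
        assert np.allclose(peaks[3:], 2.0, atol=1e-9)

    def test_smooth_trace_zero_amplitude(self):
        tr = smooth_trace(10.0, 0.0, 0.0, seed=1)
        assert np.allclose(tr.sixdof, 0.0)

    def test_smooth_trace_band_limited(self):
        # > 99% of spectral power below 0.5 Hz on every axis
        tr = smooth_trace(60.0, 5.0, 5.0, seed=2, frame_rate_hz=10.0)
        freqs = np.fft.rfftfreq(len(tr), d=0.1)
        for j in range(6):
            power = np.abs(np.fft.rfft(tr.sixdof[:, j])) ** 2
            below = power[freqs <= 0.5].sum()
            assert below / power.sum() > 0.99

    def test_smooth_trace_deterministic_per_seed(self):
        a = smooth_trace(10.0, 5.0, 5.0, seed=9)
        b = smooth_trace(10.0, 5.0, 5.0, seed=9)
        assert np.array_equal(a.sixdof, b.sixdof)


@pytest.fixture(scope="module")
def local_cloud():
    ph = make_phantom(HeadPhantomParams(n_lat=71, n_lon=72), seed=0)
    return SurfaceCloud(ph.vertices, labels=ph.labels)


class TestFacialDeformation:
    def test_zero_amplitude_is_identity(self, local_cloud):
        out = facial_deformation(local_cloud, "yawn", amplitude_mm=0.0)
        assert np.array_equal(out.points, local_cloud.points)

    def test_rigid_component_removed_by_construction(self, local_cloud):
        from surftrack.calibration import fit_rigid

        out = facial_deformation(local_cloud, "yawn", amplitude_mm=8.0,
                                 phase=0.5)
        t = fit_rigid(local_cloud.points, out.points)
        assert t.translation_norm() < 1e-6
        assert np.allclose(t.rotation, np.eye(3), atol=1e-6)

    def test_smile_confined_to_cheek_regions(self, local_cloud):
        out = facial_deformation(local_cloud, "smile", amplitude_mm=5.0,
                                 phase=0.5)
        moved = np.linalg.norm(out.points - local_cloud.points, axis=1) > 1e-9
        allowed = np.isin(local_cloud.labels,
                          [REGION_CODES["cheek_left"],
                           REGION_CODES["cheek_right"]])
        assert moved.any()
        assert np.all(allowed[moved])

    def test_peak_displacement_equals_amplitude_times_envelope(self, local_cloud):
        out = facial_deformation(local_cloud, "swallow", amplitude_mm=3.0,
                                 phase=0.5)
        peak = np.linalg.norm(out.points - local_cloud.points, axis=1).max()
        assert peak == pytest.approx(3.0, abs=1e-9)
        out = facial_deformation(local_cloud, "swallow", amplitude_mm=3.0,
                                 phase=0.25)
        peak = np.linalg.norm(out.points - local_cloud.points, axis=1).max()
        assert peak == pytest.approx(3.0 * np.sin(np.pi * 0.25), abs=1e-9)

    def test_unknown_mode_raises(self, local_cloud):
        with pytest.raises(ValueError, match="unknown mode"):
            facial_deformation(local_cloud, "sneeze", 1.0)

    def test_shake_free_mode_is_pure_rigid_hence_no_deformation(self, local_cloud):
        out = facial_deformation(local_cloud, "shake-free", amplitude_mm=5.0)
        assert np.array_equal(out.points, local_cloud.points)


class TestSimulateSession:
    def test_zero_trace_zero_noise_frames_identical(self, phantom_small,
                                                    cams_small):
        from surftrack.motion import MotionTrace

        trace = MotionTrace([0.0, 0.2, 0.4], np.zeros((3, 6)))
        frames, _ = simulate_session(phantom_small, trace, cams_small,
                                     NoiseModel.noiseless(), seed=1)
        p0 = frames.clouds[0].points
        for c in frames.clouds[1:]:
            assert np.array_equal(c.points, p0)

    def test_truth_is_commanded_trace_passthrough(self, phantom_small,
                                                  cams_small):
        trace = single_axis_protocol(range_mm=2.0, range_deg=0.0,
                                     dwell_frames=1)
        _, truth = simulate_session(phantom_small, trace, cams_small[:1],
                                    NoiseModel.noiseless(), seed=1)
        assert np.array_equal(truth.sixdof, trace.sixdof)
        assert np.array_equal(truth.t_s, trace.t_s)

    def test_fixed_seed_reproducible(self, phantom_small, cams_small):
        from surftrack.motion import MotionTrace

        trace = MotionTrace([0.0, 0.2], np.array([[0, 0, 0, 0, 0, 0],
                                                  [1.0, 0, 0, 0, 0, 0]]))
        noise = NoiseModel.from_sigma_at(1.0)
        a, _ = simulate_session(phantom_small, trace, cams_small, noise, seed=5)
        b, _ = simulate_session(phantom_small, trace, cams_small, noise, seed=5)
        for ca, cb in zip(a.clouds, b.clouds):
            assert np.array_equal(ca.points, cb.points)

    def test_deformation_applied_only_in_its_window(self, phantom_small,
                                                    cams_small):
        from surftrack.motion import MotionTrace

        trace = MotionTrace([0.0, 1.0, 2.0], np.zeros((3, 6)))
        ev = DeformationEvent("yawn", 0.5, 1.5, 8.0)
        frames, _ = simulate_session(phantom_small, trace, cams_small[:1],
                                     NoiseModel.noiseless(),
                                     deformations=[ev], seed=1)
        # frames 0 and 2 are outside the window and identical; frame 1 differs
        assert np.array_equal(frames.clouds[0].points, frames.clouds[2].points)
        assert (len(frames.clouds[1]) != len(frames.clouds[0])
                or not np.array_equal(frames.clouds[1].points,
                                      frames.clouds[0].points))
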