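import numpy as np
import pytest

from compresscan.errors import (
    EmptyContourError,
    InvalidGeometryError,
    InvalidInputError,
    InvalidPairingError,
    NonStarShapedError,
)
from compresscan.scan_geometry import (
    VibrationSequence,
    centroid,
    deformation_profile,
    extract_contour,
    label_left_right,
    load_stl,
    profile_from_points,
    radial_profile,
    resample_contour,
    save_stl_ascii,
    select_extreme_frames,
    slice_mesh,
    write_deformation_csv,
    write_profile_csv,
)
from compresscan.synthetic_data import (
    ContourSpec,
    DeformationFieldSpec,
    combine_meshes,
    deform_contour,
    make_contour,
    make_limb_mesh,
    make_vibration,
    render_contour,
)


def _polar_points(center, r, theta):
    return np.column_stack(
        [center[0] - r * np.sin(theta), center[1] + r * np.cos(theta)]
    )


class TestCentroid:
    def test_unit_square(self):
        pts = [(0, 0), (1, 0), (1, 1), (0, 1)]
        assert centroid(pts) == pytest.approx((0.5, 0.5))

    def test_translation_equivariance(self, circle_points, rng):
        tx, ty = rng.uniform(-100, 100, 2)
        c0 = centroid(circle_points)
        c1 = centroid(circle_points + np.array([tx, ty]))
        assert c1[0] == pytest.approx(c0[0] + tx)
        assert c1[1] == pytest.approx(c0[1] + ty)

    def test_uniform_circle_center(self):
        theta = np.arange(360) * (2 * np.pi / 360)
        pts = _polar_points((10.0, -3.0), 20.0, theta)
        c = centroid(pts)
        assert c[0] == pytest.approx(10.0, abs=1e-9)
        assert c[1] == pytest.approx(-3.0, abs=1e-9)

    def test_empty_raises(self):
        with pytest.raises(InvalidInputError):
            centroid(np.empty((0, 2)))


class TestRadialProfile:
    def test_circle_constant_radius(self, circle_points):
        angles, radii = radial_profile(circle_points, (128.0, 128.0), 360)
        np.testing.assert_allclose(radii, 50.0, rtol=1e-6)
        assert len(angles) == 360
        assert angles[0] == 0.0

    def test_point_distance_is_euclidean(self):
        # single ray toward a vertex at distance 5 (3-4-5 triangle)
        theta = np.arange(8) * (2 * np.pi / 8)
        pts = _polar_points((0.0, 0.0), 5.0, theta)
        _, radii = radial_profile(pts, (0.0, 0.0), 8)
        assert radii[0] == pytest.approx(5.0)

    def test_superellipse_closed_form(self):
        # |x/a|^4 + |y/a|^4 = 1 -> polar radius a / (cos^4 + sin^4)^(1/4)
        a = 50.0
        phi = np.linspace(0, 2 * np.pi, 4000, endpoint=False)
        r_true = a / (np.abs(np.cos(phi)) ** 4 + np.abs(np.sin(phi)) ** 4) ** 0.25
        pts = np.column_stack([r_true * np.cos(phi), r_true * np.sin(phi)])
        angles, radii = radial_profile(pts, (0.0, 0.0), 720)
        # convert measurement angles to standard polar for the closed form
        std = np.mod(angles + np.pi / 2, 2 * np.pi)
        expected = a / (np.abs(np.cos(std)) ** 4 + np.abs(np.sin(std)) ** 4) ** 0.25
        np.testing.assert_allclose(radii, expected, rtol=1e-3)

    def test_centroid_outside_raises(self, circle_points):
        with pytest.raises(NonStarShapedError):
            radial_profile(circle_points, (300.0, 300.0), 36)

    def test_translation_invariance(self, rng):
        spec = ContourSpec(
            base_radius=50.0,
            fourier_amplitudes=((2, 4.0, 0.3), (5, 1.5, 1.1)),
            n_vertices=720,
            center=(0.0, 0.0),
        )
        pts = make_contour(spec)
        offset = rng.uniform(-50, 50, 2)
        p0 = profile_from_points(pts, 1, "left", "control")
        p1 = profile_from_points(pts + offset, 1, "left", "control")
        np.testing.assert_allclose(p0.radii, p1.radii, atol=1e-9)

    def test_rotation_shifts_profile(self):
        spec = ContourSpec(
            base_radius=50.0,
            fourier_amplitudes=((2, 4.0, 0.0), (3, 2.0, 0.7)),
            n_vertices=720,
        )
        pts = make_contour(spec)
        n_angles = 360
        shift = 30  # 30 degrees on a 1-degree grid
        alpha = shift * 2 * np.pi / n_angles
        rot = np.array(
            [[np.cos(alpha), -np.sin(alpha)], [np.sin(alpha), np.cos(alpha)]]
        )
        _, radii = radial_profile(pts, centroid(pts), n_angles)
        _, radii_rot = radial_profile(pts @ rot.T, centroid(pts @ rot.T), n_angles)
        np.testing.assert_allclose(radii_rot, np.roll(radii, shift), atol=1e-6)


class TestResample:
    def test_preserves_perimeter_shape(self, circle_points):
        res = resample_contour(circle_points, 360)
        assert len(res) == 360
        r = np.hypot(res[:, 0] - 128.0, res[:, 1] - 128.0)
        np.testing.assert_allclose(r, 50.0, rtol=1e-4)

    def test_density_bias_removed(self):
        # heavily oversample one arc; vertex centroid biased before
        # resampling and centered afterwards
        t1 = np.linspace(0, np.pi / 4, 400, endpoint=False)
        t2 = np.linspace(np.pi / 4, 2 * np.pi, 100, endpoint=False)
        theta = np.concatenate([t1, t2])
        pts = _polar_points((0.0, 0.0), 30.0, theta)
        biased = centroid(pts)
        balanced = centroid(resample_contour(pts, 720))
        assert np.hypot(*balanced) < np.hypot(*biased) / 10


class TestExtractContour:
    def test_circle_image_round_trip(self):
        spec = ContourSpec(base_radius=50.0, n_vertices=720, center=(128.0, 128.0))
        pts = make_contour(spec)
        img = render_contour(pts, 512, 0.5)
        ext = extract_contour(img, pixel_scale=0.5)
        c = centroid(resample_contour(ext, 720))
        assert c[0] == pytest.approx(128.0, abs=0.5 * 0.5)
        assert c[1] == pytest.approx(128.0, abs=0.5 * 0.5)
        r = np.hypot(ext[:, 0] - c[0], ext[:, 1] - c[1])
        assert r.mean() == pytest.approx(50.0, abs=1.0)  # <= 1 px rasterization

    def test_all_black_raises(self):
        img = np.zeros((64, 64, 3), dtype=np.uint8)
        with pytest.raises(EmptyContourError):
            extract_contour(img)

    def test_largest_component_wins(self):
        img = np.zeros((200, 200, 3), dtype=np.uint8)
        img[20:70, 20:40] = (255, 255, 0)  # 1000 px blob
        img[150:155, 150:152] = (255, 255, 0)  # 10 px blob
        pts = extract_contour(img, pixel_scale=1.0)
        assert pts[:, 0].max() < 50  # boundary of the big blob only

    def test_ccw_orientation(self):
        img = np.zeros((100, 100, 3), dtype=np.uint8)
        img[30:70, 30:70] = (255, 255, 0)
        pts = extract_contour(img)
        x, y = pts[:, 0], pts[:, 1]
        area = 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
        assert area > 0

    def test_pixel_scale_equivariance(self):
        img = np.zeros((100, 100, 3), dtype=np.uint8)
        img[30:70, 30:70] = (255, 255, 0)
        p1 = extract_contour(img, pixel_scale=1.0)
        p2 = extract_contour(img, pixel_scale=2.0)
        np.testing.assert_allclose(p2, 2.0 * p1, rtol=1e-12)


class TestDeformationProfile:
    def test_identical_profiles_zero(self, circle_points):
        p = profile_from_points(circle_points, 4, "left", "control")
        q = profile_from_points(circle_points, 4, "left", "legging_1")
        dp = deformation_profile(p, q)
        np.testing.assert_allclose(dp.per_angle, 0.0, atol=1e-9)
        assert dp.mean == pytest.approx(0.0, abs=1e-9)

    def test_offset_circles_uniform_deformation(self):
        theta = np.arange(720) * (2 * np.pi / 720)
        control = _polar_points((0.0, 0.0), 60.0, theta)
        garment = _polar_points((5.0, 5.0), 58.0, theta)
        dp = deformation_profile(
            profile_from_points(control, 4, "left", "control"),
            profile_from_points(garment, 4, "left", "legging_1"),
        )
        np.testing.assert_allclose(dp.per_angle, 2.0, atol=1e-6)

    def test_negative_deformation_reported(self):
        theta = np.arange(720) * (2 * np.pi / 720)
        control = _polar_points((0.0, 0.0), 60.0, theta)
        garment = _polar_points((0.0, 0.0), 61.0, theta)  # bulge
        dp = deformation_profile(
            profile_from_points(control, 4, "left", "control"),
            profile_from_points(garment, 4, "left", "legging_1"),
        )
        assert dp.mean == pytest.approx(-1.0, abs=1e-6)

    def test_quadrant_summaries(self):
        theta = np.arange(720) * (2 * np.pi / 720)
        control = _polar_points((0.0, 0.0), 60.0, theta)
        # deformation concentrated anteriorly: 2 + 1*cos(2*theta) is
        # symmetric; use uniform field and check all quadrants agree
        garment = _polar_points((0.0, 0.0), 58.0, theta)
        dp = deformation_profile(
            profile_from_points(control, 4, "left", "control"),
            profile_from_points(garment, 4, "left", "legging_1"),
        )
        for name in ("anterior", "lateral", "posterior", "medial"):
            assert dp.quadrants[name] == pytest.approx(2.0, abs=1e-6)

    def test_mismatched_sections_raise(self, circle_points):
        p = profile_from_points(circle_points, 4, "left", "control")
        q = profile_from_points(circle_points, 5, "left", "legging_1")
        with pytest.raises(InvalidPairingError):
            deformation_profile(p, q)

    def test_mismatched_grids_raise(self, circle_points):
        p = profile_from_points(circle_points, 4, "left", "control", n_angles=360)
        q = profile_from_points(circle_points, 4, "left", "legging_1", n_angles=180)
        with pytest.raises(InvalidPairingError):
            deformation_profile(p, q)


class TestSliceMesh:
    def test_sphere_slice_is_unit_circle(self):
        # icosphere-ish: lat-long sphere with >5000 triangles
        nu, nv = 60, 50
        u = np.linspace(0, 2 * np.pi, nu, endpoint=False)
        v = np.linspace(-np.pi / 2, np.pi / 2, nv)
        uu, vv = np.meshgrid(u, v)
        x = (np.cos(vv) * np.cos(uu)).ravel()
        y = (np.cos(vv) * np.sin(uu)).ravel()
        z = np.sin(vv).ravel()
        verts = np.column_stack([x, y, z])
        faces = []
        for i in range(nv - 1):
            for j in range(nu):
                a = i * nu + j
                b = i * nu + (j + 1) % nu
                c = (i + 1) * nu + j
                d = (i + 1) * nu + (j + 1) % nu
                faces.append([a, b, c])
                faces.append([b, d, c])
        assert len(faces) >= 5000
        loops = slice_mesh(verts, np.asarray(faces), 0.0)
        assert len(loops) == 1
        x, y = loops[0][:, 0], loops[0][:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
        assert area == pytest.approx(np.pi, rel=0.01)

    def test_two_cylinder_legs(self):
        spec = ContourSpec(base_radius=40.0, n_vertices=180)
        leg = make_limb_mesh([(0.0, spec), (200.0, spec)])
        right = (leg[0] - np.array([60.0, 0.0, 0.0]), leg[1])
        left = (leg[0] + np.array([60.0, 0.0, 0.0]), leg[1])
        verts, faces = combine_meshes(right, left)
        loops = slice_mesh(verts, faces, 100.0)
        assert len(loops) == 2
        labelled = label_left_right(loops)
        assert centroid(labelled["right"])[0] < centroid(labelled["left"])[0]
        flipped = label_left_right(loops, flip=True)
        assert centroid(flipped["right"])[0] > centroid(flipped["left"])[0]

    def test_z_above_mesh_empty(self):
        spec = ContourSpec(base_radius=40.0, n_vertices=64)
        verts, faces = make_limb_mesh([(0.0, spec), (100.0, spec)])
        assert slice_mesh(verts, faces, 500.0) == []

    def test_loft_taper_midheight(self):
        lo = ContourSpec(base_radius=60.0, n_vertices=360)
        hi = ContourSpec(base_radius=40.0, n_vertices=360)
        verts, faces = make_limb_mesh([(0.0, lo), (100.0, hi)])
        loops = slice_mesh(verts, faces, 50.0)
        r = np.hypot(*(loops[0] - loops[0].mean(axis=0)).T)
        assert r.mean() == pytest.approx(50.0, abs=0.1)

    def test_stl_round_trip(self, tmp_path):
        spec = ContourSpec(base_radius=40.0, n_vertices=64)
        verts, faces = make_limb_mesh([(0.0, spec), (100.0, spec)])
        path = tmp_path / "limb.stl"
        save_stl_ascii(path, verts, faces)
        v2, f2 = load_stl(path)
        loops1 = slice_mesh(verts, faces, 50.0)
        loops2 = slice_mesh(v2, f2, 50.0)
        r1 = np.hypot(*(loops1[0] - loops1[0].mean(axis=0)).T).mean()
        r2 = np.hypot(*(loops2[0] - loops2[0].mean(axis=0)).T).mean()
        assert r2 == pytest.approx(r1, rel=1e-5)


class TestSelectExtremeFrames:
    def test_sinusoid_printed_displacement(self):
        seq = make_vibration(4.71, 60.0, 120.0, n_cycles=5)
        hi, lo, disp, interval = select_extreme_frames(seq)
        assert disp == pytest.approx(9.42)

    def test_monotone_ramp(self):
        seq = VibrationSequence(
            times=np.arange(10) / 120.0,
            vertical_position=np.arange(10, dtype=float),
            frame_rate=120.0,
        )
        hi, lo, disp, _ = select_extreme_frames(seq)
        assert (hi, lo) == (9, 0)
        assert disp == 9.0

    def test_first_occurrence_on_ties(self):
        seq = VibrationSequence(
            times=np.arange(6) / 120.0,
            vertical_position=np.array([0.0, 5.0, 0.0, 5.0, 0.0, 1.0]),
            frame_rate=120.0,
        )
        hi, lo, _, _ = select_extreme_frames(seq)
        assert hi == 1
        assert lo == 0

    def test_constant_sequence_warns(self):
        seq = VibrationSequence(
            times=np.arange(4) / 120.0,
            vertical_position=np.ones(4),
            frame_rate=120.0,
        )
        with pytest.warns(UserWarning, match="degenerate"):
            _, _, disp, _ = select_extreme_frames(seq)
        assert disp == 0.0


class TestWriters:
    def test_profile_csv(self, tmp_path, circle_points):
        p = profile_from_points(circle_points, 1, "left", "control", n_angles=16)
        path = tmp_path / "profile.csv"
        write_profile_csv(p, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "angle_deg,radius_mm"
        assert len(lines) == 17

    def test_deformation_csv(self, tmp_path, circle_points):
        p = profile_from_points(circle_points, 1, "left", "control", n_angles=8)
        q = profile_from_points(circle_points, 1, "left", "legging_1", n_angles=8)
        dp = deformation_profile(p, q)
        path = tmp_path / "deform.csv"
        write_deformation_csv([dp], path)
        lines = path.read_text().splitlines()
        assert lines[0] == "section,side,angle_deg,deformation_mm"
        assert len(lines) == 9
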