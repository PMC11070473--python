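import numpy as np
import pytest

from stemdepth import measurement as meas
from stemdepth import segmentation as seg
from stemdepth.camera_geometry import Point3D, align_depth_to_color
from stemdepth.exceptions import (
    FrameMismatchError,
    MeasurementFailedError,
    OpenContourError,
    ParameterError,
)
from stemdepth.measurement import measure_stem
from stemdepth.synthetic_scene import SceneSpec, render


def bar_contour(width=10, height=30, left=20):
    mask = np.zeros((height, 60), dtype=np.uint8)
    mask[5:height - 5, left:left + width] = 1
    return seg.internal_gradient_contour(mask), mask


class TestScanlineIntersections:
    def test_bar_edges_exact(self):
        contour, _ = bar_contour(width=10, left=20)
        (lc, lr), (rc, rr) = meas.scanline_intersections(contour, (25, 15))
        assert (lc, rc) == (20, 29)
        assert lr == rr == 15

    def test_row_above_mask_is_open(self):
        contour, _ = bar_contour()
        with pytest.raises(OpenContourError):
            meas.scanline_intersections(contour, (25, 1))

    def test_thick_contour_takes_inner_pixel(self):
        contour = np.zeros((10, 20), dtype=np.uint8)
        contour[5, [3, 4, 14, 15]] = 1     # 2-px-thick walls
        (lc, _), (rc, _) = meas.scanline_intersections(contour, (9, 5))
        assert (lc, rc) == (4, 14)

    def test_synthetic_width_matches_silhouette(self, default_scene):
        truth = default_scene.truth
        stem = seg.largest_component(seg.denoise(
            seg.hsv_otsu_segment(default_scene.rgb)))
        contour = seg.internal_gradient_contour(stem)
        row = 300
        center = (int(truth.axis_col_by_row[row]), row)
        (lc, _), (rc, _) = meas.scanline_intersections(contour, center)
        assert abs((rc - lc + 1) - truth.row_width_px[row]) <= 1


class TestEuclideanDistance:
    def test_coincident_points(self):
        p = Point3D(0.1, 0.2, 0.3, "color")
        assert meas.euclidean_distance(p, p) == 0.0

    def test_axis_aligned_pair(self):
        p = Point3D(0, 0, 0.6, "color")
        q = Point3D(0.025, 0, 0.6, "color")
        assert meas.euclidean_distance(p, q) == pytest.approx(25.0)

    def test_metric_properties(self, rng):
        pts = [Point3D.from_array(rng.normal(0, 1, 3), "depth") for _ in range(12)]
        for a in pts[:4]:
            for b in pts[4:8]:
                for c in pts[8:]:
                    dab = meas.euclidean_distance(a, b)
                    assert dab == meas.euclidean_distance(b, a) >= 0
                    assert dab <= (meas.euclidean_distance(a, c)
                                   + meas.euclidean_distance(c, b) + 1e-9)

    def test_frame_mismatch(self):
        with pytest.raises(FrameMismatchError):
            meas.euclidean_distance(Point3D(0, 0, 1, "color"),
                                    Point3D(0, 0, 1, "depth"))


@pytest.fixture(scope="module")
def frontal_setup(request):
    """Fronto-parallel noiseless scene with its derived pipeline rasters."""
    spec = SceneSpec(axis_direction=(0.0, 1.0, 0.0), color_noise_sd=0.0)
    scene = render(spec)
    aligned = align_depth_to_color(scene.depth, spec.cam)
    stem = seg.largest_component(seg.denoise(seg.hsv_otsu_segment(scene.rgb)))
    contour = seg.internal_gradient_contour(stem)
    return spec, scene, aligned, contour


class TestMeasureAtScanline:
    def test_frontoparallel_recovers_diameter(self, frontal_setup):
        spec, scene, aligned, contour = frontal_setup
        center = (int(scene.truth.axis_col_by_row[240]), 240)
        m = meas.measure_at_scanline(aligned, contour, center, spec.cam)
        # 2% geometric tolerance + one-pixel-equivalent at this fx and Z
        assert m.diameter_mm == pytest.approx(25.0, abs=0.5 + 1.0)

    def test_diameter_frame_invariance(self, frontal_setup):
        spec, scene, aligned, contour = frontal_setup
        center = (int(scene.truth.axis_col_by_row[250]), 250)
        m = meas.measure_at_scanline(aligned, contour, center, spec.cam)
        d_color = meas.euclidean_distance(m.p_left, m.p_right)
        d_depth = meas.euclidean_distance(m.p_left_depthframe,
                                          m.p_right_depthframe)
        assert abs(d_color - d_depth) < 1e-9
        assert abs(m.diameter_mm - d_depth) < 1e-9

    def test_center_mode_closed_form(self, frontal_setup):
        # with the shared center depth the measurement must equal the
        # pixel-footprint width scaled by Z/f exactly
        spec, scene, aligned, contour = frontal_setup
        center = (int(scene.truth.axis_col_by_row[260]), 260)
        m = meas.measure_at_scanline(aligned, contour, center, spec.cam,
                                     depth_source="center")
        w_px = m.right_px[0] - m.left_px[0] + 1
        expected = 1000.0 * w_px * m.depth_used / spec.cam.color.fx
        assert m.diameter_mm == pytest.approx(expected, abs=1e-9)

    def test_edge_ordering_invariant(self, frontal_setup):
        spec, scene, aligned, contour = frontal_setup
        center = (int(scene.truth.axis_col_by_row[270]), 270)
        m = meas.measure_at_scanline(aligned, contour, center, spec.cam)
        assert m.left_px[0] < m.center_px[0] < m.right_px[0]
        assert m.diameter_mm > 0

    def test_open_contour_row(self, frontal_setup):
        spec, scene, aligned, contour = frontal_setup
        with pytest.raises(OpenContourError):
            meas.measure_at_scanline(aligned, contour, (424, 2), spec.cam)

    def test_unknown_depth_source(self, frontal_setup):
        spec, scene, aligned, contour = frontal_setup
        with pytest.raises(ParameterError):
            meas.measure_at_scanline(aligned, contour, (424, 240), spec.cam,
                                     depth_source="edges")


class TestMeasureStem:
    def test_single_scanline_equals_aggregate(self, default_scene):
        res = measure_stem(default_scene.rgb, default_scene.depth,
                           default_scene.spec.cam, n_scanlines=1)
        assert res.diameter_mm == res.scanlines[0].diameter_mm

    def test_deterministic(self, default_scene):
        r1 = measure_stem(default_scene.rgb, default_scene.depth,
                          default_scene.spec.cam)
        r2 = measure_stem(default_scene.rgb, default_scene.depth,
                          default_scene.spec.cam)
        assert r1.diameter_mm == r2.diameter_mm
        assert [m.to_dict() for m in r1.scanlines] == \
               [m.to_dict() for m in r2.scanlines]

    def test_aggregate_within_scanline_range(self, default_scene):
        res = measure_stem(default_scene.rgb, default_scene.depth,
                           default_scene.spec.cam)
        ds = [m.diameter_mm for m in res.scanlines]
        assert min(ds) <= res.diameter_mm <= max(ds)

    def test_monotone_in_radius(self):
        measured = []
        for radius in (5.0, 9.0, 13.0, 18.0):
            spec = SceneSpec(radius_mm=radius, color_noise_sd=0.0)
            scene = render(spec)
            res = measure_stem(scene.rgb, scene.depth, spec.cam)
            measured.append(res.diameter_mm)
        assert all(a < b for a, b in zip(measured, measured[1:]))

    def test_absolute_roi(self, default_scene):
        res = measure_stem(default_scene.rgb, default_scene.depth,
                           default_scene.spec.cam, roi=(250, 300),
                           roi_absolute=True)
        assert all(250 <= m.center_px[1] <= 300 for m in res.scanlines)

    def test_invalid_scanline_count(self, default_scene):
        with pytest.raises(ParameterError):
            measure_stem(default_scene.rgb, default_scene.depth,
                         default_scene.spec.cam, n_scanlines=0)

    def test_all_invalid_depth_fails_with_reasons(self, default_scene):
        with pytest.raises(MeasurementFailedError) as err:
            measure_stem(default_scene.rgb,
                         np.zeros_like(default_scene.depth),
                         default_scene.spec.cam)
        assert len(err.value.reasons) == 3   # one reason per scanline


class TestAnnotatePointcloud:
    def test_coincident_vertex_turns_red(self):
        verts = np.array([[0, 0, 0.6], [0.1, 0, 0.6]], dtype=np.float32)
        cols = np.zeros((2, 3), dtype=np.uint8)
        out_v, out_c = meas.annotate_pointcloud(
            verts, cols, [Point3D(0, 0, 0.6, "depth")], radius_mm=1.0)
        assert tuple(out_c[0]) == (255, 0, 0)
        assert tuple(out_c[1]) == (0, 0, 0)
        assert len(out_v) == 3 and tuple(out_c[2]) == (255, 0, 0)

    def test_zero_radius_only_markers_red(self):
        verts = np.array([[0.0005, 0, 0.6]], dtype=np.float32)
        cols = np.zeros((1, 3), dtype=np.uint8)
        _, out_c = meas.annotate_pointcloud(
            verts, cols, [Point3D(0, 0, 0.6, "depth")], radius_mm=0.0)
        assert tuple(out_c[0]) == (0, 0, 0)

    def test_wrong_frame_rejected(self):
        with pytest.raises(FrameMismatchError):
            meas.annotate_pointcloud(np.zeros((1, 3)), None,
                                     [Point3D(0, 0, 0.6, "color")])

    def test_empty_cloud_warns(self):
        with pytest.warns(UserWarning):
            meas.annotate_pointcloud(np.empty((0, 3)), None,
                                     [Point3D(0, 0, 0.6, "depth")])

    def test_measured_edges_lie_on_cylinder(self, default_scene):
        res = measure_stem(default_scene.rgb, default_scene.depth,
                           default_scene.spec.cam)
        a = default_scene.truth.axis_point
        d = default_scene.truth.axis_direction
        r_m = default_scene.spec.radius_mm / 1000.0
        flip = np.array([1.0, -1.0, -1.0])
        for m in res.scanlines:
            for p in (m.p_left_depthframe, m.p_right_depthframe):
                xyz = p.as_array() * flip    # viewer -> pinhole depth frame
                w = xyz - a
                radial = np.linalg.norm(w - (w @ d) * d)
                assert radial == pytest.approx(r_m, abs=0.004)


class TestPinholeBaseline:
    def test_scaling(self):
        assert meas.pinhole_baseline(50, 100, 100) == pytest.approx(50.0)

    def test_zero_width(self):
        assert meas.pinhole_baseline(0, 100, 100) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            meas.pinhole_baseline(50, 0, 100)

    def test_error_grows_with_board_offset(self, frontal_setup):
        # checkerboard at the stem plane vs progressively farther behind it:
        # the baseline inherits a scale error proportional to the offset,
        # while the depth-based measurement is unaffected
        spec, scene, aligned, contour = frontal_setup
        cam = spec.cam
        row = 240
        width_px = scene.truth.row_width_px[row]
        z_stem = spec.axis_point[2]
        square_mm = 100.0
        errors = []
        for offset in (0.0, 0.05, 0.10, 0.20):
            z_board = z_stem + offset
            square_px = cam.color.fx * (square_mm / 1000.0) / z_board
            d = meas.pinhole_baseline(width_px, square_px, square_mm)
            errors.append(abs(d - scene.truth.diameter_mm))
        assert errors == sorted(errors)
        center = (int(scene.truth.axis_col_by_row[row]), row)
        depth_based = meas.measure_at_scanline(aligned, contour, center, cam)
        assert abs(depth_based.diameter_mm - 25.0) < errors[-1]
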