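import numpy as np
import pytest
from scipy import stats

import faceval as fv
from conftest import random_rigid
from faceval.errors import (DegenerateGeometryError, MissingLandmarkError,
                            ValidationError)


def canonical_frame_lms(extra=None):
    pts = {
        "TragionL": [60.0, 0.0, 0.0],
        "TragionR": [-60.0, 0.0, 0.0],
        "SuborbitalR": [-40.0, 70.0, 0.0],
        "Prn": [0.0, 90.0, -20.0],
    }
    if extra:
        pts.update(extra)
    return fv.LandmarkSet(pts)


class TestFacialFrame:
    def test_canonical_configuration(self):
        frame = fv.build_facial_frame(canonical_frame_lms())
        np.testing.assert_allclose(frame.origin, [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(frame.x_axis, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(frame.y_axis, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(frame.z_axis, [0, 0, 1], atol=1e-12)

    def test_equivariance_under_rigid_motion(self):
        rng = np.random.default_rng(21)
        q = random_rigid(rng)
        lms = canonical_frame_lms()
        moved = lms.transformed(q.apply)
        frame = fv.build_facial_frame(moved)
        np.testing.assert_allclose(frame.origin, q.apply(np.zeros(3)),
                                   atol=1e-9)
        np.testing.assert_allclose(frame.x_axis, q.rotation @ [1, 0, 0],
                                   atol=1e-9)
        np.testing.assert_allclose(frame.y_axis, q.rotation @ [0, 1, 0],
                                   atol=1e-9)
        np.testing.assert_allclose(frame.z_axis, q.rotation @ [0, 0, 1],
                                   atol=1e-9)

    def test_coincident_tragions_rejected(self):
        lms = fv.LandmarkSet({
            "TragionL": [0.0, 0, 0], "TragionR": [0.0, 0, 0],
            "SuborbitalR": [-40.0, 70, 0], "Prn": [0.0, 90, -20]})
        with pytest.raises(DegenerateGeometryError):
            fv.build_facial_frame(lms)

    def test_suborbital_on_tragion_line_rejected(self):
        lms = fv.LandmarkSet({
            "TragionL": [60.0, 0, 0], "TragionR": [-60.0, 0, 0],
            "SuborbitalR": [-40.0, 0, 0], "Prn": [0.0, 90, -20]})
        with pytest.raises(DegenerateGeometryError):
            fv.build_facial_frame(lms)


class TestCropRegion:
    def test_facial_crop_nontrivial(self, face_pair):
        _, mesh, lms = face_pair
        frame = fv.build_facial_frame(lms)
        cropped = fv.crop_region(mesh, lms, frame, "facial")
        assert 0 < cropped.n_vertices < mesh.n_vertices

    def test_perioral_subset_of_facial(self, face_pair):
        _, mesh, lms = face_pair
        frame = fv.build_facial_frame(lms)
        _, facial_idx = fv.crop_region(mesh, lms, frame, "facial",
                                       return_index=True)
        _, perioral_idx = fv.crop_region(mesh, lms, frame, "perioral",
                                         return_index=True)
        assert set(perioral_idx).issubset(set(facial_idx))

    def test_degenerate_vertical_order_rejected(self, face_pair):
        _, mesh, lms = face_pair
        swapped = fv.LandmarkSet(dict(lms.points) | {
            "Me'": lms["Sn"], "Sn": lms["Me'"]})
        frame = fv.build_facial_frame(swapped)
        with pytest.raises(ValidationError):
            fv.crop_region(mesh, swapped, frame, "perioral")

    def test_unknown_region_rejected(self, face_pair):
        _, mesh, lms = face_pair
        frame = fv.build_facial_frame(lms)
        with pytest.raises(ValidationError):
            fv.crop_region(mesh, lms, frame, "nasal")


def grid_plane(z=0.0, n=8):
    """Square grid in the x-y plane lifted to height z, normals +z."""
    xs = np.linspace(-5, 5, n)
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(),
                             np.full(n * n, float(z))])
    idx = np.arange(n * n).reshape(n, n)
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            faces.append([idx[i, j], idx[i + 1, j], idx[i + 1, j + 1]])
            faces.append([idx[i, j], idx[i + 1, j + 1], idx[i, j + 1]])
    return fv.TriangleMesh(verts, np.array(faces))


class TestDeviationField:
    def test_identical_meshes_zero(self, face_pair):
        _, mesh, _ = face_pair
        field = fv.deviation_field(mesh, mesh)
        np.testing.assert_allclose(field.signed_distances, 0.0, atol=1e-12)

    def test_parallel_plane_offset_signed(self):
        ref = grid_plane(0.0)
        test = grid_plane(0.5)
        field = fv.deviation_field(test, ref)
        np.testing.assert_allclose(field.signed_distances, 0.5, atol=1e-12)
        below = grid_plane(-0.5)
        field = fv.deviation_field(below, ref)
        np.testing.assert_allclose(field.signed_distances, -0.5, atol=1e-12)

    def test_rigid_invariance(self, small_face):
        _, mesh, lms = small_face
        spec = fv.DeformationSpec(bumps=(
            fv.Bump(center="Gl", width=15.0, amplitude=1.5),))
        test, _, _ = fv.apply_deformation(mesh, lms, spec)
        base = fv.deviation_field(test, mesh).signed_distances
        rng = np.random.default_rng(31)
        q = random_rigid(rng)
        moved = fv.deviation_field(
            fv.TriangleMesh(q.apply(test.vertices), test.faces),
            fv.TriangleMesh(q.apply(mesh.vertices), mesh.faces),
        ).signed_distances
        np.testing.assert_allclose(moved, base, atol=1e-9)

    def test_reference_without_faces_rejected(self):
        test = grid_plane(0.0)
        ref = fv.TriangleMesh([[0, 0, 0], [1, 0, 0]], np.zeros((0, 3)))
        with pytest.raises(ValidationError):
            fv.deviation_field(test, ref)


class TestRmse:
    def test_zero_distances(self):
        field = fv.DeviationField(np.zeros((3, 3)), [0.0, 0.0, 0.0])
        assert fv.rmse(field).rmse == 0.0

    def test_hand_evaluated_formula(self):
        field = fv.DeviationField(np.zeros((3, 3)), [1.0, 2.0, 2.0])
        assert fv.rmse(field).rmse == pytest.approx(np.sqrt(3.0), abs=1e-15)

    def test_constant_field(self):
        field = fv.DeviationField(np.zeros((5, 3)), [-0.7] * 5)
        assert fv.rmse(field).rmse == pytest.approx(0.7, abs=1e-15)

    def test_rmse_squared_is_mean_square(self):
        rng = np.random.default_rng(41)
        d = rng.normal(0, 1, 100)
        field = fv.DeviationField(np.zeros((100, 3)), d)
        summary = fv.rmse(field)
        assert summary.rmse ** 2 == pytest.approx(np.mean(d ** 2), abs=1e-12)

    def test_empty_field_rejected(self):
        with pytest.raises(ValidationError):
            fv.DeviationField(np.zeros((0, 3)), [])


class TestCohortSummary:
    def test_constant_cohort(self):
        s = fv.cohort_summary([1.0, 1.0, 1.0, 1.0])
        assert (s.mean, s.sd) == (1.0, 0.0)
        assert (s.ci_low, s.ci_high) == (1.0, 1.0)

    def test_two_values_vs_t_table(self):
        s = fv.cohort_summary([0.0, 2.0])
        assert s.mean == 1.0
        assert s.sd == pytest.approx(np.sqrt(2.0), abs=1e-12)
        half = stats.t.ppf(0.975, 1) * np.sqrt(2.0) / np.sqrt(2.0)
        assert s.ci_high - s.mean == pytest.approx(half, abs=1e-9)

    def test_printed_cohort_interval(self):
        # n=23, SD 0.24 around mean 1.26 must reproduce the published
        # 95% CI of 1.15-1.37 within print rounding
        half = stats.t.ppf(0.975, 22) * 0.24 / np.sqrt(23)
        assert half == pytest.approx(0.1038, abs=1e-4)
        assert 1.26 - half == pytest.approx(1.15, abs=0.01)
        assert 1.26 + half == pytest.approx(1.37, abs=0.01)

    def test_single_value_rejected(self):
        with pytest.raises(ValidationError):
            fv.cohort_summary([1.0])


class TestLandmarkDeviation:
    def test_identical_sets_zero(self, toy_lms):
        frame = fv.build_facial_frame(canonical_frame_lms())
        out = fv.landmark_deviation(toy_lms, toy_lms, frame)
        assert all(v.d == 0 for v in out.values())

    def test_3_4_5(self):
        frame = fv.build_facial_frame(canonical_frame_lms())
        ref = fv.LandmarkSet({"Prn": [0.0, 0, 0]})
        test = fv.LandmarkSet({"Prn": [0.3, 0.4, 0]})
        out = fv.landmark_deviation(test, ref, frame)["Prn"]
        assert (out.dx, out.dy, out.dz) == pytest.approx((0.3, 0.4, 0.0))
        assert out.d == pytest.approx(0.5)

    def test_pythagoras_invariant(self):
        frame = fv.build_facial_frame(canonical_frame_lms())
        rng = np.random.default_rng(51)
        for _ in range(20):
            ref = fv.LandmarkSet({"Prn": rng.uniform(-10, 10, 3)})
            test = fv.LandmarkSet({"Prn": rng.uniform(-10, 10, 3)})
            o = fv.landmark_deviation(test, ref, frame)["Prn"]
            assert o.d ** 2 == pytest.approx(o.dx ** 2 + o.dy ** 2 + o.dz ** 2,
                                             abs=1e-12)

    def test_missing_landmark_named(self, toy_lms):
        frame = fv.build_facial_frame(canonical_frame_lms())
        other = fv.LandmarkSet({"Prn": [0.0, 0, 0]})
        with pytest.raises(MissingLandmarkError, match="Sn"):
            fv.landmark_deviation(other, toy_lms, frame, names=["Sn"])


class TestColorize:
    def make_field(self, mesh, value):
        return fv.DeviationField(mesh.vertices,
                                 np.full(mesh.n_vertices, value))

    def test_zero_field_is_green(self):
        mesh = grid_plane(0.0, n=3)
        colored = fv.colorize(self.make_field(mesh, 0.0), mesh, limit=2.0)
        np.testing.assert_allclose(colored.colors,
                                   np.tile([0, 1, 0], (mesh.n_vertices, 1)))

    def test_positive_limit_is_red(self):
        mesh = grid_plane(0.0, n=3)
        colored = fv.colorize(self.make_field(mesh, 2.0), mesh, limit=2.0)
        np.testing.assert_allclose(colored.colors,
                                   np.tile([1, 0, 0], (mesh.n_vertices, 1)))

    def test_clamping_beyond_limit(self):
        mesh = grid_plane(0.0, n=3)
        at_limit = fv.colorize(self.make_field(mesh, -2.0), mesh, limit=2.0)
        beyond = fv.colorize(self.make_field(mesh, -4.0), mesh, limit=2.0)
        np.testing.assert_array_equal(at_limit.colors, beyond.colors)

    def test_invalid_limit_rejected(self):
        mesh = grid_plane(0.0, n=3)
        with pytest.raises(ValidationError):
            fv.colorize(self.make_field(mesh, 0.0), mesh, limit=0.0)

    def test_field_size_mismatch_rejected(self):
        mesh = grid_plane(0.0, n=3)
        field = fv.DeviationField(np.zeros((2, 3)), [0.0, 0.0])
        with pytest.raises(ValidationError):
            fv.colorize(field, mesh, limit=1.0)
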