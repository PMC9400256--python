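"""Distance field, ROI summaries, volume integration and the colour map."""

import numpy as np
import pytest
import trimesh

from palato3d import compute_distance_field, compute_volume, roi_report, summarize_roi
from palato3d.core import mesh_from_arrays
from palato3d.deviation import DistanceField, distance_ramp, export_distance_map
from palato3d.roi import RoiLabels


def _sheet(z, x0=0.0, x1=20.0, y0=0.0, y1=20.0, h=1.0):
    xs = np.arange(x0, x1 + 1e-9, h)
    ys = np.arange(y0, y1 + 1e-9, h)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    V = np.stack([X, Y, np.full_like(X, z)], axis=-1)
    nx, ny = len(xs), len(ys)
    idx = np.arange(nx * ny).reshape(nx, ny)
    f = np.vstack(
        [
            np.column_stack([idx[:-1, :-1].ravel(), idx[1:, :-1].ravel(), idx[1:, 1:].ravel()]),
            np.column_stack([idx[:-1, :-1].ravel(), idx[1:, 1:].ravel(), idx[:-1, 1:].ravel()]),
        ]
    )
    return mesh_from_arrays(V.reshape(-1, 3), f, weld=False)


def _all_roi1(mesh):
    return RoiLabels(np.ones(len(mesh.faces), dtype=np.int8))


class TestDistanceField:
    def test_coincident_surfaces_give_zero_valid_field(self):
        m = _sheet(0.0)
        fld = compute_distance_field(m, m)
        assert fld.valid.all()
        assert np.allclose(fld.distances, 0.0, atol=1e-12)

    def test_parallel_plates_signed_distance(self):
        ref = _sheet(0.0, -5, 25, -5, 25)
        act = _sheet(2.5)
        fld = compute_distance_field(act, ref)
        assert fld.valid.all()
        assert np.allclose(fld.distances, 2.5, atol=1e-9)
        below = _sheet(-1.0)
        fld2 = compute_distance_field(below, ref)
        assert np.allclose(fld2.distances, -1.0, atol=1e-9)

    def test_validity_filters_distance_and_angle(self):
        ref = _sheet(0.0, 0, 5, 0, 5)
        act = _sheet(2.0, 0, 30, 0, 5)  # overhangs the reference laterally
        fld = compute_distance_field(act, ref, max_distance=15.0, max_angle=60.0)
        inside = act.vertices.view(np.ndarray)[:, 0] <= 4.0
        assert fld.valid[inside].all()
        far = act.vertices.view(np.ndarray)[:, 0] >= 10.0
        assert not fld.valid[far].any()  # grazing angle to the sheet edge

    def test_palate_distances_recover_thickness_field(self, clean_run):
        sample, _, artifacts = clean_run
        fld = artifacts["field"]
        labels = artifacts["labels"]
        t = sample.ground_truth.per_vertex_thickness
        vids = np.unique(sample.gingiva.faces[labels.included].ravel())
        err = np.abs(fld.distances[vids] - t[vids])
        assert err.max() < 0.05


class TestSummaries:
    def test_constant_field_summary(self, clean_run):
        sample, _, artifacts = clean_run
        labels = artifacts["labels"]
        mesh = sample.gingiva
        c = 1.7
        fld = DistanceField(
            np.full(len(mesh.vertices), c),
            np.ones(len(mesh.vertices), bool),
            mesh.vertices.view(np.ndarray).copy(),
            np.zeros(len(mesh.vertices)),
        )
        rep = summarize_roi(fld, labels, mesh)
        from palato3d import surface_area

        for r in range(1, 6):
            row = rep.rows[f"ROI{r}"]
            assert row.mean_mm == pytest.approx(c, abs=1e-12)
            assert row.min_mm == row.max_mm == c
            assert row.area_mm2 == pytest.approx(
                surface_area(mesh, labels.faces_of(r)), rel=1e-9
            )

    def test_two_face_area_weighted_mean(self):
        # hand-computed: vertex distances {1,1,1} and {3,3,3} on two equal-area
        # faces -> area-weighted mean 2.0, min 1.0, max 3.0
        verts = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [5, 0, 0], [6, 0, 0], [5, 1, 0.0]]
        )
        faces = np.array([[0, 1, 2], [3, 4, 5]])
        mesh = mesh_from_arrays(verts, faces, weld=False)
        d = np.array([1.0, 1.0, 1.0, 3.0, 3.0, 3.0])
        fld = DistanceField(d, np.ones(6, bool), verts.copy(), np.zeros(6))
        labels = RoiLabels(np.ones(2, dtype=np.int8))
        rep = summarize_roi(fld, labels, mesh)
        row = rep.rows["ROI1"]
        assert row.mean_mm == pytest.approx(2.0, abs=1e-12)
        assert row.min_mm == 1.0 and row.max_mm == 3.0

    def test_invalid_face_removed_from_valid_area(self):
        verts = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [5, 0, 0], [6, 0, 0], [5, 1, 0.0]]
        )
        faces = np.array([[0, 1, 2], [3, 4, 5]])
        mesh = mesh_from_arrays(verts, faces, weld=False)
        valid = np.array([True, True, True, False, True, True])
        fld = DistanceField(np.ones(6), valid, verts.copy(), np.zeros(6))
        rep = summarize_roi(fld, RoiLabels(np.ones(2, np.int8)), mesh)
        assert rep.rows["ROI1"].area_mm2 == pytest.approx(0.5)  # one face left

    def test_empty_roi_reports_missing_not_zero(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]])
        mesh = mesh_from_arrays(verts, [[0, 1, 2]], weld=False)
        fld = DistanceField(np.ones(3), np.ones(3, bool), verts.copy(), np.zeros(3))
        rep = summarize_roi(fld, RoiLabels(np.array([1], np.int8)), mesh)
        assert np.isnan(rep.rows["ROI3"].mean_mm)


class TestVolume:
    def test_parallel_plates_slab_volume_exact(self):
        ref = _sheet(0.0, -5, 15, -5, 15)
        act = _sheet(2.0, 0, 10, 0, 10)  # area 100 mm^2
        fld = compute_distance_field(act, ref)
        labels = _all_roi1(act)
        rep = compute_volume(fld, labels, act)
        assert rep.rows["ROI1"].vol_mm3 == pytest.approx(200.0, abs=1e-9)
        assert rep.rows["ROI1"].ratio_mm == pytest.approx(2.0, abs=1e-12)

    def test_concentric_spheres_shell_volume(self):
        ref = trimesh.creation.icosphere(subdivisions=4, radius=20.0)
        act = trimesh.creation.icosphere(subdivisions=4, radius=22.0)
        fld = compute_distance_field(act, ref)
        rep = compute_volume(fld, _all_roi1(act), act)
        shell = 4.0 / 3.0 * np.pi * (22.0**3 - 20.0**3)
        assert rep.rows["ROI1"].vol_mm3 == pytest.approx(shell, rel=0.01)

    def test_ratio_identity_and_additivity(self, default_run):
        _, report, _ = default_run
        total = report.rows["total"]
        vol_sum = sum(report.rows[f"ROI{r}"].vol_mm3 for r in range(1, 6))
        area_sum = sum(report.rows[f"ROI{r}"].area_mm2 for r in range(1, 6))
        assert vol_sum == pytest.approx(total.vol_mm3, rel=1e-12)
        assert area_sum == pytest.approx(total.area_mm2, rel=1e-12)
        for key in ("ROI1", "ROI2", "ROI3", "ROI4", "ROI5", "total"):
            row = report.rows[key]
            assert row.ratio_mm * row.area_mm2 == pytest.approx(row.vol_mm3, rel=1e-9)

    def test_scaling_distances_scales_mean_and_volume(self, clean_run):
        sample, _, artifacts = clean_run
        fld, labels = artifacts["field"], artifacts["labels"]
        mesh = sample.gingiva
        k = 2.5
        scaled = DistanceField(fld.distances * k, fld.valid, fld.foot_points, fld.angles_deg)
        r1 = roi_report(fld, labels, mesh)
        rk = roi_report(scaled, labels, mesh)
        assert rk.rows["total"].mean_mm == pytest.approx(k * r1.rows["total"].mean_mm, rel=1e-9)
        # the frustum bottom is unchanged, so volume scaling holds to first order
        assert rk.rows["total"].vol_mm3 == pytest.approx(k * r1.rows["total"].vol_mm3, rel=0.02)

    def test_negative_distances_clipped_with_warning(self):
        ref = _sheet(0.0, -5, 15, -5, 15)
        act = _sheet(-1.0, 0, 10, 0, 10)
        fld = compute_distance_field(act, ref)
        with pytest.warns(UserWarning):
            rep = compute_volume(fld, _all_roi1(act), act)
        assert rep.rows["ROI1"].vol_mm3 == pytest.approx(0.0, abs=1e-12)


class TestColourMap:
    def test_ramp_anchors(self):
        assert np.array_equal(distance_ramp([0.0], 5.0)[0, :3], (0, 170, 0))
        assert np.array_equal(distance_ramp([5.0], 5.0)[0, :3], (139, 0, 0))
        assert np.array_equal(distance_ramp([99.0], 5.0)[0, :3], (139, 0, 0))

    def test_midpoint_colour_matches_direct_ramp_evaluation(self):
        # oracle: evaluate the piecewise-linear ramp at f = 1/2 directly
        f = 0.5
        anchors = [(0, (0, 170, 0)), (1 / 3, (255, 255, 0)), (2 / 3, (255, 0, 0)), (1, (139, 0, 0))]
        (f0, c0), (f1, c1) = anchors[1], anchors[2]
        w = (f - f0) / (f1 - f0)
        expect = np.rint(np.array(c0) + w * (np.array(c1) - np.array(c0)))
        got = distance_ramp([2.5, 2.5], 5.0)
        assert np.array_equal(got[0, :3], expect.astype(np.uint8))
        assert np.array_equal(got[0], got[1])

    def test_invalid_vertices_grey_and_ply_written(self, tmp_path):
        m = _sheet(0.0, 0, 5, 0, 5)
        n = len(m.vertices)
        valid = np.ones(n, bool)
        valid[0] = False
        fld = DistanceField(np.full(n, 1.0), valid, m.vertices.view(np.ndarray).copy(), np.zeros(n))
        out = export_distance_map(fld, m, 5.0, tmp_path / "map.ply")
        assert np.array_equal(np.asarray(out.visual.vertex_colors[0][:3]), (128, 128, 128))
        from palato3d import read_mesh

        back = read_mesh(tmp_path / "map.ply")
        assert np.array_equal(
            np.asarray(back.visual.vertex_colors), np.asarray(out.visual.vertex_colors)
        )
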