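"""Paramarginal / posterior boundaries and ROI band partitioning."""

import numpy as np
import pytest

from palato3d import (
    LandmarkSet,
    RigidTransform,
    build_roi_labels,
    paramarginal_boundary,
    partition_rois,
    posterior_boundary,
    surface_area,
)
from palato3d.core import BOUNDARY_LANDMARKS, mesh_from_arrays
from palato3d.errors import OrderingError, OrientationError, ProjectionError
from palato3d.roi import RoiParams
from palato3d.synthetic import perturb_pose


def _plane_mesh(x0=0.0, x1=30.0, y0=-10.0, y1=20.0, h=0.5):
    xs = np.arange(x0, x1 + 1e-9, h)
    ys = np.arange(y0, y1 + 1e-9, h)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    V = np.stack([X, Y, np.zeros_like(X)], axis=-1)
    nx, ny = len(xs), len(ys)
    idx = np.arange(nx * ny).reshape(nx, ny)
    f = np.vstack(
        [
            np.column_stack([idx[:-1, :-1].ravel(), idx[1:, :-1].ravel(), idx[1:, 1:].ravel()]),
            np.column_stack([idx[:-1, :-1].ravel(), idx[1:, 1:].ravel(), idx[:-1, 1:].ravel()]),
        ]
    )
    return mesh_from_arrays(V.reshape(-1, 3), f, weld=False)


def _plane_landmarks():
    """Straight sulcus along y=0; midpalatal reference toward +y."""
    lms = LandmarkSet()
    for x in np.linspace(0, 30, 16):
        lms.add("sulcus", "L", (x, 0.0, 0.0))
        lms.add("sulcus", "R", (x, 0.0, 0.0))
    for i, name in enumerate(BOUNDARY_LANDMARKS):
        lms.add(name, "L", (5.0, 8.0 + i, 0.0))
        lms.add(name, "R", (25.0, 8.0 + i, 0.0))
    return lms


class TestParamarginal:
    def test_planar_offset_matches_euclidean_strip(self):
        mesh = _plane_mesh()
        mask = paramarginal_boundary(mesh, _plane_landmarks(), offset=3.0)
        area = surface_area(mesh, mask)
        # analytic: strip y in [3, 20], x in [0, 30]; one face-diameter slack
        expect = 30.0 * 17.0
        assert abs(area - expect) < 30.0 * 1.0
        centroids = mesh.triangles_center[mask]
        assert centroids[:, 1].min() >= 3.0 - 0.5

    def test_zero_offset_keeps_full_palatal_side(self):
        mesh = _plane_mesh()
        mask = paramarginal_boundary(mesh, _plane_landmarks(), offset=0.0)
        centroids = mesh.triangles_center[mask]
        assert centroids[:, 1].min() >= -0.5  # nothing on the tooth side
        area = surface_area(mesh, mask)
        assert abs(area - 30.0 * 20.0) < 30.0 * 1.0

    def test_oversized_offset_empties_region_with_warning(self):
        mesh = _plane_mesh()
        with pytest.warns(UserWarning):
            mask = paramarginal_boundary(mesh, _plane_landmarks(), offset=100.0)
        assert mask.sum() == 0

    def test_increasing_offset_is_monotone(self):
        mesh = _plane_mesh()
        lms = _plane_landmarks()
        m3 = paramarginal_boundary(mesh, lms, offset=3.0)
        m5 = paramarginal_boundary(mesh, lms, offset=5.0)
        assert not np.any(m5 & ~m3)

    def test_far_sulcus_raises_projection_error(self):
        mesh = _plane_mesh()
        lms = _plane_landmarks()
        lms.add("sulcus", "L", (15.0, 0.0, 30.0))  # 30 mm off the surface
        with pytest.raises(ProjectionError):
            paramarginal_boundary(mesh, lms, offset=3.0)


class TestPosteriorBoundary:
    def test_plane_cut_matches_threshold_oracle(self, clean_palate):
        lms = LandmarkSet()
        for p in clean_palate.landmarks.points:
            if p.name != "posterior_border":
                lms.add(p.name, p.side, p.xyz)
        for x in np.linspace(-14, 14, 7):
            lms.add("posterior_border", "mid", (x, 40.0, 0.0))
        mask = posterior_boundary(clean_palate.gingiva, lms)
        y = clean_palate.gingiva.triangles_center[:, 1]
        assert not np.any(mask & (y > 40.0 + 1.0))
        assert np.all(mask[y < 40.0 - 1.0])

    def test_sample_order_invariance(self, clean_palate):
        lms1 = clean_palate.landmarks
        lms2 = LandmarkSet()
        border = [p for p in lms1.points if p.name == "posterior_border"]
        rest = [p for p in lms1.points if p.name != "posterior_border"]
        for p in rest:
            lms2.add(p.name, p.side, p.xyz)
        for p in border[::-1]:
            lms2.add(p.name, p.side, p.xyz)
        assert np.array_equal(
            posterior_boundary(clean_palate.gingiva, lms1),
            posterior_boundary(clean_palate.gingiva, lms2),
        )

    def test_border_at_mesh_edge_excludes_nothing(self, clean_palate):
        lms = LandmarkSet()
        for p in clean_palate.landmarks.points:
            if p.name != "posterior_border":
                lms.add(p.name, p.side, p.xyz)
        ymax = clean_palate.gingiva.vertices[:, 1].max()
        for x in np.linspace(-20, 20, 5):
            lms.add("posterior_border", "mid", (x, ymax + 1.0, 0.0))
        assert posterior_boundary(clean_palate.gingiva, lms).all()

    def test_border_anterior_of_molars_raises(self, clean_palate):
        lms = LandmarkSet()
        for p in clean_palate.landmarks.points:
            if p.name != "posterior_border":
                lms.add(p.name, p.side, p.xyz)
        for x in np.linspace(-14, 14, 5):
            lms.add("posterior_border", "mid", (x, 20.0, 0.0))  # anterior of M2
        with pytest.raises(OrientationError):
            posterior_boundary(clean_palate.gingiva, lms)


class TestPartition:
    def test_bands_match_y_threshold_oracle(self, clean_run):
        sample, _, artifacts = clean_run
        labels = artifacts["labels"]
        mesh_reg = sample.gingiva  # no perturbation: frames coincide
        y = mesh_reg.triangles_center[:, 1]
        edges = sample.spec.boundary_y
        for roi, (lo, hi) in enumerate(
            zip(np.concatenate([[-np.inf], edges]), np.concatenate([edges, [np.inf]])), start=1
        ):
            faces = labels.faces_of(roi)
            assert len(faces) > 0
            assert np.all(y[faces] > lo - 0.5)
            assert np.all(y[faces] < hi + 0.5)

    def test_partition_is_exact_and_additive(self, clean_run):
        sample, report, artifacts = clean_run
        labels = artifacts["labels"]
        counts = [len(labels.faces_of(r)) for r in range(1, 6)]
        assert sum(counts) == int(labels.included.sum())
        areas = [surface_area(sample.gingiva, labels.faces_of(r)) for r in range(1, 6)]
        total = surface_area(sample.gingiva, np.flatnonzero(labels.included))
        assert np.isclose(sum(areas), total, rtol=1e-12)

    def test_roi_indices_increase_anterior_to_posterior(self, clean_run):
        sample, _, artifacts = clean_run
        labels = artifacts["labels"]
        y = sample.gingiva.triangles_center[:, 1]
        medians = [np.median(y[labels.faces_of(r)]) for r in range(1, 6)]
        assert np.all(np.diff(medians) > 0)

    def test_coincident_landmarks_raise_ordering_error(self, clean_palate):
        lms = LandmarkSet()
        for p in clean_palate.landmarks.points:
            if p.name in BOUNDARY_LANDMARKS:
                lms.add(p.name, p.side, (0.0, 20.0, 5.0))  # all coincident
            else:
                lms.add(p.name, p.side, p.xyz)
        include = np.ones(len(clean_palate.gingiva.faces), dtype=bool)
        with pytest.raises(OrderingError):
            partition_rois(clean_palate.gingiva, include, lms)

    def test_labels_invariant_under_joint_rigid_transform(self, clean_palate):
        labels0 = build_roi_labels(clean_palate.gingiva, clean_palate.landmarks)
        moved, lms_m, _ = perturb_pose(clean_palate.gingiva, clean_palate.landmarks, 15, 8, seed=6)
        labels1 = build_roi_labels(moved, lms_m)
        assert np.array_equal(labels0.labels, labels1.labels)

    def test_labels_csv_round_trip(self, clean_palate, tmp_path):
        labels = build_roi_labels(clean_palate.gingiva, clean_palate.landmarks)
        labels.to_csv(tmp_path / "labels.csv")
        from palato3d.roi import RoiLabels

        back = RoiLabels.from_csv(tmp_path / "labels.csv")
        assert np.array_equal(back.labels, labels.labels)
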