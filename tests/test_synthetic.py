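"""Synthetic palate generator: determinism, calibration, ground-truth consistency."""

import numpy as np
import pytest

from palato3d import PalateSpec, generate_cohort, generate_palate, perturb_pose, voxelize_phantom
from palato3d.errors import ValidationError
from palato3d.segmentation import SegmentationParams, threshold_mask
from palato3d.synthetic import _integrate_ground_truth


class TestGeneration:
    def test_same_seed_bit_identical(self):
        a = generate_palate(PalateSpec(seed=42))
        b = generate_palate(PalateSpec(seed=42))
        assert np.array_equal(a.bone.vertices, b.bone.vertices)
        assert np.array_equal(a.gingiva.vertices, b.gingiva.vertices)
        assert np.array_equal(
            a.ground_truth.per_vertex_thickness, b.ground_truth.per_vertex_thickness
        )
        for p, q in zip(a.landmarks.points, b.landmarks.points):
            assert p.name == q.name and np.array_equal(p.xyz, q.xyz)

    def test_zero_profile_gingiva_coincides_with_bone(self):
        spec = PalateSpec(seed=1, roi_means=(0, 0, 0, 0, 0))
        s = generate_palate(spec)
        assert np.allclose(s.gingiva.vertices, s.bone.vertices, atol=1e-12)
        assert s.ground_truth.per_roi["total"]["vol_mm3"] == pytest.approx(0.0, abs=1e-9)

    def test_constant_thickness_recovered_downstream(self, tmp_path):
        from conftest import run_sample

        spec = PalateSpec(
            seed=2, roi_means=(2.0,) * 5, lateral_dip=0.0,
            thickness_noise_sd=0.0, patient_effect_sd=0.0,
        )
        s = generate_palate(spec)
        report, _ = run_sample(s, tmp_path / "const")
        for r in range(1, 6):
            row = report.rows[f"ROI{r}"]
            gt = s.ground_truth.per_roi[f"ROI{r}"]
            assert row.mean_mm == pytest.approx(2.0, abs=0.02)
            # the constant-offset construction is its own volume oracle: a
            # 2 mm shell under the concave vault holds slightly more than
            # 2 mm x top area (ratio ~2.04), so the ratio is checked against
            # the construction's true value rather than the nominal thickness
            assert gt["ratio_mm"] == pytest.approx(2.04, abs=0.01)
            assert row.ratio_mm == pytest.approx(gt["ratio_mm"], abs=0.02)

    def test_ground_truth_band_means_match_target_profile(self):
        spec = PalateSpec(seed=5, patient_effect_sd=0.0)
        s = generate_palate(spec)
        for r, target in enumerate(spec.roi_means, start=1):
            assert s.ground_truth.per_roi[f"ROI{r}"]["mean_mm"] == pytest.approx(
                target, abs=0.08
            )

    def test_too_coarse_resolution_rejected(self):
        with pytest.raises(ValidationError):
            PalateSpec(resolution=3.0)

    def test_crown_region_shared_between_meshes(self):
        s = generate_palate(PalateSpec(seed=7, vertex_noise_sd=0.0))
        seeds = s.landmarks.by_name("tooth_seed")
        v = s.bone.vertices.view(np.ndarray)
        for seed in seeds:
            near = np.linalg.norm(v[:, :2] - seed[:2], axis=1) < 3.0
            assert np.allclose(
                s.gingiva.vertices.view(np.ndarray)[near], v[near], atol=1e-12
            )


class TestGroundTruthConsistency:
    def test_ratio_identity(self, default_palate):
        for key, row in default_palate.ground_truth.per_roi.items():
            assert row["ratio_mm"] * row["area_mm2"] == pytest.approx(
                row["vol_mm3"], rel=1e-9
            )

    def test_reintegration_at_lower_refinement_agrees(self, default_palate):
        s = default_palate
        nx, ny = len(s.grid_x), len(s.grid_y)
        t = s.ground_truth.per_vertex_thickness.reshape(nx, ny)
        coarse = _integrate_ground_truth(s.spec, s.grid_x, s.grid_y, t, refine=1)
        mid = _integrate_ground_truth(s.spec, s.grid_x, s.grid_y, t, refine=2)
        for key in ("ROI1", "ROI3", "ROI5", "total"):
            a, m, b = coarse[key], mid[key], s.ground_truth.per_roi[key]
            # region-boundary quantisation shrinks with refinement: refine=2
            # is within 1% of the refine=4 reference and strictly closer than
            # refine=1 on the smallest band (ROI1)
            assert m["vol_mm3"] == pytest.approx(b["vol_mm3"], rel=0.01)
            assert m["mean_mm"] == pytest.approx(b["mean_mm"], abs=0.01)
            if key == "ROI1":
                assert abs(m["vol_mm3"] - b["vol_mm3"]) < abs(a["vol_mm3"] - b["vol_mm3"])

    def test_min_le_mean_le_max(self, default_palate):
        for row in default_palate.ground_truth.per_roi.values():
            assert row["min_mm"] <= row["mean_mm"] <= row["max_mm"]


class TestPerturbPose:
    def test_zero_bounds_identity(self, clean_palate):
        moved, lms, T = perturb_pose(clean_palate.gingiva, clean_palate.landmarks, 0.0, 0.0)
        assert np.allclose(T.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(moved.vertices, clean_palate.gingiva.vertices, atol=1e-12)

    def test_invertibility(self, clean_palate):
        moved, _, T = perturb_pose(clean_palate.gingiva, clean_palate.landmarks, 10, 5, seed=3)
        back = T.inverse().apply(moved.vertices)
        assert np.allclose(back, clean_palate.gingiva.vertices, atol=1e-9)

    def test_bounds_respected(self, clean_palate):
        for seed in range(5):
            _, _, T = perturb_pose(clean_palate.gingiva, clean_palate.landmarks, 10, 5, seed=seed)
            assert T.rotation_angle_deg() <= 10.0 + 1e-9
            assert np.linalg.norm(T.translation) <= 5.0 + 1e-9


class TestPhantom:
    def test_bone_window_selects_exactly_bone_voxels(self, clean_palate):
        grid = voxelize_phantom(clean_palate.bone, clean_palate.gingiva, spacing=0.3)
        mask = threshold_mask(grid, SegmentationParams(min_component_voxels=1, keep_largest=False))
        bone_vox = np.asarray(grid.data) == 1200
        assert np.array_equal(mask.data.astype(bool), bone_vox)
        assert not ((np.asarray(grid.data) == 60) & mask.data.astype(bool)).any()

    def test_tissue_voxel_count_matches_ground_truth_volume(self, clean_palate):
        sp = 0.1
        grid = voxelize_phantom(clean_palate.bone, clean_palate.gingiva, spacing=sp)
        tissue = float((np.asarray(grid.data) == 60).sum()) * sp**3
        assert tissue == pytest.approx(
            clean_palate.ground_truth.mucosa_total_vol_mm3, rel=0.02
        )

    def test_empty_meshes_give_air_grid(self):
        grid = voxelize_phantom(None, None)
        assert (np.asarray(grid.data) == -1000).all()


class TestCohort:
    def test_determinism_and_distinctness(self):
        a = generate_cohort(6, PalateSpec(seed=9))
        b = generate_cohort(6, PalateSpec(seed=9))
        totals_a = [s.ground_truth.per_roi["total"]["vol_mm3"] for s in a]
        totals_b = [s.ground_truth.per_roi["total"]["vol_mm3"] for s in b]
        assert totals_a == totals_b
        assert len(set(np.round(totals_a, 6))) == 6

    def test_single_patient_equals_direct_generation(self):
        spec = PalateSpec(seed=13)
        one = generate_cohort(1, spec)[0]
        child = int(np.random.default_rng(13).integers(0, 2**31 - 1, 1)[0])
        from dataclasses import replace

        direct = generate_palate(replace(spec, seed=child))
        assert np.array_equal(one.gingiva.vertices, direct.gingiva.vertices)

    def test_posterior_variance_grows(self, perturbed_cohort):
        samples, _, _ = perturbed_cohort
        means = np.array(
            [[s.ground_truth.per_roi[f"ROI{r}"]["mean_mm"] for r in range(1, 6)] for s in samples]
        )
        sds = means.std(axis=0, ddof=1)
        assert sds[4] == sds.max()
        assert sds[0] == sds.min()
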