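"""Shared fixtures: synthetic palates and pipeline runs reused across modules."""

import warnings

import numpy as np
import pytest

from palato3d import PalateSpec, generate_cohort, generate_palate
from palato3d.pipeline import PipelineConfig, run_pipeline
from palato3d.synthetic import perturb_pose


def run_sample(sample, out_dir, seed=1, gingiva=None, landmarks=None):
    """Run the full pipeline on a synthetic sample with in-memory objects."""
    config = PipelineConfig(out_dir=str(out_dir), seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(
            config,
            objects={
                "gingiva": gingiva if gingiva is not None else sample.gingiva,
                "bone": sample.bone,
                "landmarks": landmarks if landmarks is not None else sample.landmarks,
                "landmarks_bone": sample.landmarks,
            },
        )


@pytest.fixture(scope="session")
def clean_palate():
    """Noise-free palate: geometry errors only."""
    return generate_palate(PalateSpec(seed=3, thickness_noise_sd=0.0, patient_effect_sd=0.0))


@pytest.fixture(scope="session")
def default_palate():
    return generate_palate(PalateSpec(seed=42))


@pytest.fixture(scope="session")
def default_run(default_palate, tmp_path_factory):
    report, artifacts = run_sample(default_palate, tmp_path_factory.mktemp("run42"))
    return default_palate, report, artifacts


@pytest.fixture(scope="session")
def clean_run(clean_palate, tmp_path_factory):
    report, artifacts = run_sample(clean_palate, tmp_path_factory.mktemp("run3"))
    return clean_palate, report, artifacts


@pytest.fixture(scope="session")
def perturbed_cohort(tmp_path_factory):
    """20 patients, each pose-perturbed (<=10 deg / 5 mm) and re-registered.

    Returns (samples, reports, registration_errors) where registration_errors
    are (rotation_deg, translation_mm) of estimated-vs-applied transform.
    """
    out = tmp_path_factory.mktemp("cohort")
    samples = generate_cohort(20, PalateSpec(seed=0))
    reports, reg_errors = [], []
    for i, s in enumerate(samples):
        gingiva, lms, applied = perturb_pose(s.gingiva, s.landmarks, 10.0, 5.0, seed=1000 + i)
        report, artifacts = run_sample(s, out / s.patient_id, gingiva=gingiva, landmarks=lms)
        est = artifacts["transform"].transform
        err = est.compose(applied)
        reg_errors.append((err.rotation_angle_deg(), float(np.linalg.norm(err.translation))))
        reports.append(report)
    return samples, reports, reg_errors
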