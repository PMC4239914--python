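"""Shared fixtures: synthetic studies at the frozen study conditions.

The expensive end-to-end comparison (five seeded studies at default
noise plus one low-noise study) is computed once per session and shared
by every test that inspects fusion behaviour.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from fermfuse.pipeline import RunConfig, run_study, split_by_run
from fermfuse.preprocessing import enose_feature_matrix, spectra_feature_matrix
from fermfuse.synthetic_data import StudyConfig, StudyDesign, generate_study

DEFAULT_SEEDS = (1, 2, 3, 4, 5)
LOW_NOISE = dict(rep_noise_scale=0.005, run_effect_scale=0.001)


@pytest.fixture(scope="session")
def split_study():
    """One default-noise modality-split study (seed 0)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_study(config=StudyConfig.split_study(seed=0))


@pytest.fixture(scope="session")
def split_study_features(split_study):
    manifest, recordings, spectra = split_study
    return (
        manifest,
        enose_feature_matrix(recordings),
        spectra_feature_matrix(spectra),
    )


@pytest.fixture(scope="session")
def tiny_run_config():
    """A miniature study configuration for fast pipeline-level tests."""
    study = StudyConfig.split_study(seed=0)
    study.design = StudyDesign(n_runs=2, n_days=7, n_reps=2, seed=0)
    return RunConfig(study=study, train_runs=(1,), pc_candidates=(1, 2), seed=0)


@pytest.fixture(scope="session")
def fusion_experiment():
    """Five seeded comparisons at default noise + one low-noise run.

    Returns (default_reports, low_noise_report).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        defaults = [
            run_study(RunConfig(study=StudyConfig.split_study(seed=s), seed=s))
            for s in DEFAULT_SEEDS
        ]
        low = run_study(
            RunConfig(study=StudyConfig.split_study(seed=1, **LOW_NOISE), seed=1)
        )
    return defaults, low


def rates_by_model(report):
    return {
        row["model"]: {
            "latent": row["latent_vectors"],
            "train": row["training_rate"],
            "val": row["validation_rate"],
        }
        for row in report["comparison"]
    }
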