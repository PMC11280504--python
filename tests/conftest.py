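"""Shared fixtures: synthetic recordings, segmented cohorts, a trained model.

Expensive artefacts (the segmented default cohort and a trained autoencoder)
are session-scoped so the end-to-end tests share one training run.
"""

from __future__ import annotations

import numpy as np
import pytest

from fallscore import autoencoder as ae
from fallscore import segmentation as seg
from fallscore import synthetic_data as sd
from fallscore.kinematics import compute_angle_series

#: Scaled-down architecture used by every training test: same 3+3 bow-tie
#: topology with latent width 4, smaller hidden widths and few epochs so the
#: suite stays fast on one CPU.
SMALL_MODEL = dict(
    encoder_units=(16, 8, 4),
    decoder_units=(4, 8, 16),
    batch_size=32,
    learning_rate=3e-3,
    max_epochs=40,
    patience_epochs=12,
)


@pytest.fixture(scope="session")
def noise_free_spec() -> sd.CohortSpec:
    return sd.CohortSpec(healthy=sd.ClassParams(0.0, 0.0, 0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def noise_free_recording(noise_free_spec):
    return sd.generate_recording(noise_free_spec, "healthy", 7, "S1")


@pytest.fixture(scope="session")
def noise_free_series(noise_free_recording):
    return compute_angle_series(noise_free_recording)


def segment_cohort(spec: sd.CohortSpec) -> dict:
    """subject_id → repetitions for a generated cohort."""
    cohort = {}
    for rec in sd.generate_cohort(spec):
        reps = seg.extract_repetitions(
            compute_angle_series(rec),
            subject_id=rec.subject_id,
            class_label=rec.class_label,
        )
        if reps:
            cohort[rec.subject_id] = reps
    return cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default study cohort (40 HealthyAdult, 10 NonFaller, 10 at-risk)."""
    return segment_cohort(sd.CohortSpec(seed=11))


@pytest.fixture(scope="session")
def trained_model(default_cohort):
    """Autoencoder trained on the default cohort's healthy subjects."""
    healthy = sorted(s for s in default_cohort
                     if default_cohort[s][0].class_label == "HealthyAdult")
    train_reps = [r for s in healthy[:32] for r in default_cohort[s]]
    val_reps = [r for s in healthy[32:] for r in default_cohort[s]]
    cfg = ae.ModelConfig(**SMALL_MODEL, seed=1)
    return ae.train(ae.build_model(cfg), train_reps, val_reps, cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
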