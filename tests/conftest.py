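"""Shared fixtures.

The desk-scale study conditions are fixed here once: an 18-scan training
cohort of 64x64-pixel phantoms (12 frames each, 6 mm span), a u-net of
depth 3 with 8 base channels, and the standard optimiser regime for 20
epochs.  Training is expensive, so the trained model is a session fixture
shared by every test that needs one.
"""

from __future__ import annotations

import numpy as np
import pytest

from octowound.phantom import desk_geometry, generate_cohort
from octowound.segmentation import (
    TrainingConfig,
    UNetConfig,
    build_model,
    train,
)

TRAIN_N_SCANS = 18
TRAIN_BASE_SEED = 11
MODEL_SEED = 0


@pytest.fixture(scope="session")
def desk_geo():
    return desk_geometry()


@pytest.fixture(scope="session")
def training_cohort(desk_geo):
    stages = list(np.linspace(0, 1, TRAIN_N_SCANS))
    return generate_cohort(
        TRAIN_N_SCANS, stages, base_seed=TRAIN_BASE_SEED, geometry=desk_geo
    )


@pytest.fixture(scope="session")
def training_pairs(training_cohort, desk_geo):
    return [
        (scan.frames[i], labels.labels[i])
        for scan, labels, _ in training_cohort
        for i in range(desk_geo.n_frames)
    ]


@pytest.fixture(scope="session")
def trained_model(training_pairs):
    """Desk-scale u-net trained for 20 epochs under the standard regime."""
    model = build_model(
        UNetConfig(depth=3, base_channels=16, input_patch=(64, 64)),
        seed=MODEL_SEED,
    )
    model, record = train(model, training_pairs, TrainingConfig(seed=MODEL_SEED))
    return model, record
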