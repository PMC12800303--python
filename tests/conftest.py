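"""Shared fixtures: a desk-scale synthetic cohort and models trained on it.

The trained models are session-scoped because training, although small
(96 x 96 images, depth-3 / 8-channel networks), dominates suite runtime;
both the segmentation recovery tests and the end-to-end pipeline checks
reuse the same fitted models.
"""

from __future__ import annotations

import numpy as np
import pytest

from ivcmquant.io import rasterize_dc_mask, rasterize_nerve_mask
from ivcmquant.segmentation import ResUNetConfig, build_model, make_folds, train
from ivcmquant.synth import SynthParams, generate_cohort

DESK_SHAPE = (96, 96)
DESK_SEED = 7


@pytest.fixture(scope="session")
def desk_cohort():
    """8 subjects (4 per group), 6 frames each, at desk scale."""
    params = SynthParams(image_shape=DESK_SHAPE)
    return generate_cohort(n_subjects=4, images_per_eye=3, seed=DESK_SEED,
                           params=params)


@pytest.fixture(scope="session")
def desk_split(desk_cohort):
    """Subject-stratified split: folds 1-3 train, fold 0 held out."""
    subjects = sorted({c.subject_id for c in desk_cohort})
    folds = make_folds(subjects, k=4, seed=0)
    train_set = [c for c in desk_cohort if folds[c.subject_id] != 0]
    test_set = [c for c in desk_cohort if folds[c.subject_id] == 0]
    return train_set, test_set


@pytest.fixture(scope="session")
def desk_models(desk_split):
    """Nerve (binary) and DC (3-class) models trained on the cohort."""
    train_set, _ = desk_split
    nerve_cfg = ResUNetConfig(depth=3, base_channels=8, epochs=25,
                              batch_size=4, learning_rate=3e-3, seed=0)
    nerve_model = build_model(nerve_cfg)
    train(nerve_model,
          [(c.sample.image.pixels, rasterize_nerve_mask(c.sample.tracing, 4).data)
           for c in train_set],
          nerve_cfg)

    dc_cfg = ResUNetConfig(depth=3, base_channels=8, head="softmax3",
                           loss="dice_plus_ce", epochs=25, batch_size=4,
                           learning_rate=3e-3, seed=1)
    dc_model = build_model(dc_cfg)
    train(dc_model,
          [(c.sample.image.pixels, rasterize_dc_mask(c.sample.annotation).data)
           for c in train_set],
          dc_cfg)
    return {"nerve": nerve_model, "dc": dc_model}
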