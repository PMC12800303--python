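"""Residual U-Net behaviour, fold stratification, and desk-scale recovery."""

import numpy as np
import pytest

from ivcmquant import nn
from ivcmquant.io import rasterize_dc_mask, rasterize_nerve_mask
from ivcmquant.metrics import dice, specificity
from ivcmquant.segmentation import (
    ResUNetConfig,
    build_model,
    load_model,
    make_folds,
    predict_mask,
    save_model,
    train,
)
from ivcmquant.synth import SynthParams, generate_sample

TINY = ResUNetConfig(depth=3, base_channels=8, epochs=5, batch_size=2,
                     learning_rate=3e-3, seed=0)


class TestConfigAndForward:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ResUNetConfig(depth=1)
        with pytest.raises(ValueError):
            ResUNetConfig(base_channels=2)
        with pytest.raises(ValueError):
            ResUNetConfig(head="what")
        with pytest.raises(ValueError):
            ResUNetConfig(loss="hinge")

    def test_forward_preserves_shape(self):
        model = build_model(TINY)
        x = nn.Tensor(np.zeros((1, 1, 64, 64), dtype=np.float32))
        assert model.forward(x).shape == (1, 1, 64, 64)

    def test_softmax_head_probabilities_sum_to_one(self):
        cfg = ResUNetConfig(depth=3, base_channels=8, head="softmax3", seed=1)
        model = build_model(cfg)
        proba = model.predict_proba(np.random.default_rng(0).integers(
            0, 256, (2, 32, 32), dtype=np.uint8))
        assert proba.shape == (2, 3, 32, 32)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-5)

    def test_binary_head_probabilities_in_unit_interval(self):
        model = build_model(TINY)
        proba = model.predict_proba(np.zeros((1, 32, 32), dtype=np.uint8))
        assert np.all(proba > 0) and np.all(proba < 1)

    def test_indivisible_shape_rejected(self):
        model = build_model(ResUNetConfig(depth=4, base_channels=8))
        with pytest.raises(ValueError, match="divisible"):
            model.forward(nn.Tensor(np.zeros((1, 1, 36, 36), dtype=np.float32)))


class TestFolds:
    def test_ten_subjects_five_folds_of_two(self):
        folds = make_folds([f"s{i}" for i in range(10)], k=5, seed=0)
        sizes = np.bincount(list(folds.values()), minlength=5)
        assert sizes.tolist() == [2, 2, 2, 2, 2]

    def test_128_subjects_pigeonhole_sizes(self):
        folds = make_folds([f"s{i}" for i in range(128)], k=5, seed=1)
        sizes = sorted(np.bincount(list(folds.values()), minlength=5), reverse=True)
        assert sizes == [26, 26, 26, 25, 25]

    def test_deterministic_and_order_independent(self):
        ids = [f"s{i}" for i in range(12)]
        a = make_folds(ids, k=5, seed=3)
        b = make_folds(list(reversed(ids)) * 4, k=5, seed=3)  # images repeat subjects
        assert a == b

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], k=5)


def _nerve_pairs(n, shape=(32, 32), seed0=0):
    params = SynthParams(image_shape=shape, dc_with_per_image=0.0,
                         dc_without_per_image=0.0)
    pairs = []
    for seed in range(seed0, seed0 + n):
        s = generate_sample(params, seed=seed)
        pairs.append((s.image.pixels, rasterize_nerve_mask(s.tracing, 4).data))
    return pairs


class TestTraining:
    def test_loss_decreases(self):
        pairs = _nerve_pairs(8)
        cfg = ResUNetConfig(depth=3, base_channels=8, epochs=8, batch_size=4,
                            learning_rate=3e-3, seed=0)
        model = build_model(cfg)
        history = train(model, pairs, cfg)
        assert history[-1]["loss"] < history[0]["loss"]

    def test_overfit_two_images(self):
        """Capacity check: two frames memorized to Dice >= 0.95."""
        params = SynthParams(image_shape=(48, 48), nerves_per_image=(1, 2),
                             dc_with_per_image=0.0, dc_without_per_image=0.0)
        pairs = []
        for seed in (5, 6):
            s = generate_sample(params, seed=seed)
            pairs.append((s.image.pixels, rasterize_nerve_mask(s.tracing, 4).data))
        cfg = ResUNetConfig(depth=3, base_channels=16, epochs=300, batch_size=2,
                            learning_rate=1e-2, seed=0)
        model = build_model(cfg)
        train(model, pairs, cfg)
        dices = [dice(predict_mask(model, img).data, m) for img, m in pairs]
        assert min(dices) >= 0.95

    def test_seed_determinism(self):
        pairs = _nerve_pairs(4)
        cfg = ResUNetConfig(depth=2, base_channels=4, epochs=3, batch_size=2, seed=7)
        h1 = train(build_model(cfg), pairs, cfg)
        h2 = train(build_model(cfg), pairs, cfg)
        assert h1[-1]["loss"] == h2[-1]["loss"]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(build_model(TINY), [], TINY)


class TestPredictMask:
    def test_threshold_extremes(self):
        model = build_model(TINY)
        img = np.zeros((32, 32), dtype=np.uint8)
        assert predict_mask(model, img, threshold=0.0).data.all()
        assert not predict_mask(model, img, threshold=1.0).data.any()

    def test_softmax_head_returns_onehot(self):
        cfg = ResUNetConfig(depth=3, base_channels=8, head="softmax3", seed=2)
        mask = predict_mask(build_model(cfg), np.zeros((32, 32), dtype=np.uint8))
        assert mask.data.shape == (3, 32, 32)
        assert (mask.data.sum(axis=0) == 1).all()

    def test_checkpoint_round_trip(self, tmp_path):
        pairs = _nerve_pairs(2)
        cfg = ResUNetConfig(depth=2, base_channels=4, epochs=2, batch_size=2, seed=0)
        model = build_model(cfg)
        train(model, pairs, cfg)
        save_model(model, tmp_path / "m.npz")
        restored = load_model(tmp_path / "m.npz")
        img = pairs[0][0]
        np.testing.assert_array_equal(predict_mask(model, img).data,
                                      predict_mask(restored, img).data)


class TestDeskScaleRecovery:
    """Held-out performance on the shared synthetic cohort: these are
    direction-of-effect analogues of clinical-scale segmentation results,
    not reproductions of them."""

    def test_heldout_nerve_dice(self, desk_models, desk_split):
        _, test_set = desk_split
        dices = []
        for c in test_set:
            gt = rasterize_nerve_mask(c.sample.tracing, 4)
            pred = predict_mask(desk_models["nerve"], c.sample.image.pixels)
            dices.append(dice(pred.data, gt.data))
        assert np.mean(dices) >= 0.70

    def test_heldout_dc_specificity(self, desk_models, desk_split):
        _, test_set = desk_split
        specs = []
        for c in test_set:
            gt = rasterize_dc_mask(c.sample.annotation)
            pred = predict_mask(desk_models["dc"], c.sample.image.pixels)
            # foreground-vs-background specificity: true negatives are
            # background pixels predicted background
            specs.append(specificity(1 - pred.data[0], 1 - gt.data[0]))
        assert np.mean(specs) >= 0.99
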