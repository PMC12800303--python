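"""Residual U-Net segmentation of nerve fibers and dendritic cells.

The segmentation family integrates residual learning with the U-Net
encoder-decoder: pre-activation residual blocks at every resolution level,
2x2 max-pool downsampling, nearest-neighbour upsampling with skip
concatenation, and either a single-logit head (binary nerve mask, sigmoid)
or a 3-logit head (background / cells with dendrites / cells without
dendrites, softmax).

Model evaluation follows subject-stratified k-fold cross-validation: folds
are assigned per *subject*, never per image, so no subject's images leak
between training and validation folds.

Training is deterministic given the config seed (initialization and epoch
shuffling both derive from it) and runs on plain numpy — sized for
desk-scale cohorts, not clinical-scale datasets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import nn
from .io import ImageRecord, MaskKind, SegmentationMask

__all__ = [
    "ResUNetConfig",
    "ResUNet",
    "build_model",
    "make_folds",
    "train",
    "predict_mask",
    "save_model",
    "load_model",
]

_HEADS = ("binary_sigmoid", "softmax3")
_LOSSES = ("dice", "bce", "ce", "dice_plus_bce", "dice_plus_ce")


@dataclass(frozen=True)
class ResUNetConfig:
    """Hyperparameters of the residual U-Net family.

    ``depth`` counts encoder resolution levels; inputs must be divisible by
    ``2**(depth-1)``. The compound Dice + cross-entropy loss is the default
    for both heads; Dice counters the heavy background/foreground class
    imbalance typical of nerve and cell masks.
    """

    depth: int = 5
    base_channels: int = 16
    blocks_per_level: int = 1
    head: str = "binary_sigmoid"
    loss: str = "dice_plus_bce"
    epochs: int = 20
    batch_size: int = 4
    learning_rate: float = 3e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if self.head not in _HEADS:
            raise ValueError(f"head must be one of {_HEADS}")
        if self.loss not in _LOSSES:
            raise ValueError(f"loss must be one of {_LOSSES}")

    @property
    def out_channels(self) -> int:
        return 1 if self.head == "binary_sigmoid" else 3


class _ResBlock(nn.Module):
    """Pre-activation residual block: BN-ReLU-Conv x2 plus (projected) skip."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.bn1 = nn.BatchNorm2d(cin)
        self.conv1 = nn.Conv2d(cin, cout, 3, rng)
        self.bn2 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, rng)
        self.proj = nn.Conv2d(cin, cout, 1, rng) if cin != cout else None

    def __call__(self, x: nn.Tensor, training: bool) -> nn.Tensor:
        h = self.conv1(nn.relu(self.bn1(x, training)))
        h = self.conv2(nn.relu(self.bn2(h, training)))
        skip = self.proj(x) if self.proj is not None else x
        return h + skip


class ResUNetEncoder(nn.Module):
    """Encoder half, reusable for the length-regression network."""

    def __init__(self, config: ResUNetConfig, rng: np.random.Generator):
        self.config = config
        self.stem = nn.Conv2d(1, config.base_channels, 3, rng)
        self.levels: list[list[_ResBlock]] = []
        cin = config.base_channels
        for lvl in range(config.depth):
            cout = config.base_channels * 2**lvl
            blocks = [_ResBlock(cin if b == 0 else cout, cout, rng)
                      for b in range(config.blocks_per_level)]
            self.levels.append(blocks)
            cin = cout

    def __call__(self, x: nn.Tensor, training: bool) -> tuple[nn.Tensor, list[nn.Tensor]]:
        h = self.stem(x)
        skips: list[nn.Tensor] = []
        for lvl, blocks in enumerate(self.levels):
            for block in blocks:
                h = block(h, training)
            if lvl < len(self.levels) - 1:
                skips.append(h)
                h = nn.maxpool2(h)
        return h, skips


class ResUNet(nn.Module):
    """Encoder-decoder with residual blocks and skip connections."""

    def __init__(self, config: ResUNetConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.encoder = ResUNetEncoder(config, rng)
        self.dec_levels: list[list[_ResBlock]] = []
        base = config.base_channels
        for lvl in reversed(range(config.depth - 1)):
            cin = base * 2 ** (lvl + 1) + base * 2**lvl  # upsampled + skip
            cout = base * 2**lvl
            blocks = [_ResBlock(cin if b == 0 else cout, cout, rng)
                      for b in range(config.blocks_per_level)]
            self.dec_levels.append(blocks)
        self.head_bn = nn.BatchNorm2d(base)
        self.head_conv = nn.Conv2d(base, config.out_channels, 1, rng)

    def _check_shape(self, shape: tuple[int, ...]) -> None:
        factor = 2 ** (self.config.depth - 1)
        if shape[-2] % factor or shape[-1] % factor:
            raise ValueError(
                f"input spatial shape {shape[-2:]} must be divisible by {factor} "
                f"(depth {self.config.depth})"
            )

    def forward(self, x: nn.Tensor, training: bool = False) -> nn.Tensor:
        self._check_shape(x.shape)
        h, skips = self.encoder(x, training)
        for blocks, skip in zip(self.dec_levels, reversed(skips)):
            h = nn.upsample2(h)
            h = nn.concat(h, skip)
            for block in blocks:
                h = block(h, training)
        return self.head_conv(nn.relu(self.head_bn(h, training)))

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Per-pixel probabilities for a batch of (N, H, W) uint8/float images."""
        x = nn.Tensor(_to_batch(images))
        logits = self.forward(x, training=False).data
        if self.config.head == "binary_sigmoid":
            return nn.sigmoid_np(logits)[:, 0]
        return nn.softmax_np(logits, axis=1)


def build_model(config: ResUNetConfig) -> ResUNet:
    """Instantiate a residual U-Net with seeded initialization."""
    return ResUNet(config)


# ---------------------------------------------------------------------------
# Subject-stratified folds
# ---------------------------------------------------------------------------

def make_folds(subject_ids: Iterable[str], k: int = 5, seed: int = 0) -> dict[str, int]:
    """Assign each subject to one of ``k`` folds, sizes differing by <= 1.

    Fold membership depends only on the *set* of subjects and the seed, so
    shuffling image order can never move a subject between folds.
    """
    subjects = sorted(set(subject_ids))
    if len(subjects) < k:
        raise ValueError(f"need at least {k} subjects for {k} folds, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    return {subjects[idx]: i % k for i, idx in enumerate(order)}


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _to_batch(images: np.ndarray | Sequence) -> np.ndarray:
    """Stack images into a normalized (N, 1, H, W) float32 batch."""
    batch = np.asarray(images, dtype=np.float32)
    if batch.ndim == 2:
        batch = batch[None]
    return batch[:, None] / 255.0


def _prepare(dataset: Sequence[tuple], head: str) -> tuple[np.ndarray, np.ndarray]:
    images, masks = [], []
    for img, mask in dataset:
        arr = img.pixels if isinstance(img, ImageRecord) else np.asarray(img)
        images.append(np.asarray(arr, dtype=np.float32))
        m = mask.data if isinstance(mask, SegmentationMask) else np.asarray(mask)
        masks.append(np.asarray(m, dtype=np.float32))
    x = np.stack(images)[:, None] / 255.0
    y = np.stack(masks)
    if head == "binary_sigmoid" and y.ndim == 3:
        y = y[:, None]
    return x.astype(np.float32), y.astype(np.float32)


def _loss_fn(logits: nn.Tensor, y: np.ndarray, config: ResUNetConfig) -> nn.Tensor:
    binary = config.head == "binary_sigmoid"
    if config.loss == "dice":
        return (nn.dice_loss_binary if binary else nn.dice_loss_softmax)(logits, y)
    if config.loss == "bce":
        return nn.bce_loss(logits, y)
    if config.loss == "ce":
        return nn.softmax_ce_loss(logits, y)
    if binary:
        return nn.add_losses(nn.dice_loss_binary(logits, y), nn.bce_loss(logits, y))
    return nn.add_losses(nn.dice_loss_softmax(logits, y), nn.softmax_ce_loss(logits, y))


def _batch_dice(model: ResUNet, x: np.ndarray, y: np.ndarray) -> float:
    """Hard Dice of predictions vs targets (foreground channels for softmax)."""
    logits = model.forward(nn.Tensor(x), training=False).data
    if model.config.head == "binary_sigmoid":
        pred = (nn.sigmoid_np(logits) >= 0.5).astype(np.float32)
        tp = float((pred * y).sum())
        return 1.0 if pred.sum() + y.sum() == 0 else 2.0 * tp / float(pred.sum() + y.sum())
    cls = logits.argmax(axis=1)
    dices = []
    for c in (1, 2):
        p = (cls == c).astype(np.float32)
        t = y[:, c]
        denom = p.sum() + t.sum()
        dices.append(1.0 if denom == 0 else 2.0 * float((p * t).sum()) / float(denom))
    return float(np.mean(dices))


def train(
    model: ResUNet,
    dataset: Sequence[tuple],
    config: ResUNetConfig | None = None,
    val_dataset: Sequence[tuple] | None = None,
) -> list[dict]:
    """Train in place; returns per-epoch history of loss (and val Dice).

    ``dataset`` pairs images (uint8 arrays or :class:`ImageRecord`) with
    masks matching the head type. Deterministic given the config seed.
    """
    if config is None:
        config = model.config
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    x, y = _prepare(dataset, config.head)
    if config.head == "softmax3" and y.shape[1] != 3:
        raise ValueError("softmax3 head requires 3-channel one-hot masks")
    model._check_shape(x.shape)
    xv = yv = None
    if val_dataset:
        xv, yv = _prepare(val_dataset, config.head)

    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    history: list[dict] = []
    n = x.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            logits = model.forward(nn.Tensor(x[idx]), training=True)
            loss = _loss_fn(logits, y[idx], config)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        entry = {"epoch": epoch, "loss": float(np.mean(losses))}
        if xv is not None:
            entry["val_dice"] = _batch_dice(model, xv, yv)
        history.append(entry)
    return history


def predict_mask(model: ResUNet, image, threshold: float = 0.5) -> SegmentationMask:
    """Deterministic inference: thresholded sigmoid or per-pixel argmax.

    The binary head marks pixels with probability >= ``threshold``; the
    3-class head takes the per-pixel argmax and returns a one-hot mask.
    """
    arr = image.pixels if isinstance(image, ImageRecord) else np.asarray(image)
    proba = model.predict_proba(arr[None])
    if model.config.head == "binary_sigmoid":
        return SegmentationMask(MaskKind.NERVE_BINARY,
                                (proba[0] >= threshold).astype(np.uint8))
    cls = proba[0].argmax(axis=0)
    onehot = np.stack([(cls == c) for c in range(3)]).astype(np.uint8)
    return SegmentationMask(MaskKind.DC_ONEHOT, onehot)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_model(model: ResUNet, path: str | Path) -> None:
    """Save weights + config to an .npz checkpoint."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_arrays()
    np.savez_compressed(path, __config__=json.dumps(asdict(model.config)), **state)


def load_model(path: str | Path) -> ResUNet:
    """Rebuild a model from a checkpoint written by :func:`save_model`."""
    with np.load(path, allow_pickle=False) as data:
        config = ResUNetConfig(**json.loads(str(data["__config__"])))
        model = ResUNet(config)
        model.load_state_arrays({k: data[k] for k in data.files if k != "__config__"})
    return model
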