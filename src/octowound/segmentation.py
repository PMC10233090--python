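"""U-net segmentation of OCT frames into the seven tissue classes.

The training regime mirrors the study design: stochastic gradient descent
with momentum 0.9 at an initial learning rate of 0.05, L2 regularisation
1e-4, mini-batches of 16 whole frames, and reshuffling of the training
data at every epoch.  "Mini-batch accuracy" is the fraction of correctly
classified pixels in a training batch, tracked at every iteration; the
value at the final iteration summarises the run.

Frames are normalised per frame to [0, 1] by min-max scaling before they
enter the network, both in training and prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import N_CLASSES, LabelStack, OCTScan
from .unet import SGDMomentum, UNet, softmax_cross_entropy

__all__ = [
    "UNetConfig",
    "TrainingConfig",
    "TrainingRecord",
    "SegmentationModel",
    "DivergenceError",
    "build_model",
    "select_training_frames",
    "normalize_frame",
    "train",
    "predict_frame",
    "predict_scan",
    "save_model",
    "load_model",
]


class DivergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class UNetConfig:
    """Architecture of the u-net (desk scale by default)."""

    depth: int = 4
    base_channels: int = 16
    input_patch: tuple[int, int] = (64, 64)
    n_classes: int = N_CLASSES

    def __post_init__(self) -> None:
        if self.n_classes != N_CLASSES:
            raise ValueError(f"n_classes is fixed at {N_CLASSES}")
        f = 2**self.depth
        h, w = self.input_patch
        if h % f or w % f:
            raise ValueError(
                f"input_patch {h}x{w} must be divisible by 2**depth = {f}"
            )


@dataclass(frozen=True)
class TrainingConfig:
    """Optimiser settings; the defaults are the study's stated regime."""

    learning_rate: float = 0.05
    momentum: float = 0.9
    l2_regularisation: float = 1e-4
    batch_size: int = 16
    n_epochs: int = 20
    shuffle_each_epoch: bool = True
    gradient_clip_norm: float | None = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.momentum < 0 or self.l2_regularisation < 0:
            raise ValueError("rates must be positive")
        if self.batch_size < 1 or self.n_epochs < 1:
            raise ValueError("batch_size and n_epochs must be >= 1")


@dataclass
class TrainingRecord:
    """Per-iteration and per-epoch training metrics."""

    minibatch_accuracy: list[float] = field(default_factory=list)
    minibatch_loss: list[float] = field(default_factory=list)
    epoch_mean_loss: list[float] = field(default_factory=list)

    @property
    def final_minibatch_accuracy(self) -> float:
        return self.minibatch_accuracy[-1]

    def to_frame(self):
        """Metrics as a pandas DataFrame (iteration, loss, accuracy)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": np.arange(1, len(self.minibatch_loss) + 1),
                "loss": self.minibatch_loss,
                "minibatch_accuracy": self.minibatch_accuracy,
            }
        )


@dataclass
class SegmentationModel:
    """A u-net plus the configuration it was built with."""

    config: UNetConfig
    net: UNet

    @property
    def n_params(self) -> int:
        return self.net.n_params


def build_model(config: UNetConfig, seed: int = 0) -> SegmentationModel:
    """Build an untrained u-net: ``depth`` levels of two 3x3 convolutions,
    channels doubling per down level, skip concatenation on the way up,
    and a per-pixel 7-way softmax head at the input resolution."""
    net = UNet(config.depth, config.base_channels, config.n_classes, seed=seed)
    return SegmentationModel(config=config, net=net)


def normalize_frame(frame: np.ndarray) -> np.ndarray:
    """Per-frame min-max scaling to [0, 1] followed by mean subtraction.

    Zero-centred inputs are what keeps ReLU units alive under the hot
    momentum-SGD regime; constant frames map to all zeros.
    """
    f = np.asarray(frame, dtype=np.float32)
    lo, hi = float(f.min()), float(f.max())
    if hi - lo <= 0:
        return np.zeros_like(f)
    f = (f - lo) / (hi - lo)
    return f - f.mean()


def select_training_frames(
    cohort: list[tuple[OCTScan, LabelStack]],
    fraction: float,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified frame selection for annotation/training.

    Picks ``max(1, round(fraction * total_frames))`` (frame, label-frame)
    pairs, subject to covering every stratum (distinct scan ``stage``
    metadata value, falling back to one stratum per scan) at least once.
    Within each scan, frames are taken evenly spaced so wound centres and
    flanks are both represented.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if not cohort:
        raise ValueError("cohort is empty")
    total = sum(scan.geometry.n_frames for scan, _ in cohort)
    n_sel = max(1, round(fraction * total))

    # Group scans by stratum.
    strata: dict[object, list[int]] = {}
    for i, (scan, _) in enumerate(cohort):
        key = scan.metadata.get("stage", f"scan{i}")
        strata.setdefault(key, []).append(i)
    n_sel = max(n_sel, len(strata))

    # Allocate selections round-robin across strata, then evenly within scans.
    keys = sorted(strata, key=str)
    alloc = {k: 0 for k in keys}
    for j in range(n_sel):
        alloc[keys[j % len(keys)]] += 1
    pairs: list[tuple[np.ndarray, np.ndarray]] = []
    for k in keys:
        scan_ids = strata[k]
        per_scan = np.zeros(len(scan_ids), dtype=int)
        for j in range(alloc[k]):
            per_scan[j % len(scan_ids)] += 1
        for sid, m in zip(scan_ids, per_scan):
            scan, labels = cohort[sid]
            nf = scan.geometry.n_frames
            idx = np.unique(np.linspace(0, nf - 1, max(m, 0), dtype=int))
            for fi in idx:
                pairs.append((scan.frames[fi], labels.labels[fi]))
    return pairs


def _as_batches(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    order: np.ndarray,
    batch_size: int,
):
    for start in range(0, len(order), batch_size):
        ix = order[start : start + batch_size]
        x = np.stack([normalize_frame(pairs[i][0]) for i in ix])[..., None]
        y = np.stack([pairs[i][1] for i in ix])
        yield x, y


def train(
    model: SegmentationModel,
    pairs: list[tuple[np.ndarray, np.ndarray]],
    cfg: TrainingConfig,
) -> tuple[SegmentationModel, TrainingRecord]:
    """Train with momentum SGD and pixel-wise cross-entropy + L2 penalty.

    The training set is reshuffled every epoch under ``cfg.seed``; runs are
    bit-reproducible for a fixed seed.  Raises :class:`DivergenceError` on
    a non-finite loss.
    """
    if not pairs:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(cfg.seed)
    opt = SGDMomentum(
        model.net,
        cfg.learning_rate,
        cfg.momentum,
        cfg.l2_regularisation,
        clip_norm=cfg.gradient_clip_norm,
    )
    record = TrainingRecord()
    n = len(pairs)
    order = np.arange(n)
    for _epoch in range(cfg.n_epochs):
        if cfg.shuffle_each_epoch:
            order = rng.permutation(n)
        epoch_losses = []
        for x, y in _as_batches(pairs, order, cfg.batch_size):
            logits = model.net.forward(x, train=True)
            loss, dlogits, acc = softmax_cross_entropy(logits, y)
            if not np.isfinite(loss):
                raise DivergenceError(
                    "training loss is non-finite; try a lower learning rate"
                )
            model.net.backward(dlogits)
            opt.step()
            record.minibatch_loss.append(loss)
            record.minibatch_accuracy.append(acc)
            epoch_losses.append(loss)
        record.epoch_mean_loss.append(float(np.mean(epoch_losses)))
    return model, record


def _pad_to_multiple(frame: np.ndarray, f: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = frame.shape
    ph = (-h) % f
    pw = (-w) % f
    if ph or pw:
        frame = np.pad(frame, ((0, ph), (0, pw)), mode="reflect")
    return frame, (h, w)


def predict_frame(model: SegmentationModel, frame: np.ndarray) -> np.ndarray:
    """Per-pixel argmax class for one frame (ties -> lowest class code).

    Frames whose size is not divisible by ``2**depth`` are reflect-padded,
    predicted, and cropped back.
    """
    frame = np.asarray(frame)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    x = normalize_frame(frame)
    f = 2**model.config.depth
    x, (h, w) = _pad_to_multiple(x, f)
    logits = model.net.forward(x[None, ..., None], train=False)
    # np.argmax returns the first (lowest-code) class on exact ties.
    pred = np.argmax(logits[0], axis=-1).astype(np.uint8)
    return pred[:h, :w]


def predict_scan(model: SegmentationModel, scan: OCTScan) -> LabelStack:
    """Frame-wise prediction over a whole scan, preserving order/geometry."""
    preds = np.empty(scan.geometry.shape, dtype=np.uint8)
    for i in range(scan.geometry.n_frames):
        preds[i] = predict_frame(model, scan.frames[i])
    return LabelStack(
        geometry=scan.geometry,
        labels=preds,
        metadata={**scan.metadata, "source": "unet"},
    )


def save_model(model: SegmentationModel, path) -> None:
    """Single-file checkpoint: npz with an embedded JSON config header."""
    state = model.net.state_dict()
    header = json.dumps(
        {
            "depth": model.config.depth,
            "base_channels": model.config.base_channels,
            "input_patch": list(model.config.input_patch),
            "n_classes": model.config.n_classes,
        }
    )
    np.savez_compressed(path, __config__=np.frombuffer(header.encode(), np.uint8), **state)


def load_model(path) -> SegmentationModel:
    with np.load(path) as data:
        header = json.loads(bytes(data["__config__"]).decode())
        cfg = UNetConfig(
            depth=int(header["depth"]),
            base_channels=int(header["base_channels"]),
            input_patch=tuple(header["input_patch"]),
            n_classes=int(header["n_classes"]),
        )
        model = build_model(cfg)
        model.net.load_state_dict({k: v for k, v in data.items() if k != "__config__"})
    return model
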