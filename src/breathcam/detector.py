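"""The per-pixel respiration ROI detector: a 1-D residual CNN.

The detector looks at one pixel at a time: its input is an ``(l, 3)`` RGB
time series (z-scored per channel) and its output is the probability that
the temporal variance of that pixel carries respiration. Spatial layout is
deliberately invisible to the model — it must recognise breathing by its
temporal signature alone, which is what lets a model trained on one
subject generalise to others and to arbitrary body positions in frame.

Architecture: a stack of residual blocks (1-D convolutions along time,
kernel 3, first convolution of each block at stride 2 in place of
pooling, batch normalization + ReLU after each convolution, projection
shortcuts), global average pooling to a 128-dimensional embedding, and a
fully connected layer with batch normalization and a sigmoid output.
Binary cross-entropy is the training loss.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nnet
from .preprocessing import PixelWindow, Window, standardize_signals

__all__ = [
    "DetectorConfig", "Detector", "build_detector", "augment",
    "train_detector", "predict_roi", "TrainingReport",
    "save_detector", "load_detector",
]

log = logging.getLogger(__name__)

KERNEL_SIZE = 3       # fixed for every convolution
EMBEDDING_WIDTH = 128  # width of the global-average-pooled feature vector


@dataclass(frozen=True)
class DetectorConfig:
    """Architecture and training hyperparameters of the ROI detector."""

    block_widths: tuple = (16, 32, 64, 128)
    threshold: float = 0.5
    epochs: int = 15
    batch_size: int = 256
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    val_fraction: float = 0.1
    seed: int = 0
    # augmentation ranges: per-channel scale, additive shift (8-bit units),
    # sign-inversion probability
    aug_scale_range: tuple = (0.5, 2.0)
    aug_shift_range: tuple = (-20.0, 20.0)
    aug_invert_p: float = 0.5
    n_augment: int = 1  # augmented copies appended per training window

    def __post_init__(self):
        if self.block_widths[-1] != EMBEDDING_WIDTH:
            raise ValueError(
                f"final block width must equal the embedding width {EMBEDDING_WIDTH}"
            )
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class TrainingReport:
    epoch_loss: list = field(default_factory=list)
    epoch_val_accuracy: list = field(default_factory=list)
    n_train: int = 0
    n_val: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


class Detector:
    """The assembled network plus its configuration."""

    def __init__(self, config: DetectorConfig, input_len: int):
        self.config = config
        self.input_len = input_len
        rng = np.random.default_rng(config.seed)
        lengths = [input_len]
        for _ in config.block_widths:
            lengths.append(nnet.conv_out_len(lengths[-1], 2))
        if any(l < 2 for l in lengths[1:]):
            # each stride-2 block must leave >= 2 time steps to halve again
            max_blocks, l = 0, input_len
            while nnet.conv_out_len(l, 2) >= 2:
                l = nnet.conv_out_len(l, 2)
                max_blocks += 1
            raise ValueError(
                f"input length {input_len} supports at most {max_blocks} stride-2 "
                f"blocks; {len(config.block_widths)} requested"
            )
        self.temporal_lengths = lengths[1:]
        self.blocks = []
        c_in = 3
        for c_out in config.block_widths:
            self.blocks.append(nnet.ResidualBlock(c_in, c_out, KERNEL_SIZE, rng))
            c_in = c_out
        self.gap = nnet.GlobalAvgPool()
        self.fc = nnet.Dense(EMBEDDING_WIDTH, 1, rng)
        self.bn_out = nnet.BatchNorm(1)

    # -- plumbing -----------------------------------------------------------
    def params(self) -> list[nnet.Param]:
        ps = []
        for blk in self.blocks:
            ps += blk.params()
        ps += self.fc.params() + self.bn_out.params()
        return ps

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(B, l, 3) standardized input -> (B,) pre-sigmoid logits."""
        if x.shape[1] != self.input_len:
            raise ValueError(
                f"window length {x.shape[1]} does not match detector input "
                f"length {self.input_len}"
            )
        y = x
        for blk in self.blocks:
            y = blk.forward(y, train)
        y = self.gap.forward(y, train)
        y = self.bn_out.forward(self.fc.forward(y, train), train)
        return y[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.fc.backward(self.bn_out.backward(dlogits[:, None]))
        g = self.gap.backward(g)
        for blk in reversed(self.blocks):
            g = blk.backward(g)

    def predict_proba(self, x: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        """Respiration probability per standardized window, shape (B,)."""
        out = np.empty(x.shape[0])
        for i in range(0, x.shape[0], batch_size):
            out[i:i + batch_size] = nnet.sigmoid(
                self.forward_logits(x[i:i + batch_size], train=False)
            )
        return out

    # -- serialisation ------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for i, p in enumerate(self.params()):
            state[f"param_{i}"] = p.value
        bns = [l for blk in self.blocks
               for l in (blk.bn1, blk.bn2, blk.bn_proj)] + [self.bn_out]
        for i, bn in enumerate(bns):
            state[f"bn_{i}_mean"] = bn.running_mean
            state[f"bn_{i}_var"] = bn.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value[...] = state[f"param_{i}"]
        bns = [l for blk in self.blocks
               for l in (blk.bn1, blk.bn2, blk.bn_proj)] + [self.bn_out]
        for i, bn in enumerate(bns):
            bn.running_mean[...] = state[f"bn_{i}_mean"]
            bn.running_var[...] = state[f"bn_{i}_var"]


def build_detector(config: DetectorConfig, input_len: int) -> Detector:
    """Instantiate the residual network for windows of ``input_len`` samples."""
    return Detector(config, input_len)


def augment(window: PixelWindow | np.ndarray, seed=None,
            config: DetectorConfig = DetectorConfig()) -> PixelWindow | np.ndarray:
    """Randomly scale, shift and sign-invert each RGB channel independently.

    Emulates variation in clothing and background colour so the detector
    keys on the temporal pattern rather than absolute intensities. The
    label is unaffected: scaling/shifting preserves correlation up to sign
    and the label depends on |r| only.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sig = window.signal if isinstance(window, PixelWindow) else np.asarray(window, float)
    lo_s, hi_s = config.aug_scale_range
    lo_o, hi_o = config.aug_shift_range
    scale = rng.uniform(lo_s, hi_s, size=3)
    shift = rng.uniform(lo_o, hi_o, size=3)
    sign = np.where(rng.random(3) < config.aug_invert_p, -1.0, 1.0)
    out = sig * (scale * sign) + shift
    if isinstance(window, PixelWindow):
        return PixelWindow(signal=out, x=window.x, y=window.y,
                           start_s=window.start_s, rate_hz=window.rate_hz)
    return out


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)).mean())


def train_detector(
    windows: np.ndarray,
    labels: np.ndarray,
    config: DetectorConfig = DetectorConfig(),
) -> tuple[Detector, TrainingReport]:
    """Train the ROI detector on raw ``(N, l, 3)`` pixel windows.

    Augmented copies (``config.n_augment`` per window) are appended before
    per-channel standardization. Minimises binary cross-entropy with Adam;
    a held-out fraction tracks validation accuracy each epoch. All
    randomness flows from ``config.seed``.
    """
    windows = np.asarray(windows, dtype=float)
    labels = np.asarray(labels, dtype=float).ravel()
    if windows.shape[0] != labels.size:
        raise ValueError("windows and labels must align")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError(
            "training set contains a single class; both respiration and "
            "non-respiration windows are required"
        )
    rng = np.random.default_rng(config.seed)

    if config.n_augment > 0:
        aug = [windows]
        for _ in range(config.n_augment):
            aug.append(np.stack([augment(w, rng, config) for w in windows]))
        windows = np.concatenate(aug)
        labels = np.tile(labels, config.n_augment + 1)

    x = standardize_signals(windows)
    n = x.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.val_fraction * n))) if config.val_fraction > 0 else 0
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if np.unique(labels[train_idx]).size < 2:
        raise ValueError("validation split left a single-class training set")

    det = build_detector(config, input_len=x.shape[1])
    opt = nnet.Adam(det.params(), lr=config.learning_rate)
    report = TrainingReport(n_train=train_idx.size, n_val=val_idx.size)

    xt, yt = x[train_idx], labels[train_idx]
    for epoch in range(config.epochs):
        order = rng.permutation(train_idx.size)
        losses = []
        for i in range(0, order.size, config.batch_size):
            bi = order[i:i + config.batch_size]
            xb, yb = xt[bi], yt[bi]
            logits = det.forward_logits(xb, train=True)
            p = nnet.sigmoid(logits)
            losses.append(_bce(p, yb) * bi.size)
            opt.zero_grad()
            det.backward((p - yb) / bi.size)
            opt.step()
        loss = float(np.sum(losses) / order.size)
        if n_val:
            pv = det.predict_proba(x[val_idx])
            acc = float(((pv >= config.threshold) == (labels[val_idx] >= 0.5)).mean())
        else:
            acc = float("nan")
        report.epoch_loss.append(loss)
        report.epoch_val_accuracy.append(acc)
        log.info("epoch %d: loss %.4f, val acc %.4f", epoch + 1, loss, acc)
    return det, report


@dataclass
class ROIProbabilityMap:
    probabilities: np.ndarray  # (H, W) in [0, 1]
    window_start_s: float


@dataclass
class ROIMask:
    mask: np.ndarray  # (H, W) bool
    threshold: float
    window_start_s: float


def predict_roi(
    window: Window, detector: Detector, threshold: float | None = None
) -> tuple[ROIProbabilityMap, ROIMask]:
    """Classify every pixel of a window; threshold the probability map."""
    if threshold is None:
        threshold = detector.config.threshold
    if window.length != detector.input_len:
        raise ValueError(
            f"window length {window.length} does not match detector input "
            f"length {detector.input_len}"
        )
    sig = standardize_signals(window.pixel_signals())
    probs = detector.predict_proba(sig)
    h, w = window.frames.shape[1:3]
    pm = probs.reshape(h, w)
    return (
        ROIProbabilityMap(probabilities=pm, window_start_s=window.start_s),
        ROIMask(mask=pm >= threshold, threshold=threshold,
                window_start_s=window.start_s),
    )


def save_detector(detector: Detector, path) -> None:
    """Write weights (npz) plus a JSON sidecar with the configuration."""
    path = Path(path)
    np.savez(path, input_len=np.array(detector.input_len), **detector.state_arrays())
    cfg = asdict(detector.config)
    path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))


def load_detector(path) -> Detector:
    path = Path(path)
    cfg_raw = json.loads(path.with_suffix(".json").read_text())
    for key in ("block_widths", "aug_scale_range", "aug_shift_range"):
        cfg_raw[key] = tuple(cfg_raw[key])
    config = DetectorConfig(**cfg_raw)
    with np.load(path) as state:
        det = Detector(config, input_len=int(state["input_len"]))
        det.load_state_arrays({k: state[k] for k in state.files})
    return det
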