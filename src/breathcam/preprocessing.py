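"""Video preprocessing: spatial/temporal downsampling, windowing, z-scoring.

Raw capture is nominally 640x480 RGB, 8-bit, 20 fps. The pipeline reduces
the spatial resolution by block averaging (a factor of 8 for the nominal
capture) and resamples to 5 fps before any per-pixel analysis: averaging
suppresses sensor noise and cuts the per-frame pixel count by the square of
the factor, and 5 fps comfortably covers the 10-40 bpm band (Nyquist
2.5 Hz vs. a 0.667 Hz maximum breathing frequency).

Coordinates are 0-based with x = column and y = row, origin at the
top-left; frames are stored time-major as ``(T, H, W, 3)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FrameSequence",
    "PixelWindow",
    "Window",
    "downsample",
    "extract_windows",
    "standardize",
    "standardize_signals",
    "MIN_WINDOW_SECONDS",
]

#: The analysis window must span at least two periods of the slowest breath
#: considered (10 bpm -> 6 s period), hence >= 12 s.
MIN_WINDOW_SECONDS = 12.0


@dataclass
class FrameSequence:
    """A time-ordered RGB frame stack on the 8-bit intensity scale."""

    frames: np.ndarray  # (T, H, W, 3), values in [0, 255]
    fps: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError(f"frames must be (T, H, W, 3), got {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise ValueError("need at least one frame")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        lo, hi = float(self.frames.min()), float(self.frames.max())
        if lo < 0 or hi > 255:
            raise ValueError(f"intensities must lie in [0, 255], got [{lo}, {hi}]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass
class PixelWindow:
    """One pixel's 3-channel time series over one analysis window."""

    signal: np.ndarray  # (l, 3) in R, G, B order
    x: int
    y: int
    start_s: float
    rate_hz: float

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[1] != 3:
            raise ValueError(f"signal must be (l, 3), got {self.signal.shape}")


@dataclass
class Window:
    """All pixels of one analysis window (a time slice of the video)."""

    frames: np.ndarray  # (l, H, W, 3)
    start_s: float
    rate_hz: float

    @property
    def length(self) -> int:
        return self.frames.shape[0]

    def pixel_signals(self) -> np.ndarray:
        """Per-pixel time series, shape ``(H*W, l, 3)``, row-major order."""
        l, h, w, _ = self.frames.shape
        return np.moveaxis(self.frames.reshape(l, h * w, 3), 0, 1).astype(float)

    def pixel(self, x: int, y: int) -> PixelWindow:
        return PixelWindow(
            signal=self.frames[:, y, x, :].astype(float),
            x=x, y=y, start_s=self.start_s, rate_hz=self.rate_hz,
        )


def _block_mean_2d(frames: np.ndarray, factor: int) -> np.ndarray:
    """Mean over factor x factor spatial blocks; ragged edge blocks use
    the pixels that exist (output size = ceil(dim / factor))."""
    t, h, w, c = frames.shape
    ho, wo = -(-h // factor), -(-w // factor)
    pad_h, pad_w = ho * factor - h, wo * factor - w
    if pad_h or pad_w:
        # Ragged edge: mean over the pixels actually present in each block.
        out = np.empty((t, ho, wo, c), dtype=float)
        for by in range(ho):
            ys = slice(by * factor, min((by + 1) * factor, h))
            row = frames[:, ys].mean(axis=1)
            for bx in range(wo):
                xs = slice(bx * factor, min((bx + 1) * factor, w))
                out[:, by, bx] = row[:, xs].mean(axis=1)
        return out
    return frames.reshape(t, ho, factor, wo, factor, c).mean(axis=(2, 4))


def downsample(
    seq: FrameSequence,
    spatial_factor: int = 8,
    target_fps: float = 5.0,
    temporal_mode: str = "mean",
) -> FrameSequence:
    """Reduce spatial resolution by block mean and resample the frame rate.

    ``temporal_mode="mean"`` averages each group of ``fps/target_fps``
    consecutive frames (anti-aliasing, the default); ``"decimate"`` keeps
    every n-th frame. Both require the ratio to be an integer. Upsampling
    is refused.
    """
    if spatial_factor < 1:
        raise ValueError("spatial_factor must be >= 1")
    if target_fps > seq.fps:
        raise ValueError(
            f"target_fps {target_fps} exceeds source fps {seq.fps}: upsampling not supported"
        )
    frames = seq.frames.astype(float)
    if spatial_factor > 1:
        frames = _block_mean_2d(frames, spatial_factor)
    ratio = seq.fps / target_fps
    g = int(round(ratio))
    if abs(ratio - g) > 1e-9:
        raise ValueError(
            f"fps ratio {seq.fps}/{target_fps} = {ratio:.4f} is not an integer; "
            "choose a target_fps that divides the source fps"
        )
    if g > 1:
        t_out = frames.shape[0] // g
        frames = frames[: t_out * g]
        if temporal_mode == "mean":
            frames = frames.reshape(t_out, g, *frames.shape[1:]).mean(axis=1)
        elif temporal_mode == "decimate":
            frames = frames[::g]
        else:
            raise ValueError(f"unknown temporal_mode {temporal_mode!r}")
    return FrameSequence(frames=frames, fps=target_fps)


def extract_windows(
    seq: FrameSequence, window_seconds: float = 12.0, hop_seconds: float = 1.0
) -> list[Window]:
    """Slice the video into overlapping analysis windows.

    Windows start at multiples of ``hop_seconds``; a trailing partial window
    is dropped. The count is ``floor((duration - window) / hop) + 1``.
    """
    if window_seconds < MIN_WINDOW_SECONDS:
        raise ValueError(
            f"window_seconds must be >= {MIN_WINDOW_SECONDS} s "
            "(two periods of the slowest 10 bpm breath)"
        )
    if hop_seconds <= 0:
        raise ValueError("hop_seconds must be > 0")
    if seq.duration_s < window_seconds:
        raise ValueError(
            f"video lasts {seq.duration_s:.2f} s but a window needs at least "
            f"{window_seconds:.2f} s"
        )
    l = int(round(window_seconds * seq.fps))
    hop = hop_seconds * seq.fps
    windows = []
    k = 0
    while True:
        start = int(round(k * hop))
        if start + l > seq.n_frames:
            break
        windows.append(
            Window(frames=seq.frames[start : start + l], start_s=start / seq.fps,
                   rate_hz=seq.fps)
        )
        k += 1
    return windows


def standardize_signals(signals: np.ndarray) -> np.ndarray:
    """Z-score each channel of each signal in an ``(N, l, 3)`` batch.

    Zero-variance channels map to all-zeros rather than NaN.
    """
    signals = np.asarray(signals, dtype=float)
    mean = signals.mean(axis=-2, keepdims=True)
    std = signals.std(axis=-2, keepdims=True)
    out = np.where(std > 0, (signals - mean) / np.where(std > 0, std, 1.0), 0.0)
    return out


def standardize(window: PixelWindow) -> PixelWindow:
    """Mean-center and unit-scale each RGB channel of one pixel window."""
    if window.signal.shape[0] < 2:
        raise ValueError("need at least 2 samples to standardize")
    return PixelWindow(
        signal=standardize_signals(window.signal[None])[0],
        x=window.x, y=window.y, start_s=window.start_s, rate_hz=window.rate_hz,
    )
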