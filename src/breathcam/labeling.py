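"""Automatic per-pixel labeling by windowed Pearson correlation.

Training labels for the ROI detector come from a contact reference trace:
a pixel whose temporal trajectory correlates strongly — in either sign,
since the camera cannot tell inhale from exhale motion — with the
reference over an analysis window is a respiration pixel. The label rule is

    label(x, y) = 1  if |r(x, y)| >= T,  else 0

with r the Pearson correlation between the pixel's scalar trajectory and
the reference, and T = 0.7 by default.

A pixel is RGB; the correlation wants one scalar trajectory. The default
reduction is the channel mean of the mean-centered RGB trace (achromatic
motion edges move all channels together, so averaging raises SNR);
``channel_mode="max"`` instead takes the channel with the largest |r|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocessing import Window

__all__ = ["pearson", "CorrelationMap", "LabelMap", "label_window",
           "pixel_trajectories", "resample_reference"]

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.7


def pearson(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation coefficient between two equal-length vectors.

    Returns 0.0 (with a log note) when either vector has zero variance —
    a static pixel carries no correlation information.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.size != v.size:
        raise ValueError(f"length mismatch: {u.size} vs {v.size}")
    if u.size < 2:
        raise ValueError("need at least 2 samples")
    du, dv = u - u.mean(), v - v.mean()
    su, sv = np.sqrt((du * du).sum()), np.sqrt((dv * dv).sum())
    if su == 0.0 or sv == 0.0:
        log.debug("pearson: zero-variance input, returning r = 0")
        return 0.0
    return float((du * dv).sum() / (su * sv))


@dataclass
class CorrelationMap:
    """Per-pixel correlation r against the reference for one window."""

    r: np.ndarray  # (H, W), values in [-1, 1]; 0 for static pixels


@dataclass
class LabelMap:
    """Binary respiration-pixel labels for one window."""

    labels: np.ndarray  # (H, W) uint8
    threshold: float


def pixel_trajectories(window: Window, channel_mode: str = "mean") -> np.ndarray:
    """Reduce each pixel's RGB window to one scalar trajectory.

    Returns ``(H, W, l)``. ``"mean"``: channel mean of the mean-centered
    RGB trace. ``"max"`` is resolved later (per-channel correlation).
    """
    frames = window.frames.astype(float)  # (l, H, W, 3)
    centered = frames - frames.mean(axis=0, keepdims=True)
    traj = centered.mean(axis=-1)  # (l, H, W)
    return np.moveaxis(traj, 0, -1)


def resample_reference(
    times_s: np.ndarray, values: np.ndarray, target_times_s: np.ndarray
) -> np.ndarray:
    """Linearly interpolate a reference trace onto the processing clock.

    The belt samples at >= 20 S/s while the pipeline runs at 5 fps; linear
    interpolation is adequate for sub-Hz breathing content.
    """
    times_s = np.asarray(times_s, dtype=float)
    values = np.asarray(values, dtype=float)
    if times_s.shape != values.shape:
        raise ValueError("times and values must have equal shape")
    return np.interp(np.asarray(target_times_s, dtype=float), times_s, values)


def _corr_many(traj: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r between ``traj`` (..., l) and ``ref`` (l,)."""
    dt = traj - traj.mean(axis=-1, keepdims=True)
    dr = ref - ref.mean()
    st = np.sqrt((dt * dt).sum(axis=-1))
    sr = np.sqrt((dr * dr).sum())
    num = (dt * dr).sum(axis=-1)
    denom = st * sr
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(r, -1.0, 1.0)


def label_window(
    window: Window,
    reference_window: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    channel_mode: str = "mean",
) -> tuple[CorrelationMap, LabelMap]:
    """Correlate every pixel of a window against the reference and threshold.

    ``reference_window`` must already be resampled to the window's rate and
    length (see :func:`resample_reference`). The threshold comparison is
    inclusive: |r| exactly equal to T labels 1.
    """
    ref = np.asarray(reference_window, dtype=float).ravel()
    if ref.size != window.length:
        raise ValueError(
            f"reference window has {ref.size} samples but the video window has "
            f"{window.length}; resample the reference to the processing rate first"
        )
    if channel_mode == "mean":
        r = _corr_many(pixel_trajectories(window), ref)
    elif channel_mode == "max":
        frames = window.frames.astype(float)  # (l, H, W, 3)
        per_ch = np.stack(
            [_corr_many(np.moveaxis(frames[..., c], 0, -1), ref) for c in range(3)],
            axis=-1,
        )
        idx = np.abs(per_ch).argmax(axis=-1)
        r = np.take_along_axis(per_ch, idx[..., None], axis=-1)[..., 0]
    else:
        raise ValueError(f"unknown channel_mode {channel_mode!r}")
    labels = (np.abs(r) >= threshold).astype(np.uint8)
    return CorrelationMap(r=r), LabelMap(labels=labels, threshold=threshold)
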