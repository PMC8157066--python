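"""Breathing-rate guideline patterns and reference-trace synthesis.

A :class:`BreathingPattern` is a piecewise-constant schedule of breathing
rates (breaths per minute) over time, including apnea (rate 0) segments.
:func:`generate_reference` turns a pattern into a sampled waveform with a
continuous phase: the instantaneous frequency is integrated over time, so a
step change in rate never introduces a discontinuity in the waveform itself
— the subject keeps breathing through the transition, only faster or slower.

The waveform plays the role of the contact respiration-belt trace: it is the
labeling reference, the training target and the evaluation ground truth for
synthetic scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BreathingPattern",
    "generate_reference",
    "constant_pattern",
    "staircase_pattern",
    "rapid_change_pattern",
    "apnea_pattern",
]

#: Physiological breathing-rate band assumed by the method, bpm.
BPM_MIN, BPM_MAX = 10.0, 40.0


@dataclass(frozen=True)
class BreathingPattern:
    """Piecewise-constant breathing schedule.

    Parameters
    ----------
    segments
        Sequence of ``(duration_s, rate_bpm)`` tuples. ``rate_bpm == 0``
        denotes apnea (breathing pause). Rates must lie in [0, 60].
    waveform
        Periodic cycle shape: ``"sinusoid"`` (default) or ``"skewed"``, a
        fast-exhale asymmetric shape closer to real belt traces.
    amplitude
        Waveform amplitude in arbitrary units.
    """

    segments: tuple = field(default_factory=tuple)
    waveform: str = "sinusoid"
    amplitude: float = 1.0

    def __post_init__(self):
        if len(self.segments) == 0:
            raise ValueError("pattern must contain at least one segment")
        object.__setattr__(self, "segments", tuple((float(d), float(r)) for d, r in self.segments))
        for dur, rate in self.segments:
            if dur <= 0:
                raise ValueError(f"segment duration must be > 0, got {dur}")
            if not 0.0 <= rate <= 60.0:
                raise ValueError(f"rate must be within [0, 60] bpm, got {rate}")
        if self.waveform not in ("sinusoid", "skewed"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if self.duration_s <= 0:
            raise ValueError("total duration must be > 0")

    @property
    def duration_s(self) -> float:
        return sum(d for d, _ in self.segments)

    def rate_at(self, t: np.ndarray) -> np.ndarray:
        """Instantaneous guideline rate (bpm) at times ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        edges = np.cumsum([d for d, _ in self.segments])
        rates = np.array([r for _, r in self.segments])
        idx = np.minimum(np.searchsorted(edges, t, side="right"), len(rates) - 1)
        return rates[idx]


def _cycle_shape(phase: np.ndarray, waveform: str) -> np.ndarray:
    if waveform == "sinusoid":
        return np.sin(phase)
    # Fast-exhale skew: phase distortion compresses the falling flank.
    return np.sin(phase - 0.4 * np.sin(phase))


def generate_reference(pattern: BreathingPattern, fps: float, seed: int | None = None) -> np.ndarray:
    """Sample the pattern's breathing waveform at ``fps`` Hz.

    Phase accumulates across rate changes (no waveform discontinuity at
    segment boundaries); apnea segments hold the waveform constant at the
    value reached when the pause begins.

    Returns an array of length ``round(total_duration * fps)``.

    The ``seed`` argument is accepted for interface uniformity; the
    reference itself is deterministic (noise lives in the scene renderer).
    """
    if fps <= 0:
        raise ValueError("fps must be > 0")
    n = int(round(pattern.duration_s * fps))
    t = np.arange(n) / fps
    freq_hz = pattern.rate_at(t) / 60.0
    # Integrate instantaneous frequency -> continuous phase.
    phase = 2.0 * np.pi * np.concatenate(([0.0], np.cumsum(freq_hz[:-1]))) / fps
    return pattern.amplitude * _cycle_shape(phase, pattern.waveform)


# ---------------------------------------------------------------------------
# Guideline presets used to acquire the training subject's data: a staircase
# through the physiological band, rapid alternation, and apnea interleaving.
# ---------------------------------------------------------------------------

def constant_pattern(rate_bpm: float, duration_s: float, **kw) -> BreathingPattern:
    """Single steady rate for ``duration_s`` seconds."""
    return BreathingPattern(segments=((duration_s, rate_bpm),), **kw)


def staircase_pattern(step_s: float = 20.0, **kw) -> BreathingPattern:
    """Sequential 10 -> 40 bpm in steps of 5, one step every ``step_s`` s."""
    return BreathingPattern(
        segments=tuple((step_s, r) for r in np.arange(10.0, 45.0, 5.0)), **kw
    )


def rapid_change_pattern(step_s: float = 20.0, **kw) -> BreathingPattern:
    """Rapid alternation between slow breathing and up to 30 bpm."""
    rates = (10.0, 30.0, 12.0, 28.0, 15.0, 30.0)
    return BreathingPattern(segments=tuple((step_s, r) for r in rates), **kw)


def apnea_pattern(apnea_s: float = 10.0, breathe_s: float = 10.0, **kw) -> BreathingPattern:
    """Rates 10..40 bpm by 10, each interleaved with apnea pauses.

    For each rate the subject breathes ``breathe_s`` s, pauses ``apnea_s`` s,
    breathes again, pauses again (40 s per rate with the defaults).
    """
    segs = []
    for r in (10.0, 20.0, 30.0, 40.0):
        segs += [(breathe_s, r), (apnea_s, 0.0), (breathe_s, r), (apnea_s, 0.0)]
    return BreathingPattern(segments=tuple(segs), **kw)
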