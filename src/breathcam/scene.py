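"""Synthetic scene renderer with per-pixel ground truth.

Emulates the statistical structure a chest-and-clothing video presents to
the pipeline: rectangular regions whose intensity is modulated in phase
(+1) or in antiphase (-1) with a breathing waveform — the two flanks of a
moving clothing edge brighten and darken in opposition — a static noisy
background, and optionally a textured distractor block oscillating at a
non-respiratory frequency (a moving person in the background).

Breathing pixel model, per channel c:

    value_c(t) = baseline_c + gain * phase * reference(t) + noise

with i.i.d. Gaussian noise per pixel/channel/frame, clipped to [0, 255].
Frames are float32 on the 8-bit scale; ``quantize=True`` rounds to uint8.
A fixed seed makes the rendered stack byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .patterns import BreathingPattern, generate_reference
from .preprocessing import FrameSequence

__all__ = [
    "Rect",
    "Distractor",
    "SceneSpec",
    "GroundTruth",
    "render_scene",
    "default_scene_spec",
    "experiment2_scene_spec",
    "simulate",
]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle: x = column, y = row, 0-based, top-left origin."""

    x: int
    y: int
    w: int
    h: int

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y, self.y + self.h), slice(self.x, self.x + self.w)

    def intersects(self, other: "Rect") -> bool:
        return not (
            self.x + self.w <= other.x or other.x + other.w <= self.x
            or self.y + self.h <= other.y or other.y + other.h <= self.y
        )


@dataclass(frozen=True)
class Distractor:
    """Textured block oscillating horizontally at a non-respiratory rate."""

    x: int = 24
    y: int = 2
    w: int = 12
    h: int = 12
    amplitude_px: float = 8.0
    freq_hz: float = 1.3

    def bounding_rect(self) -> Rect:
        a = int(np.ceil(self.amplitude_px))
        return Rect(self.x - a, self.y, self.w + 2 * a, self.h)


@dataclass(frozen=True)
class SceneSpec:
    """Geometry, noise and modulation parameters of a synthetic scene."""

    height: int = 48
    width: int = 64
    fps: float = 10.0
    in_phase: tuple = (Rect(8, 16, 16, 24),)
    antiphase: tuple = (Rect(40, 16, 16, 24),)
    gain: float = 10.0
    noise_std: float = 2.0
    baseline: tuple = (128.0, 128.0, 128.0)
    distractor: Distractor | None = None
    seed: int = 0
    quantize: bool = False

    def __post_init__(self):
        object.__setattr__(self, "in_phase", tuple(self.in_phase))
        object.__setattr__(self, "antiphase", tuple(self.antiphase))
        if self.gain < 0:
            raise ValueError("gain must be >= 0")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        bounds = Rect(0, 0, self.width, self.height)
        for r in self.in_phase + self.antiphase:
            if r.x < 0 or r.y < 0 or r.x + r.w > self.width or r.y + r.h > self.height:
                raise ValueError(f"region {r} exceeds frame bounds {bounds}")
        for a in self.in_phase:
            for b in self.antiphase:
                if a.intersects(b):
                    raise ValueError(f"in-phase {a} and antiphase {b} regions overlap")
        if self.distractor is not None:
            d = self.distractor.bounding_rect()
            for r in self.in_phase + self.antiphase:
                if d.intersects(r):
                    raise ValueError("distractor sweep overlaps a breathing region")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["in_phase"] = [asdict(r) for r in self.in_phase]
        d["antiphase"] = [asdict(r) for r in self.antiphase]
        return d


@dataclass
class GroundTruth:
    """Per-frame reference trace plus per-pixel class and phase maps."""

    reference: np.ndarray  # (T,) breathing waveform value per frame
    class_map: np.ndarray  # (H, W) uint8, 1 = breathing pixel
    phase_map: np.ndarray  # (H, W) int8, +1 in-phase / -1 antiphase / 0 none

    def downsampled(self, factor: int) -> "GroundTruth":
        """Ground truth on the block-mean downsampled pixel grid.

        A block is a breathing pixel iff its net modulation (sum of member
        phases) is nonzero after averaging — exact for uniform gain.
        """
        h, w = self.phase_map.shape
        ho, wo = -(-h // factor), -(-w // factor)
        net = np.zeros((ho, wo), dtype=float)
        for by in range(ho):
            for bx in range(wo):
                blk = self.phase_map[by * factor:(by + 1) * factor,
                                     bx * factor:(bx + 1) * factor]
                net[by, bx] = blk.astype(float).sum()
        return GroundTruth(
            reference=self.reference.copy(),
            class_map=(net != 0).astype(np.uint8),
            phase_map=np.sign(net).astype(np.int8),
        )


def render_scene(spec: SceneSpec, reference: np.ndarray) -> tuple[FrameSequence, GroundTruth]:
    """Render a frame stack modulated by ``reference`` plus its ground truth."""
    reference = np.asarray(reference, dtype=float)
    if reference.ndim != 1 or reference.size == 0:
        raise ValueError("reference must be a non-empty 1-D array")
    t_n = reference.size
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)

    phase_map = np.zeros((h, w), dtype=np.int8)
    for r in spec.in_phase:
        phase_map[r.slices()] = 1
    for r in spec.antiphase:
        phase_map[r.slices()] = -1
    if spec.gain == 0:
        # unmodulated regions carry no respiration: nothing to detect
        phase_map = np.zeros_like(phase_map)
    class_map = (phase_map != 0).astype(np.uint8)

    frames = np.empty((t_n, h, w, 3), dtype=np.float32)
    frames[:] = np.asarray(spec.baseline, dtype=np.float32)
    mod = spec.gain * phase_map[None, :, :].astype(np.float32) * \
        reference[:, None, None].astype(np.float32)
    frames += mod[:, :, :, None]

    if spec.distractor is not None:
        d = spec.distractor
        texture = rng.uniform(0.0, 255.0, size=(d.h, d.w, 3)).astype(np.float32)
        t_s = np.arange(t_n) / spec.fps
        xoff = np.rint(d.amplitude_px * np.sin(2 * np.pi * d.freq_hz * t_s)).astype(int)
        for i in range(t_n):
            x0 = int(np.clip(d.x + xoff[i], 0, w - d.w))
            frames[i, d.y:d.y + d.h, x0:x0 + d.w, :] = texture

    if spec.noise_std > 0:
        frames += rng.normal(0.0, spec.noise_std, size=frames.shape).astype(np.float32)
    np.clip(frames, 0.0, 255.0, out=frames)
    if spec.quantize:
        frames = np.rint(frames).astype(np.uint8)

    gt = GroundTruth(reference=reference.copy(), class_map=class_map, phase_map=phase_map)
    return FrameSequence(frames=frames, fps=spec.fps), gt


def default_scene_spec(seed: int = 0, noise_std: float = 2.0, **kw) -> SceneSpec:
    """The standard two-region test scene (no distractor)."""
    return SceneSpec(seed=seed, noise_std=noise_std, **kw)


def experiment2_scene_spec(seed: int = 0, noise_std: float = 2.0, **kw) -> SceneSpec:
    """Two-region scene plus a moving background distractor."""
    return SceneSpec(seed=seed, noise_std=noise_std, distractor=Distractor(), **kw)


def simulate(pattern: BreathingPattern, spec: SceneSpec) -> tuple[FrameSequence, GroundTruth]:
    """Convenience: generate the reference for ``pattern`` and render it."""
    ref = generate_reference(pattern, spec.fps)
    return render_scene(spec, ref)
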