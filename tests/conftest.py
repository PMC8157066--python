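"""Shared fixtures: scaled-down synthetic scenes and a trained detector.

Scenes render at 64x48 @ 10 fps and are processed at spatial factor 4 /
5 fps (a 16x12 pixel grid) — the same pipeline semantics as the nominal
640x480 @ 20 fps capture at a fraction of the cost. The session-scoped
trained detector is shared by the pipeline, detector-generalisation and
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import breathcam as bc
from breathcam.detector import DetectorConfig
from breathcam.pipeline import train_pipeline

TRAIN_NOISE_STD = 4.0  # "moderate" sensor noise on the 8-bit scale
SOURCE_FPS = 10.0


def small_config(seed: int = 0, epochs: int = 6) -> bc.PipelineConfig:
    return bc.PipelineConfig(
        spatial_factor=4,
        target_fps=5.0,
        max_train_samples=6000,
        detector=DetectorConfig(epochs=epochs, seed=seed),
        seed=seed,
    )


@pytest.fixture(scope="session")
def pipeline_config() -> bc.PipelineConfig:
    return small_config()


@pytest.fixture(scope="session")
def training_scenes():
    """One synthetic 'subject' breathing the three guideline patterns."""
    seqs, refs = [], []
    for i, pat in enumerate(
        [bc.staircase_pattern(), bc.rapid_change_pattern(), bc.apnea_pattern()]
    ):
        ref = bc.generate_reference(pat, SOURCE_FPS)
        seq, _ = bc.render_scene(
            bc.default_scene_spec(seed=10 + i, noise_std=TRAIN_NOISE_STD), ref
        )
        seqs.append(seq)
        refs.append(ref)
    return seqs, refs


@pytest.fixture(scope="session")
def trained_detector(training_scenes, pipeline_config):
    seqs, refs = training_scenes
    detector, report = train_pipeline(seqs, refs, pipeline_config)
    return detector, report


def constant_scene(bpm: float, duration_s: float = 40.0, seed: int = 0,
                   noise_std: float = TRAIN_NOISE_STD, distractor: bool = False):
    """Held-out constant-rate test scene with its reference trace."""
    ref = bc.generate_reference(bc.constant_pattern(bpm, duration_s), SOURCE_FPS)
    spec_fn = bc.experiment2_scene_spec if distractor else bc.default_scene_spec
    seq, gt = bc.render_scene(spec_fn(seed=seed, noise_std=noise_std), ref)
    return seq, ref, gt
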