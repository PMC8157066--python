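"""ROI detector: architecture contract, augmentation, training, inference."""

import numpy as np
import pytest

import breathcam as bc
from breathcam.detector import (DetectorConfig, ROIMask, augment,
                                build_detector, load_detector, predict_roi,
                                save_detector, train_detector)
from breathcam.preprocessing import Window
from conftest import constant_scene, small_config


def analytic_parameter_count(widths, c_in=3):
    """Independent hand count of conv/BN/FC parameters."""
    total = 0
    for c in widths:
        total += 3 * c_in * c + c      # conv1 (k=3) + bias
        total += 2 * c                 # bn1
        total += 3 * c * c + c         # conv2
        total += 2 * c                 # bn2
        total += 1 * c_in * c + c      # projection shortcut (k=1)
        total += 2 * c                 # bn of shortcut
        c_in = c
    total += 128 * 1 + 1               # fully connected head
    total += 2                         # output batch norm
    return total


class TestBuildDetector:
    def test_temporal_length_chain(self):
        det = build_detector(DetectorConfig(), input_len=60)
        assert det.temporal_lengths == [30, 15, 8, 4]

    def test_output_is_a_probability(self):
        det = build_detector(DetectorConfig(), input_len=60)
        p = det.predict_proba(np.random.default_rng(0).normal(size=(5, 60, 3)))
        assert np.all((p > 0) & (p < 1))

    def test_parameter_count_matches_hand_count(self):
        cfg = DetectorConfig()
        det = build_detector(cfg, input_len=60)
        assert det.n_parameters() == analytic_parameter_count(cfg.block_widths)

    def test_too_short_input_names_max_depth(self):
        with pytest.raises(ValueError, match="at most 3"):
            build_detector(DetectorConfig(), input_len=12)

    def test_embedding_width_is_fixed(self):
        with pytest.raises(ValueError, match="128"):
            DetectorConfig(block_widths=(16, 32))

    def test_same_seed_same_weights(self):
        a = build_detector(DetectorConfig(seed=5), input_len=60)
        b = build_detector(DetectorConfig(seed=5), input_len=60)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)


class TestAugment:
    def test_degenerate_ranges_give_identity(self):
        cfg = DetectorConfig(aug_scale_range=(1.0, 1.0),
                             aug_shift_range=(0.0, 0.0), aug_invert_p=0.0)
        sig = np.random.default_rng(0).normal(size=(60, 3))
        np.testing.assert_allclose(augment(sig, seed=1, config=cfg), sig)

    def test_fixed_seed_is_deterministic(self):
        sig = np.random.default_rng(0).normal(size=(60, 3))
        np.testing.assert_array_equal(augment(sig, seed=7), augment(sig, seed=7))

    def test_inversion_preserves_the_label(self):
        """|r| is even in sign, so an inverted respiration window stays
        a respiration window."""
        ref = np.sin(np.arange(60) * 0.3)
        sig = np.repeat(ref[:, None], 3, axis=1)
        cfg = DetectorConfig(aug_scale_range=(1.0, 1.0),
                             aug_shift_range=(0.0, 0.0), aug_invert_p=1.0)
        out = augment(sig, seed=0, config=cfg)
        assert abs(bc.pearson(out[:, 0], ref)) == pytest.approx(1.0)


class TestTraining:
    def test_single_class_set_rejected(self):
        x = np.random.default_rng(0).normal(size=(10, 60, 3))
        with pytest.raises(ValueError, match="single class"):
            train_detector(x, np.ones(10), DetectorConfig(epochs=1))

    def test_loss_trend_and_separable_accuracy(self):
        """On a zero-noise scene the classes are separable by construction:
        loss decreases over early epochs and held-out accuracy is perfect."""
        ref = bc.generate_reference(bc.constant_pattern(20.0, 30.0), 10.0)
        seq, _ = bc.render_scene(bc.default_scene_spec(seed=0, noise_std=0.0), ref)
        cfg = small_config(epochs=4)
        from breathcam.pipeline import build_training_set
        x, y = build_training_set(seq, ref, cfg)
        det, report = train_detector(x, y, cfg.detector)
        assert report.epoch_loss[-1] < report.epoch_loss[0]
        assert report.epoch_val_accuracy[-1] == 1.0

    def test_generalises_to_a_different_layout(self, trained_detector, pipeline_config):
        """Spatial invariance by construction: a detector trained on one
        region geometry classifies another at >= 0.9 accuracy."""
        det, _ = trained_detector
        ref = bc.generate_reference(bc.constant_pattern(22.0, 16.0), 10.0)
        spec = bc.SceneSpec(
            in_phase=(bc.Rect(4, 4, 8, 8), bc.Rect(44, 32, 12, 8)),
            antiphase=(bc.Rect(24, 20, 16, 12),),
            seed=77, noise_std=4.0,
        )
        seq, gt = bc.render_scene(spec, ref)
        low = bc.downsample(seq, 4, 5.0)
        win = bc.extract_windows(low, 12.0, 1.0)[0]
        _, mask = predict_roi(win, det)
        truth = gt.downsampled(4).class_map.astype(bool)
        assert (mask.mask == truth).mean() >= 0.9


class TestPredictROI:
    def test_constant_video_gives_uniform_map(self):
        det = build_detector(DetectorConfig(), input_len=60)
        win = Window(frames=np.full((60, 4, 5, 3), 100.0), start_s=0.0, rate_hz=5.0)
        pm, mask = predict_roi(win, det)
        assert np.unique(pm.probabilities).size == 1
        assert np.unique(mask.mask).size == 1

    def test_mask_count_non_increasing_in_threshold(self):
        det = build_detector(DetectorConfig(), input_len=60)
        rng = np.random.default_rng(1)
        win = Window(frames=rng.uniform(0, 255, (60, 6, 6, 3)), start_s=0.0,
                     rate_hz=5.0)
        counts = [predict_roi(win, det, threshold=t)[1].mask.sum()
                  for t in (0.2, 0.4, 0.6, 0.8)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_length_mismatch_rejected(self):
        det = build_detector(DetectorConfig(), input_len=60)
        win = Window(frames=np.zeros((50, 2, 2, 3)), start_s=0.0, rate_hz=5.0)
        with pytest.raises(ValueError, match="length"):
            predict_roi(win, det)

    def test_spatial_permutation_equivariance(self):
        """Permuting pixel positions permutes the probability map
        identically — the detector sees only time series."""
        det = build_detector(DetectorConfig(), input_len=60)
        rng = np.random.default_rng(2)
        frames = rng.uniform(0, 255, (60, 4, 6, 3))
        win = Window(frames=frames, start_s=0.0, rate_hz=5.0)
        pm, _ = predict_roi(win, det)
        perm = rng.permutation(24)
        sh = frames.reshape(60, 24, 3)[:, perm, :].reshape(60, 4, 6, 3)
        pm2, _ = predict_roi(Window(frames=sh, start_s=0.0, rate_hz=5.0), det)
        np.testing.assert_array_equal(
            pm2.probabilities.ravel(), pm.probabilities.ravel()[perm])


def test_save_load_round_trip(tmp_path):
    det = build_detector(DetectorConfig(), input_len=60)
    rng = np.random.default_rng(3)
    x = rng.normal(size=(7, 60, 3))
    p_before = det.predict_proba(x)
    path = tmp_path / "model.npz"
    save_detector(det, path)
    det2 = load_detector(path)
    np.testing.assert_array_equal(det2.predict_proba(x), p_before)
    assert det2.config == det.config
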