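"""End-to-end orchestration: raw video -> ROI -> fused trace -> bpm.

Stages (matching the method's two-step structure after preprocessing):

1. preprocess: block-mean spatial downsampling, resampling to the
   processing rate, overlapping window extraction;
2. ROI detection: the per-pixel 1-D residual CNN yields a probability
   map per window, thresholded into a mask;
3. respiration estimation: mirror-augmented cosine clustering selects
   the symmetric in-phase/antiphase pair, fused into one trace per
   window;
4. vitals: breath peaks -> PPI -> bpm per window; windows with no ROI,
   no symmetric pair, or fewer than two peaks carry a missing bpm and a
   status flag instead of a number.

Window traces are stitched into one continuous respiration trace by
sign-aligned overlap-averaging: each window's fused trace is unit-scaled,
its sign is matched to the trace accumulated so far on the overlapping
samples, and overlaps are averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import labeling, metrics
from .config import PipelineConfig
from .detector import Detector, predict_roi, train_detector, TrainingReport
from .errors import NoBreathDetectedError, NoROIError, NoSymmetryError
from .estimator import estimate_window
from .preprocessing import FrameSequence, downsample, extract_windows

__all__ = [
    "WindowResult", "PipelineResult", "preprocess", "build_training_set",
    "train_pipeline", "run_pipeline", "reference_bpm_series", "evaluate_run",
]

log = logging.getLogger(__name__)


def preprocess(seq: FrameSequence, config: PipelineConfig) -> FrameSequence:
    factor = config.spatial_factor
    return downsample(seq, spatial_factor=factor, target_fps=config.target_fps,
                      temporal_mode=config.temporal_mode)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def build_training_set(
    sequences,
    references,
    config: PipelineConfig,
    preprocessed: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble labeled pixel windows from (video, reference) pairs.

    ``references`` are per-frame traces aligned with each *source* video;
    they are resampled to the processing clock internally. Labels come
    from the correlation rule with the configured threshold. The class
    balance is capped (``balance_ratio`` negatives per positive) and the
    total is subsampled to ``max_train_samples``, both seeded.
    """
    if isinstance(sequences, FrameSequence):
        sequences = [sequences]
        references = [references]
    xs, ys = [], []
    for seq, ref in zip(sequences, references):
        src_times = np.arange(len(ref)) / seq.fps
        low = seq if preprocessed else preprocess(seq, config)
        windows = extract_windows(low, config.window_seconds, config.train_hop_seconds)
        for win in windows:
            t = win.start_s + np.arange(win.length) / win.rate_hz
            ref_win = labeling.resample_reference(src_times, ref, t)
            _, lm = labeling.label_window(
                win, ref_win, threshold=config.label_threshold,
                channel_mode=config.channel_mode,
            )
            sig = win.pixel_signals()  # (H*W, l, 3)
            xs.append(sig)
            ys.append(lm.labels.ravel())
    x = np.concatenate(xs)
    y = np.concatenate(ys).astype(float)

    rng = np.random.default_rng(config.seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if pos.size and neg.size > config.balance_ratio * pos.size:
        neg = rng.choice(neg, size=int(config.balance_ratio * pos.size), replace=False)
    idx = np.concatenate([pos, neg])
    if idx.size > config.max_train_samples:
        idx = rng.choice(idx, size=config.max_train_samples, replace=False)
    idx = np.sort(idx)
    log.info("training set: %d windows (%d positive)", idx.size, int(y[idx].sum()))
    return x[idx], y[idx]


def train_pipeline(
    sequences, references, config: PipelineConfig
) -> tuple[Detector, TrainingReport]:
    """Label, assemble and train the ROI detector from raw video(s)."""
    x, y = build_training_set(sequences, references, config)
    return train_detector(x, y, config.detector)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

@dataclass
class WindowResult:
    start_s: float
    status: str                 # "ok" | "no_roi" | "no_symmetry" | "no_breath"
    bpm: float                  # NaN unless status allows a rate
    mean_ppi_ms: float          # NaN unless >= 2 peaks
    n_roi_pixels: int
    fused: np.ndarray | None    # (l,) zero-mean trace, or None


@dataclass
class PipelineResult:
    fps: float
    window_seconds: float
    windows: list = field(default_factory=list)  # WindowResult
    trace: np.ndarray = None                     # (T,) stitched respiration
    trace_times_s: np.ndarray = None

    @property
    def bpm_series(self) -> np.ndarray:
        return np.array([w.bpm for w in self.windows])

    @property
    def ppi_series_ms(self) -> np.ndarray:
        return np.array([w.mean_ppi_ms for w in self.windows])

    @property
    def window_starts_s(self) -> np.ndarray:
        return np.array([w.start_s for w in self.windows])


def _stitch(windows, results, n_total: int, fps: float) -> np.ndarray:
    trace = np.zeros(n_total)
    weight = np.zeros(n_total)
    for win, res in zip(windows, results):
        if res.fused is None:
            continue
        f = res.fused
        std = f.std()
        f = f / std if std > 0 else f
        i0 = int(round(win.start_s * fps))
        seg = slice(i0, i0 + len(f))
        covered = weight[seg] > 0
        if covered.any():
            prev = trace[seg][covered] / weight[seg][covered]
            if np.dot(prev, f[covered]) < 0:
                f = -f
        trace[seg] += f
        weight[seg] += 1.0
    out = np.where(weight > 0, trace / np.where(weight > 0, weight, 1.0), 0.0)
    return out


def run_pipeline(
    seq: FrameSequence,
    detector: Detector,
    config: PipelineConfig,
    preprocessed: bool = False,
) -> PipelineResult:
    """Run detection + estimation over every window of a video."""
    low = seq if preprocessed else preprocess(seq, config)
    windows = extract_windows(low, config.window_seconds, config.hop_seconds)
    result = PipelineResult(fps=low.fps, window_seconds=config.window_seconds)
    for win in windows:
        _, mask = predict_roi(win, detector)
        n_roi = int(mask.mask.sum())
        status, bpm, ppi, fused = "ok", float("nan"), float("nan"), None
        try:
            fused = estimate_window(win, mask, k=config.n_clusters)
            bm = metrics.compute_bpm(
                metrics.detect_peaks(
                    fused, low.fps,
                    min_distance_s=config.min_distance_s,
                    min_prominence_frac=config.min_prominence_frac,
                    refine=config.refine_peaks,
                ),
                low.fps,
            )
            bpm, ppi = bm.bpm, float(bm.ppi_ms.mean())
        except NoROIError:
            status = "no_roi"
            log.info("window @%.1fs: no ROI pixels", win.start_s)
        except NoSymmetryError:
            status = "no_symmetry"
            log.info("window @%.1fs: no symmetric cluster pair", win.start_s)
        except NoBreathDetectedError:
            status = "no_breath"
            log.info("window @%.1fs: no breath peaks (apnea?)", win.start_s)
        result.windows.append(WindowResult(
            start_s=win.start_s, status=status, bpm=bpm, mean_ppi_ms=ppi,
            n_roi_pixels=n_roi, fused=fused,
        ))
    result.trace = _stitch(windows, result.windows, low.n_frames, low.fps)
    result.trace_times_s = np.arange(low.n_frames) / low.fps
    return result


def reference_bpm_series(
    reference: np.ndarray,
    source_fps: float,
    config: PipelineConfig,
    n_windows: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Windowed (bpm, mean PPI ms, resampled trace) for a reference trace.

    The reference goes through the same windowing and peak pipeline as the
    camera estimate — one definition of bpm for both sides. Windows
    without two detectable peaks (apnea) yield NaN.
    """
    ref = np.asarray(reference, dtype=float)
    src_times = np.arange(ref.size) / source_fps
    duration = ref.size / source_fps
    fps = config.target_fps
    t = np.arange(int(round(duration * fps))) / fps
    ref_proc = labeling.resample_reference(src_times, ref, t)
    l = int(round(config.window_seconds * fps))
    hop = config.hop_seconds * fps
    bpms, ppis = [], []
    k = 0
    while True:
        i0 = int(round(k * hop))
        if i0 + l > ref_proc.size:
            break
        seg = ref_proc[i0:i0 + l]
        try:
            bm = metrics.compute_bpm(
                metrics.detect_peaks(
                    seg, fps,
                    min_distance_s=config.min_distance_s,
                    min_prominence_frac=config.min_prominence_frac,
                    refine=config.refine_peaks,
                ),
                fps,
            )
            bpms.append(bm.bpm)
            ppis.append(float(bm.ppi_ms.mean()))
        except NoBreathDetectedError:
            bpms.append(float("nan"))
            ppis.append(float("nan"))
        k += 1
    if n_windows is not None:
        bpms, ppis = bpms[:n_windows], ppis[:n_windows]
    return np.array(bpms), np.array(ppis), ref_proc


def evaluate_run(
    result: PipelineResult,
    reference: np.ndarray,
    source_fps: float,
    config: PipelineConfig,
) -> metrics.AgreementReport:
    """Agreement between a pipeline run and its reference trace.

    The stitched trace correlation is sign-aligned: the fused trace's
    canonical orientation is arbitrary relative to the belt's polarity,
    so the trace is flipped, if needed, before the report's correlation.
    """
    n = len(result.windows)
    ref_bpm, ref_ppi, ref_proc = reference_bpm_series(
        reference, source_fps, config, n_windows=n
    )
    if ref_bpm.size != n:
        raise ValueError("reference shorter than the estimated run")
    est_trace = result.trace
    m = min(est_trace.size, ref_proc.size)
    est_t, ref_t = est_trace[:m], ref_proc[:m]
    if labeling.pearson(est_t, ref_t) < 0:
        est_t = -est_t
    return metrics.evaluate(
        est_t, ref_t,
        result.bpm_series, ref_bpm,
        result.ppi_series_ms, ref_ppi,
    )
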