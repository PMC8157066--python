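"""Breath peak detection, bpm/PPI computation and agreement statistics.

bpm is derived from the peak-to-peak interval (PPI): detect breath peaks,
take successive gaps in milliseconds, and report bpm = 60000 / mean(PPI).
Agreement between estimated and reference bpm series is summarised with
the Pearson correlation, MAE, Bland–Altman mean of differences (MOD) and
limits of agreement (LOA = ±1.96 × SD of the differences, sample SD),
and the R² of an ordinary least-squares regression of estimate on
reference. Differences are taken as estimated − reference throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import find_peaks

from .errors import NoBreathDetectedError
from .labeling import pearson

__all__ = [
    "BreathMetrics", "AgreementReport", "detect_peaks", "compute_bpm", "evaluate",
]

#: Minimum peak separation: just under the 1.5 s period of the fastest
#: normal breath (40 bpm), so adjacent true peaks are never merged.
DEFAULT_MIN_DISTANCE_S = 60.0 / 45.0
DEFAULT_MIN_PROMINENCE_FRAC = 0.3


@dataclass
class BreathMetrics:
    """Peaks, peak-to-peak intervals and the windowed breathing rate."""

    peaks: np.ndarray      # sample positions (possibly sub-sample refined)
    ppi_ms: np.ndarray     # successive peak gaps, ms
    bpm: float


def _parabolic_refine(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Sub-sample peak positions via a parabola through each peak triplet."""
    pos = idx.astype(float)
    interior = (idx > 0) & (idx < len(x) - 1)
    i = idx[interior]
    denom = x[i - 1] - 2 * x[i] + x[i + 1]
    ok = denom < 0
    delta = np.zeros_like(denom)
    delta[ok] = 0.5 * (x[i - 1] - x[i + 1])[ok] / denom[ok]
    pos[interior] += np.clip(delta, -0.5, 0.5)
    return pos


def detect_peaks(
    signal: np.ndarray,
    fps: float,
    min_distance_s: float = DEFAULT_MIN_DISTANCE_S,
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
    refine: bool = True,
) -> np.ndarray:
    """Locate breath peaks: local maxima separated by at least
    ``min_distance_s`` with prominence at least ``min_prominence_frac``
    times the signal's standard deviation.

    With ``refine`` the integer peak indices are adjusted by parabolic
    interpolation, removing most of the frame-rate quantisation of the
    PPI. Raises :class:`NoBreathDetectedError` when fewer than two peaks
    survive — the apnea/flat-signal case, where bpm is undefined.
    """
    x = np.asarray(signal, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("signal must contain at least 3 samples")
    std = x.std()
    if std == 0:
        raise NoBreathDetectedError("constant signal: no breaths detectable")
    distance = max(1, int(round(min_distance_s * fps)))
    idx, _ = find_peaks(x, distance=distance, prominence=min_prominence_frac * std)
    if idx.size < 2:
        raise NoBreathDetectedError(
            f"only {idx.size} peak(s) found; bpm undefined for this window"
        )
    return _parabolic_refine(x, idx) if refine else idx.astype(float)


def compute_bpm(peaks: np.ndarray, fps: float) -> BreathMetrics:
    """PPI series (ms) and bpm from peak positions at ``fps`` Hz."""
    peaks = np.asarray(peaks, dtype=float).ravel()
    if peaks.size < 2:
        raise NoBreathDetectedError("need at least 2 peaks to compute a PPI")
    if np.any(np.diff(peaks) <= 0):
        raise ValueError("peaks must be strictly increasing")
    ppi_ms = np.diff(peaks) / fps * 1000.0
    return BreathMetrics(peaks=peaks, ppi_ms=ppi_ms, bpm=60000.0 / ppi_ms.mean())


@dataclass
class AgreementReport:
    """Agreement statistics between estimated and reference measurements."""

    correlation: float
    R2: float
    MOD: float
    LOA: float
    MAE_bpm: float
    MAE_PPI_ms: float | None
    n_pairs: int
    bland_altman: list = field(default_factory=list)  # (mean, diff) points

    def to_dict(self) -> dict:
        return asdict(self)


def _ols_r2(est: np.ndarray, ref: np.ndarray) -> float:
    """R² of the least-squares line (with intercept) of est on ref."""
    if est.size < 2 or np.ptp(ref) < 1e-9:
        return float("nan")
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a, b = np.polyfit(ref, est, 1)
    resid = est - (a * ref + b)
    ss_tot = ((est - est.mean()) ** 2).sum()
    if ss_tot == 0:
        return 1.0
    return float(1.0 - (resid ** 2).sum() / ss_tot)


def evaluate(
    estimated_signal: np.ndarray | None,
    reference_signal: np.ndarray | None,
    estimated_bpm: np.ndarray,
    reference_bpm: np.ndarray,
    estimated_ppi_ms: np.ndarray | None = None,
    reference_ppi_ms: np.ndarray | None = None,
) -> AgreementReport:
    """Full agreement report between an estimate and its reference.

    ``estimated_bpm`` and ``reference_bpm`` are paired per-window series of
    equal length; windows where either side is NaN (no detectable breath)
    are excluded from the bpm statistics, and ``n_pairs`` reports how many
    pairs remain. When signal traces are given, the signed Pearson
    correlation between them is reported (the fused trace is canonically
    oriented, so sign is meaningful); otherwise the bpm series correlate.
    """
    est_bpm = np.asarray(estimated_bpm, dtype=float).ravel()
    ref_bpm = np.asarray(reference_bpm, dtype=float).ravel()
    if est_bpm.size != ref_bpm.size:
        raise ValueError(
            f"bpm series length mismatch: {est_bpm.size} vs {ref_bpm.size}"
        )
    ok = ~(np.isnan(est_bpm) | np.isnan(ref_bpm))
    e, r = est_bpm[ok], ref_bpm[ok]
    diff = e - r
    mod = float(diff.mean()) if diff.size else float("nan")
    loa = float(1.96 * diff.std(ddof=1)) if diff.size > 1 else 0.0 if diff.size else float("nan")
    mae = float(np.abs(diff).mean()) if diff.size else float("nan")

    if estimated_signal is not None and reference_signal is not None:
        corr = pearson(estimated_signal, reference_signal)
    else:
        corr = pearson(e, r) if e.size >= 2 else float("nan")

    mae_ppi = None
    if estimated_ppi_ms is not None and reference_ppi_ms is not None:
        ep = np.asarray(estimated_ppi_ms, dtype=float).ravel()
        rp = np.asarray(reference_ppi_ms, dtype=float).ravel()
        if ep.size != rp.size:
            raise ValueError("PPI series length mismatch")
        okp = ~(np.isnan(ep) | np.isnan(rp))
        mae_ppi = float(np.abs(ep[okp] - rp[okp]).mean()) if okp.any() else float("nan")

    return AgreementReport(
        correlation=corr,
        R2=_ols_r2(e, r),
        MOD=mod,
        LOA=loa,
        MAE_bpm=mae,
        MAE_PPI_ms=mae_ppi,
        n_pairs=int(diff.size),
        bland_altman=[((float(a) + float(b)) / 2.0, float(a) - float(b))
                      for a, b in zip(e, r)],
    )
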