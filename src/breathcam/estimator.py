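"""Respiration estimation from ROI pixel signals by origin symmetry.

Within the detected ROI, pixels split into two families: those whose
intensity rises with inhalation (in phase) and those whose intensity
falls (antiphase). Their mean-centered time series are near-negations of
each other, i.e. symmetric about the origin of signal space. Noise pixels
that slipped past the detector lack a symmetric partner population.

The estimator exploits this: every ROI signal p_i is paired with its
mirrored copy p_i' = -p_i, the union is clustered agglomeratively under
cosine distance, and for each cluster pair (C_n, C_m) a mutual-inclusion
score counts pixels i with

    f(n, m, i) = 1  if (p_i in C_n and p_i' in C_m)
                    or (p_i' in C_n and p_i in C_m),  else 0.

The pair maximising the sum of f over pixels is the strongest-symmetry
pair — the in-phase and antiphase breathing clusters. Fusion inverts the
phase of one cluster's original signals and averages everything into one
respiration trace. Mirrored copies participate in clustering and pair
selection only; fusion averages original signals, so no pixel is counted
twice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA

from .errors import NoROIError, NoSymmetryError
from .preprocessing import Window

__all__ = [
    "PixelSignalSet", "ClusterModel", "prepare_signals", "cluster_with_mirrors",
    "mutual_inclusion_score", "select_symmetric_pair", "fuse", "project_2d",
    "estimate_window",
]

log = logging.getLogger(__name__)

DEFAULT_N_CLUSTERS = 6


@dataclass
class PixelSignalSet:
    """Mean-centered 1-D signals of the ROI pixels and their mirrors."""

    signals: np.ndarray    # (N, l) originals, zero mean each
    positions: np.ndarray  # (N, 2) as (x, y)

    @property
    def n(self) -> int:
        return self.signals.shape[0]

    def with_mirrors(self) -> np.ndarray:
        """(2N, l): originals followed by their exact negations."""
        return np.concatenate([self.signals, -self.signals])


@dataclass
class ClusterModel:
    """Cluster assignment of the 2N mirrored points."""

    labels: np.ndarray  # (2N,) cluster index per point; i and i+N are mirrors
    k: int
    n_signals: int      # N

    def members(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


def prepare_signals(window: Window, mask) -> PixelSignalSet:
    """Build the ROI signal set for one window.

    Per masked pixel: mean-center each RGB channel, average the channels
    into one scalar trace, and mean-center again. Constant (zero-variance)
    traces are dropped with a log note — they carry no direction in signal
    space and cosine distance is undefined for them.
    """
    m = np.asarray(mask.mask if hasattr(mask, "mask") else mask, dtype=bool)
    ys, xs = np.nonzero(m)
    if ys.size == 0:
        raise NoROIError("no respiration pixels in window")
    traces = window.frames[:, ys, xs, :].astype(float)  # (l, N, 3)
    traces = traces - traces.mean(axis=0, keepdims=True)
    sig = traces.mean(axis=-1).T                        # (N, l)
    sig = sig - sig.mean(axis=1, keepdims=True)
    keep = sig.std(axis=1) > 0
    dropped = int((~keep).sum())
    if dropped:
        log.info("prepare_signals: dropped %d constant pixel trace(s)", dropped)
    return PixelSignalSet(
        signals=sig[keep],
        positions=np.column_stack([xs[keep], ys[keep]]),
    )


def cluster_with_mirrors(signals: PixelSignalSet, k: int = DEFAULT_N_CLUSTERS) -> ClusterModel:
    """Agglomerative (average-linkage) clustering of originals + mirrors
    under cosine distance, cut at ``k`` clusters.

    Cosine distance is scale-free, so a pixel's modulation depth does not
    affect its cluster, only the shape and sign of its trajectory do.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if signals.n < 2:
        raise NoROIError(
            f"need at least 2 usable pixel signals, got {signals.n}"
        )
    pts = signals.with_mirrors()
    k_eff = min(k, pts.shape[0])
    if k_eff < k:
        log.info("cluster_with_mirrors: reducing k from %d to %d points", k, k_eff)
    model = AgglomerativeClustering(n_clusters=k_eff, metric="cosine", linkage="average")
    labels = model.fit_predict(pts)
    return ClusterModel(labels=labels, k=k_eff, n_signals=signals.n)


def mutual_inclusion_score(model: ClusterModel, n: int, m: int) -> int:
    """Count of pixels whose original and mirrored copies straddle
    clusters ``n`` and ``m`` (in either order)."""
    if not (0 <= n < model.k and 0 <= m < model.k):
        raise ValueError(f"cluster index out of range (k = {model.k})")
    if n == m:
        raise ValueError("mutual inclusion is defined for distinct clusters")
    orig = model.labels[: model.n_signals]
    mirr = model.labels[model.n_signals:]
    return int(np.sum(((orig == n) & (mirr == m)) | ((mirr == n) & (orig == m))))


def select_symmetric_pair(model: ClusterModel) -> tuple[int, int]:
    """The distinct cluster pair with the maximal mutual-inclusion score.

    Ties break deterministically: clusters are ranked by descending size
    (then ascending index), and the lexicographically first pair in that
    ranking among the score maximisers wins — larger clusters carry more
    evidence.
    """
    if model.k < 2:
        raise NoSymmetryError("need at least 2 clusters")
    sizes = model.cluster_sizes()
    order = np.lexsort((np.arange(model.k), -sizes))  # descending size, then index
    best, best_score = None, 0
    for a in range(model.k):
        for b in range(a + 1, model.k):
            n, m = int(order[a]), int(order[b])
            s = mutual_inclusion_score(model, n, m)
            if s > best_score:
                best, best_score = (n, m), s
    if best is None:
        raise NoSymmetryError(
            "no cluster pair has mutual inclusion; window is unmeasurable"
        )
    return best


def canonical_orientation(signal: np.ndarray) -> np.ndarray:
    """Flip sign if needed so the first local maximum precedes the first
    local minimum — the camera cannot tell inhale from exhale, so a
    reproducible convention stands in for physical sign."""
    s = np.asarray(signal, dtype=float)
    d = np.diff(s)
    peak = trough = None
    for i in range(1, len(s) - 1):
        if d[i - 1] > 0 >= d[i] and peak is None:
            peak = i
        if d[i - 1] < 0 <= d[i] and trough is None:
            trough = i
        if peak is not None and trough is not None:
            break
    if peak is not None and trough is not None and trough < peak:
        return -s
    return s


def fuse(signals: PixelSignalSet, model: ClusterModel, pair: tuple[int, int]) -> np.ndarray:
    """Merge the symmetric pair into one zero-mean respiration trace.

    Original signals in the second cluster of the pair are phase-inverted,
    then all original signals of both clusters are averaged sample-wise.
    """
    n, m = pair
    orig = model.labels[: model.n_signals]
    in_n = orig == n
    in_m = orig == m
    if not (in_n.any() or in_m.any()):
        raise NoSymmetryError("selected pair covers no original signals")
    stack = np.concatenate([signals.signals[in_n], -signals.signals[in_m]])
    fused = stack.mean(axis=0)
    fused = fused - fused.mean()
    return canonical_orientation(fused)


def project_2d(signals: PixelSignalSet, include_mirrors: bool = True) -> np.ndarray:
    """First two principal-component scores of the signal set (diagnostic).

    With mirrors included the point cloud is closed under negation, so the
    projection is symmetric about the origin.
    """
    if signals.n < 2:
        raise ValueError("need at least 2 signals")
    pts = signals.with_mirrors() if include_mirrors else signals.signals
    return PCA(n_components=2).fit_transform(pts)


def estimate_window(window: Window, mask, k: int = DEFAULT_N_CLUSTERS) -> np.ndarray:
    """ROI signals -> clustering -> pair selection -> fused trace."""
    sigset = prepare_signals(window, mask)
    model = cluster_with_mirrors(sigset, k=k)
    pair = select_symmetric_pair(model)
    return fuse(sigset, model, pair)
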