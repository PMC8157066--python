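"""Symmetry clustering, mutual inclusion, pair selection and fusion."""

import itertools

import numpy as np
import pytest

from breathcam.errors import NoROIError, NoSymmetryError
from breathcam.estimator import (ClusterModel, PixelSignalSet,
                                 cluster_with_mirrors, fuse,
                                 mutual_inclusion_score, prepare_signals,
                                 project_2d, select_symmetric_pair)
from breathcam.labeling import pearson
from breathcam.preprocessing import Window


def sigset(signals):
    signals = np.asarray(signals, dtype=float)
    signals = signals - signals.mean(axis=1, keepdims=True)
    return PixelSignalSet(signals=signals,
                          positions=np.zeros((len(signals), 2), dtype=int))


def base_signal(l=60, f=0.25, fps=5.0):
    return np.sin(2 * np.pi * f * np.arange(l) / fps)


def brute_force_pair(model: ClusterModel):
    """Exhaustive maximisation of the mutual-inclusion sum (oracle):
    evaluates f(n, m, i) by direct membership loops over every cluster
    pair and pixel."""
    orig = model.labels[: model.n_signals]
    mirr = model.labels[model.n_signals:]
    best_score, best_pairs = 0, []
    for n, m in itertools.combinations(range(model.k), 2):
        s = 0
        for i in range(model.n_signals):
            if (orig[i] == n and mirr[i] == m) or (mirr[i] == n and orig[i] == m):
                s += 1
        if s > best_score:
            best_score, best_pairs = s, [(n, m)]
        elif s == best_score and s > 0:
            best_pairs.append((n, m))
    return best_score, best_pairs


class TestPrepareSignals:
    def test_single_pixel_with_mirror(self):
        s = base_signal()
        frames = np.zeros((60, 1, 1, 3))
        frames[:, 0, 0, :] = 128.0 + s[:, None]
        win = Window(frames=frames, start_s=0.0, rate_hz=5.0)
        out = prepare_signals(win, np.ones((1, 1), bool))
        assert out.n == 1
        np.testing.assert_allclose(out.signals[0], s - s.mean(), atol=1e-12)
        pts = out.with_mirrors()
        np.testing.assert_allclose(pts[1], -pts[0])

    def test_constant_trace_excluded(self):
        frames = np.zeros((60, 1, 2, 3))
        frames[:, 0, 0, :] = 128.0
        frames[:, 0, 1, :] = 128.0 + base_signal()[:, None]
        win = Window(frames=frames, start_s=0.0, rate_hz=5.0)
        out = prepare_signals(win, np.ones((1, 2), bool))
        assert out.n == 1

    def test_all_signals_are_zero_mean(self):
        rng = np.random.default_rng(0)
        frames = rng.uniform(0, 255, (60, 3, 3, 3))
        win = Window(frames=frames, start_s=0.0, rate_hz=5.0)
        out = prepare_signals(win, np.ones((3, 3), bool))
        np.testing.assert_allclose(out.signals.sum(axis=1), 0.0, atol=1e-9)

    def test_empty_mask_raises_no_roi(self):
        win = Window(frames=np.zeros((60, 2, 2, 3)), start_s=0.0, rate_hz=5.0)
        with pytest.raises(NoROIError):
            prepare_signals(win, np.zeros((2, 2), bool))


class TestClustering:
    def test_antipodal_points_split(self):
        s = base_signal()
        model = cluster_with_mirrors(sigset([s, -s]), k=2)
        assert model.labels[0] != model.labels[1]

    def test_positive_scaling_leaves_clustering_unchanged(self):
        rng = np.random.default_rng(1)
        s = base_signal()
        sigs = [s + rng.normal(0, 0.2, s.size) for _ in range(4)]
        a = cluster_with_mirrors(sigset(sigs), k=3)
        scaled = [c * sig for c, sig in zip((0.5, 2.0, 7.0, 1.0), sigs)]
        b = cluster_with_mirrors(sigset(scaled), k=3)
        # same partition up to relabeling
        for i, j in itertools.combinations(range(len(a.labels)), 2):
            assert (a.labels[i] == a.labels[j]) == (b.labels[i] == b.labels[j])

    def test_toy_partition_matches_sign_grouping(self):
        """3 noisy copies of s and 3 of -s, k=2: the partition recovers the
        sign grouping and agrees with exhaustive 2-partition scoring under
        average-linkage cosine distance."""
        rng = np.random.default_rng(2)
        s = base_signal()
        pos = [s + rng.normal(0, 0.1, s.size) for _ in range(3)]
        neg = [-s + rng.normal(0, 0.1, s.size) for _ in range(3)]
        pts = np.array([p - p.mean() for p in pos + neg])

        def cosd(a, b):
            return 1.0 - a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

        best, best_cost = None, np.inf
        for assign in itertools.product([0, 1], repeat=5):
            lab = np.array((0,) + assign)
            if len(set(lab)) < 2:
                continue
            cost = 0.0
            for c in (0, 1):
                idx = np.flatnonzero(lab == c)
                pairs = list(itertools.combinations(idx, 2))
                if pairs:
                    cost += np.mean([cosd(pts[i], pts[j]) for i, j in pairs])
            if cost < best_cost:
                best, best_cost = lab, cost
        want = np.array([0, 0, 0, 1, 1, 1])
        assert np.array_equal(best, want) or np.array_equal(1 - best, want)

        model = cluster_with_mirrors(
            PixelSignalSet(signals=pts, positions=np.zeros((6, 2))), k=2)
        lab = model.labels[:6]
        assert len(set(lab[:3])) == 1 and len(set(lab[3:])) == 1
        assert lab[0] != lab[3]

    def test_too_few_signals_raise(self):
        with pytest.raises(NoROIError):
            cluster_with_mirrors(sigset([base_signal()]), k=2)


class TestMutualInclusion:
    def make_model(self, orig, mirr, k):
        return ClusterModel(labels=np.array(list(orig) + list(mirr)), k=k,
                            n_signals=len(orig))

    def test_perfect_split_scores_n(self):
        m = self.make_model([0, 0, 0], [1, 1, 1], k=2)
        assert mutual_inclusion_score(m, 0, 1) == 3
        assert mutual_inclusion_score(m, 1, 0) == 3  # symmetric in (n, m)

    def test_unrelated_clusters_score_zero(self):
        m = self.make_model([0, 0], [1, 1], k=3)
        assert mutual_inclusion_score(m, 0, 2) == 0

    def test_hand_enumerated_five_signal_assignment(self):
        # i:      1  2  3  4  5
        orig = [0, 0, 1, 2, 1]
        mirr = [1, 2, 0, 0, 1]
        m = self.make_model(orig, mirr, k=3)
        # manual evaluation of f over i: pairs straddling (0,1): i=1 (0->1),
        # i=3 (1->0); i=5 has both copies in 1 -> no. score(0,1) = 2
        assert mutual_inclusion_score(m, 0, 1) == 2
        # (0,2): i=2 (0->2), i=4 (2->0) -> 2
        assert mutual_inclusion_score(m, 0, 2) == 2
        # (1,2): none -> 0
        assert mutual_inclusion_score(m, 1, 2) == 0

    def test_same_cluster_rejected(self):
        m = self.make_model([0], [1], k=2)
        with pytest.raises(ValueError):
            mutual_inclusion_score(m, 1, 1)

    def test_bad_index_rejected(self):
        m = self.make_model([0], [1], k=2)
        with pytest.raises(ValueError):
            mutual_inclusion_score(m, 0, 5)


class TestPairSelection:
    def test_mirror_pair_selected(self):
        s = base_signal()
        sigs = sigset([s, -s])
        model = cluster_with_mirrors(sigs, k=2)
        pair = select_symmetric_pair(model)
        assert set(pair) == {0, 1}
        assert mutual_inclusion_score(model, *pair) == 2

    def test_matches_brute_force_on_random_instances(self):
        """Pair selection equals exhaustive maximisation for random
        cluster assignments (N <= 6, k <= 4)."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(2, 7))
            k = int(rng.integers(2, 5))
            labels = rng.integers(0, k, size=2 * n)
            model = ClusterModel(labels=labels, k=k, n_signals=n)
            want_score, want_pairs = brute_force_pair(model)
            if want_score == 0:
                with pytest.raises(NoSymmetryError):
                    select_symmetric_pair(model)
            else:
                got = select_symmetric_pair(model)
                assert mutual_inclusion_score(model, *got) == want_score
                assert tuple(sorted(got)) in [tuple(sorted(p)) for p in want_pairs]

    def test_noise_cluster_with_lower_score_never_wins(self):
        rng = np.random.default_rng(4)
        s = base_signal()
        pos = [s + rng.normal(0, 0.05, s.size) for _ in range(4)]
        neg = [-s + rng.normal(0, 0.05, s.size) for _ in range(4)]
        noise = [rng.normal(0, 1.0, s.size) for _ in range(2)]
        sigs = sigset(pos + neg + noise)
        model = cluster_with_mirrors(sigs, k=4)
        pair = select_symmetric_pair(model)
        # the selected clusters contain the breathing signals, not the noise
        orig = model.labels[:10]
        breathing = set(orig[:8])
        assert set(pair) <= breathing

    def test_all_zero_scores_raise_no_symmetry(self):
        # every cluster contains each pixel's original AND mirror
        model = ClusterModel(labels=np.array([0, 1, 0, 1]), k=2, n_signals=2)
        with pytest.raises(NoSymmetryError):
            select_symmetric_pair(model)


class TestFusion:
    def test_two_singleton_clusters_recover_signal(self):
        s = base_signal()
        sigs = sigset([s, -s])
        model = cluster_with_mirrors(sigs, k=2)
        fused = fuse(sigs, model, select_symmetric_pair(model))
        r = pearson(fused, s)
        assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_averaging_gain_over_single_pixels(self):
        """Fused output correlates with the truth better than the median
        single pixel does (seeded Monte-Carlo)."""
        rng = np.random.default_rng(5)
        s = base_signal()
        m = 8
        pos = [s + rng.normal(0, 1.0, s.size) for _ in range(m)]
        neg = [-s + rng.normal(0, 1.0, s.size) for _ in range(m)]
        sigs = sigset(pos + neg)
        model = cluster_with_mirrors(sigs, k=2)
        fused = fuse(sigs, model, select_symmetric_pair(model))
        single = np.median([abs(pearson(p, s)) for p in pos + neg])
        assert abs(pearson(fused, s)) > single

    def test_global_sign_invariance(self):
        rng = np.random.default_rng(6)
        s = base_signal()
        sigs_list = [s + rng.normal(0, 0.3, s.size) for _ in range(3)] + \
                    [-s + rng.normal(0, 0.3, s.size) for _ in range(3)]
        a_sigs = sigset(sigs_list)
        b_sigs = sigset([-x for x in sigs_list])
        ma = cluster_with_mirrors(a_sigs, k=2)
        mb = cluster_with_mirrors(b_sigs, k=2)
        fa = fuse(a_sigs, ma, select_symmetric_pair(ma))
        fb = fuse(b_sigs, mb, select_symmetric_pair(mb))
        assert abs(pearson(fa, fb)) == pytest.approx(1.0, abs=1e-9)

    def test_selected_clusters_are_near_negations(self):
        """Mirror-set invariance: centroids of the selected pair point in
        opposite directions on clean data."""
        rng = np.random.default_rng(7)
        s = base_signal()
        sigs = sigset([s + rng.normal(0, 0.1, s.size) for _ in range(5)]
                      + [-s + rng.normal(0, 0.1, s.size) for _ in range(5)])
        model = cluster_with_mirrors(sigs, k=3)
        n, m = select_symmetric_pair(model)
        pts = sigs.with_mirrors()
        ca = pts[model.labels == n].mean(axis=0)
        cb = pts[model.labels == m].mean(axis=0)
        cos = ca @ cb / (np.linalg.norm(ca) * np.linalg.norm(cb))
        assert cos <= -0.9

    def test_pair_without_originals_raises(self):
        model = ClusterModel(labels=np.array([0, 0, 1, 1]), k=3, n_signals=2)
        sigs = sigset([base_signal(), base_signal() + 0.1])
        with pytest.raises(NoSymmetryError):
            fuse(sigs, model, (2, 1))  # cluster 2 is empty, 1 holds mirrors only


class TestProject2D:
    def test_mirror_symmetry_about_origin(self):
        rng = np.random.default_rng(8)
        sigs = sigset(rng.normal(size=(4, 30)))
        xy = project_2d(sigs)
        np.testing.assert_allclose(xy[4:], -xy[:4], atol=1e-9)

    def test_rank_one_set_has_flat_second_component(self):
        s = base_signal()
        sigs = sigset([c * s for c in (1.0, 2.0, -1.5, 0.7)])
        xy = project_2d(sigs)
        np.testing.assert_allclose(xy[:, 1], 0.0, atol=1e-8)

    def test_pc1_variance_matches_eigendecomposition(self):
        rng = np.random.default_rng(9)
        s = base_signal()
        sigs = sigset([s + rng.normal(0, 0.2, s.size) for _ in range(4)]
                      + [-s + rng.normal(0, 0.2, s.size) for _ in range(4)])
        pts = sigs.with_mirrors()
        xy = project_2d(sigs)
        evals = np.linalg.eigvalsh(np.cov(pts.T, bias=False))
        assert xy[:, 0].var(ddof=1) == pytest.approx(evals[-1], rel=1e-9)
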