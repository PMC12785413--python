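import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scafdl.errors import UndefinedMetricError
from scafdl.metrics import (
    ProCurve,
    ScoredImage,
    auroc,
    evaluate_items,
    image_score,
    pixel_auroc,
    pro_curve,
    pro_score,
)


def pairwise_auroc(scores, labels):
    """Exhaustive pairwise-comparison statistic (ties count 1/2)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


class TestImageScore:
    def test_uniform_map(self):
        assert image_score(np.full((10, 10), 0.3, np.float32)) == pytest.approx(0.3)

    def test_exactly_k_hot(self):
        m = np.zeros(100, np.float32)
        m[:50] = 1.0
        assert image_score(m.reshape(10, 10), K=50) == pytest.approx(1.0)

    def test_half_k_hot(self):
        m = np.zeros(100, np.float32)
        m[:25] = 1.0
        assert image_score(m.reshape(10, 10), K=50) == pytest.approx(0.5)

    def test_monotone_in_pixel_values(self, rng):
        m = rng.random((10, 10)).astype(np.float32)
        base = image_score(m, K=50)
        m2 = m.copy()
        m2[3, 3] = min(1.0, m2[3, 3] + 0.5)
        assert image_score(m2, K=50) >= base

    def test_k_exceeding_pixels_rejected(self):
        with pytest.raises(ValueError):
            image_score(np.zeros((5, 5), np.float32), K=26)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert auroc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_reference_example(self):
        # 3 of 4 positive/negative pairs correctly ordered
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    @given(st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        # quantized scores force ties through the midrank convention
        scores = rng.integers(0, 6, n) / 5.0
        assert auroc(scores, labels) == pytest.approx(
            pairwise_auroc(scores, labels), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            auroc([0.2, 0.4], [1, 1])


def _random_items(rng, n_frac=2, n_norm=1, size=8):
    items = []
    for _ in range(n_frac):
        g = np.zeros((size, size), bool)
        while not g.any():
            g = rng.random((size, size)) > 0.8
        items.append(
            ScoredImage(saliency=rng.random((size, size)).astype(np.float32), label=1, mask=g)
        )
    for _ in range(n_norm):
        items.append(
            ScoredImage(saliency=rng.random((size, size)).astype(np.float32), label=0)
        )
    return items


class TestPixelAuroc:
    def test_oracle_prediction_is_one(self, rng):
        items = []
        for _ in range(3):
            g = rng.random((8, 8)) > 0.8
            g[0, 0] = True
            items.append(ScoredImage(saliency=g.astype(np.float32), label=1, mask=g))
        items.append(ScoredImage(saliency=np.zeros((8, 8), np.float32), label=0))
        assert pixel_auroc(items) == 1.0

    def test_anti_predictor_is_zero(self, rng):
        g = rng.random((8, 8)) > 0.7
        g[0, 0] = True
        items = [ScoredImage(saliency=(1 - g).astype(np.float32), label=1, mask=g)]
        assert pixel_auroc(items) == 0.0

    def test_matches_concatenation_oracle(self, rng):
        items = _random_items(rng, n_frac=2, n_norm=1)
        scores = np.concatenate([it.saliency.ravel() for it in items])
        labels = np.concatenate(
            [
                (it.mask if it.mask is not None else np.zeros((8, 8), bool)).ravel()
                for it in items
            ]
        ).astype(int)
        assert pixel_auroc(items) == pytest.approx(pairwise_auroc(scores, labels), abs=1e-9)


def pro_point_loop_oracle(items, thr):
    """Per-pixel loop recomputation of one PRO-curve point."""
    overlaps = []
    fp = 0
    neg = 0
    for it in items:
        g = it.mask if it.mask is not None else np.zeros_like(it.saliency, dtype=bool)
        h, w = it.saliency.shape
        inter = 0
        area = 0
        for r in range(h):
            for c in range(w):
                pred = it.saliency[r, c] > thr
                if g[r, c]:
                    area += 1
                    inter += pred
                else:
                    neg += 1
                    fp += pred
        if it.label == 1:
            overlaps.append(inter / area)
    return float(np.mean(overlaps)), fp / neg


class TestProCurve:
    def test_extreme_thresholds(self, rng):
        items = _random_items(rng)
        curve = pro_curve(items, thresholds=np.array([-0.1, 1.1]))
        # below min: everything predicted; above max: nothing
        i_lo = int(np.argmin(curve.thresholds))
        i_hi = int(np.argmax(curve.thresholds))
        assert curve.pro[i_lo] == 1.0 and curve.fpr[i_lo] == 1.0
        assert curve.pro[i_hi] == 0.0 and curve.fpr[i_hi] == 0.0

    def test_every_point_matches_pixel_loop(self, rng):
        items = _random_items(rng, n_frac=2, n_norm=1, size=16)
        thresholds = np.linspace(0, 1, 50)
        curve = pro_curve(items, thresholds=thresholds)
        by_thr = dict(zip(curve.thresholds, zip(curve.pro, curve.fpr)))
        for thr in thresholds:
            want_pro, want_fpr = pro_point_loop_oracle(items, thr)
            got_pro, got_fpr = by_thr[thr]
            assert got_pro == pytest.approx(want_pro, abs=1e-12)
            assert got_fpr == pytest.approx(want_fpr, abs=1e-12)

    def test_needs_fractured_items(self, rng):
        items = [ScoredImage(saliency=rng.random((8, 8)).astype(np.float32), label=0)]
        with pytest.raises(UndefinedMetricError):
            pro_curve(items)

    def test_normal_only_images_leave_pro_unchanged(self, rng):
        """Adding normal images with zero saliency never changes PRO; FPR
        can only shrink through the larger pooled negative set."""
        items = _random_items(rng, n_frac=3, n_norm=0)
        extra = items + [ScoredImage(saliency=np.zeros((8, 8), np.float32), label=0)]
        thr = np.linspace(0, 1, 20)
        c1 = pro_curve(items, thresholds=thr)
        c2 = pro_curve(extra, thresholds=thr)
        assert np.allclose(c1.pro, c2.pro)
        assert np.all(c2.fpr <= c1.fpr + 1e-12)


class TestProScore:
    def test_ideal_curve(self):
        c = ProCurve(
            thresholds=np.array([0.9, 0.1]),
            pro=np.array([1.0, 1.0]),
            fpr=np.array([0.0, 1.0]),
        )
        assert pro_score(c) == pytest.approx(1.0)

    def test_zero_curve(self):
        c = ProCurve(
            thresholds=np.array([0.9, 0.1]),
            pro=np.array([0.0, 0.0]),
            fpr=np.array([0.0, 1.0]),
        )
        assert pro_score(c) == 0.0

    def test_linear_toy_triangle(self):
        c = ProCurve(
            thresholds=np.array([1.0, 0.5]),
            pro=np.array([0.0, 1.0]),
            fpr=np.array([0.0, 0.3]),
        )
        assert pro_score(c, fpr_cap=0.3) == pytest.approx(0.5)

    def test_interpolation_at_cap(self):
        # PRO = FPR line: area up to the cap is cap^2/2, normalized cap/2
        c = ProCurve(
            thresholds=np.array([1.0, 0.0]),
            pro=np.array([0.0, 1.0]),
            fpr=np.array([0.0, 1.0]),
        )
        assert pro_score(c, fpr_cap=0.3) == pytest.approx(0.15)


class TestEvaluateItems:
    def test_oracle_saliency_all_metrics_one(self, rng):
        items = []
        for _ in range(4):
            g = rng.random((8, 8)) > 0.8
            g[2, 2] = True
            items.append(ScoredImage(saliency=g.astype(np.float32), label=1, mask=g))
        for _ in range(4):
            items.append(ScoredImage(saliency=np.zeros((8, 8), np.float32), label=0))
        report = evaluate_items(items, K=10)
        assert report.image_auroc == 1.0
        assert report.pixel_auroc == 1.0
        assert report.pro_auc == pytest.approx(1.0)

    def test_random_saliency_near_chance(self):
        """Null simulation: with random saliency, image AUROC concentrates
        around 0.5 for 40+40 images."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            items = []
            for _ in range(40):
                g = np.zeros((8, 8), bool)
                g[rng.integers(0, 8), rng.integers(0, 8)] = True
                items.append(
                    ScoredImage(saliency=rng.random((8, 8)).astype(np.float32), label=1, mask=g)
                )
            for _ in range(40):
                items.append(
                    ScoredImage(saliency=rng.random((8, 8)).astype(np.float32), label=0)
                )
            rep = evaluate_items(items, K=10)
            if 0.3 <= rep.image_auroc <= 0.7:
                hits += 1
        assert hits >= 19

    def test_metrics_bounded_and_curves_serialized(self, rng):
        items = _random_items(rng, n_frac=3, n_norm=3)
        rep = evaluate_items(items, K=10)
        for v in (rep.image_auroc, rep.pixel_auroc, rep.pro_auc):
            assert 0.0 <= v <= 1.0
        assert len(rep.roc["fpr"]) == len(rep.roc["tpr"])
        assert len(rep.pro["fpr"]) == len(rep.pro["pro"]) == len(rep.pro["thresholds"])
        assert len(rep.scores) == 6
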