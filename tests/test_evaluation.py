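import numpy as np
import pytest

from upna_ppi import (L3Table, compute_metrics, l3_prediction_correlation,
                      optimal_threshold, ppi_hits_at_top_k,
                      ppni_hits_at_bottom_k, roc_pr)


def _preds(scores):
    return {(f"a{i}", f"b{i}"): s for i, s in enumerate(scores)}


def _labels(labels):
    return {(f"a{i}", f"b{i}"): y for i, y in enumerate(labels)}


class TestHitsAtK:
    @pytest.mark.parametrize("scores,labels,k,expected", [
        ((0.9, 0.8, 0.1), (1, 1, 0), 2, 1.0),
        ((0.9, 0.8, 0.1), (0, 1, 1), 2, 0.5),
        ((0.9, 0.8, 0.1), (1, 1, 1), 3, 1.0),
    ])
    def test_top_k_hand_values(self, scores, labels, k, expected):
        assert ppi_hits_at_top_k(_preds(scores), _labels(labels), k) == expected

    @pytest.mark.parametrize("scores,labels,k,expected", [
        ((0.9, 0.8, 0.1), (1, 1, 0), 1, 1.0),
        ((0.1, 0.2, 0.9), (1, 1, 0), 1, 0.0),  # inverted ranking
    ])
    def test_bottom_k_hand_values(self, scores, labels, k, expected):
        assert ppni_hits_at_bottom_k(_preds(scores), _labels(labels), k) == expected

    def test_k_equal_n_is_prevalence(self):
        rng = np.random.default_rng(0)
        scores = rng.random(40)
        labels = [1] * 25 + [0] * 15
        assert ppi_hits_at_top_k(_preds(scores), _labels(labels), 40) == 25 / 40
        assert ppni_hits_at_bottom_k(_preds(scores), _labels(labels), 40) == 15 / 40

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            ppi_hits_at_top_k(_preds((0.5,)), _labels((1,)), 0)
        with pytest.raises(ValueError):
            ppi_hits_at_top_k(_preds((0.5,)), _labels((1,)), 2)

    def test_tie_break_deterministic(self):
        # equal scores: canonical pair order decides
        preds = {("a", "b"): 0.5, ("c", "d"): 0.5}
        labels = {("a", "b"): 1, ("c", "d"): 0}
        assert ppi_hits_at_top_k(preds, labels, 1) == 1.0


class TestRocPr:
    def test_perfect_separation(self):
        auroc, auprc = roc_pr(_preds((0.9, 0.8, 0.2, 0.1)), _labels((1, 1, 0, 0)))
        assert (auroc, auprc) == (1.0, 1.0)

    def test_hand_mann_whitney(self):
        auroc, _ = roc_pr(_preds((0.9, 0.8, 0.1)), _labels((1, 0, 1)))
        assert auroc == 0.5

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(11)
        scores = rng.random(2000)
        labels = rng.integers(0, 2, size=2000)
        auroc, _ = roc_pr(_preds(scores), _labels(labels))
        assert abs(auroc - 0.5) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_pr(_preds((0.5, 0.6)), _labels((1, 1)))

    def test_auroc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.random(200)
        labels = rng.integers(0, 2, size=200)
        a1, _ = roc_pr(_preds(scores), _labels(labels))
        a2, _ = roc_pr(_preds(np.exp(5 * scores)), _labels(labels))
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestOptimalThreshold:
    def test_separated_returns_smallest_grid_point_above_negatives(self):
        preds = _preds((0.9, 0.9, 0.1, 0.1))
        labels = _labels((1, 1, 0, 0))
        thr, f1 = optimal_threshold(preds, labels, grid_step=0.001)
        assert f1 == 1.0
        assert thr == pytest.approx(0.101, abs=1e-9)

    def test_constant_half_predictions(self):
        preds = _preds((0.5,) * 10)
        labels = _labels((1,) * 5 + (0,) * 5)
        thr, f1 = optimal_threshold(preds, labels)
        assert f1 == pytest.approx(2 / 3)
        assert thr == pytest.approx(0.001)  # ties resolved to smallest threshold

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            optimal_threshold(_preds((0.4, 0.6)), _labels((0, 0)))


class TestL3Correlation:
    def test_monotone_gives_one(self):
        preds = {("a", "b"): 0.1, ("a", "c"): 0.5, ("b", "c"): 0.9}
        l3 = L3Table({("a", "b"): 0, ("a", "c"): 3, ("b", "c"): 7})
        assert l3_prediction_correlation(preds, l3) == pytest.approx(1.0)

    def test_constant_predictions_warn_and_return_zero(self):
        preds = {("a", "b"): 0.5, ("a", "c"): 0.5, ("b", "c"): 0.5}
        l3 = L3Table({("a", "b"): 0, ("a", "c"): 3, ("b", "c"): 7})
        with pytest.warns(UserWarning):
            assert l3_prediction_correlation(preds, l3) == 0.0

    def test_tied_spearman_hand_value(self):
        # hand computation with one tie under average-rank convention:
        # preds ranks (1, 2.5, 2.5, 4, 5); l3 ranks (1, 2, 3, 4, 5)
        # pearson of ranks = 0.9747 (computed by hand via rank covariance)
        pairs = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d")]
        preds = dict(zip(pairs, (0.1, 0.3, 0.3, 0.6, 0.9)))
        l3 = L3Table(dict(zip(pairs, (0, 1, 2, 5, 9))))
        got = l3_prediction_correlation(preds, l3)
        assert got == pytest.approx(0.9746794, abs=1e-6)

    def test_too_few_shared_pairs(self):
        preds = {("a", "b"): 0.5}
        l3 = L3Table({("a", "b"): 0})
        with pytest.raises(ValueError):
            l3_prediction_correlation(preds, l3)


def test_metrics_report_bundle():
    preds = _preds((0.9, 0.8, 0.3, 0.1))
    labels = _labels((1, 1, 0, 0))
    rep = compute_metrics(preds, labels, ks=(2, 4))
    assert rep.auroc == 1.0
    assert rep.ppi_hits[2] == 1.0 and rep.ppni_hits[2] == 1.0
    assert rep.ppi_hits[4] == 0.5  # prevalence at k = n
    d = rep.as_dict()
    assert set(d) >= {"auroc", "auprc", "ppi_hits", "optimal_threshold"}


def test_hits_profiles_past_class_boundary_on_separated_scores():
    """With fully separated scores, Hits@K is flat at 1 up to the class
    boundary and decays (never rises) beyond it."""
    n_pos, n_neg = 12, 8
    scores = list(np.linspace(0.9, 0.6, n_pos)) + list(np.linspace(0.4, 0.1, n_neg))
    preds = _preds(scores)
    labels = _labels([1] * n_pos + [0] * n_neg)
    top = [ppi_hits_at_top_k(preds, labels, k) for k in range(1, n_pos + n_neg + 1)]
    bottom = [ppni_hits_at_bottom_k(preds, labels, k)
              for k in range(1, n_pos + n_neg + 1)]
    assert all(x >= y - 1e-12 for x, y in zip(top, top[1:]))
    assert all(v == 1.0 for v in top[:n_pos])
    assert all(v == 1.0 for v in bottom[:n_neg])
    assert all(x >= y - 1e-12 for x, y in zip(bottom[n_neg - 1:], bottom[n_neg:]))
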