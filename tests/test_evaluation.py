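import numpy as np
import pytest

from ndd import (
    NNConfig,
    best_threshold_metrics,
    confusion_metrics,
    permute_interactions,
    ranking_metrics,
    run_cv,
    stratified_folds,
    tune_nested_cv,
)
from ndd.exceptions import MetricUndefinedError, ParameterError

# 4-sample hand fixture: TP=1, FP=1, FN=1 at threshold 0.5; AUC = 3/4
LABELS4 = [1, 1, 0, 0]
SCORES4 = [0.9, 0.4, 0.6, 0.1]

FAST_NN = NNConfig(hidden_sizes=(16,), epochs=8, batch_size=64,
                   learning_rate=0.05, dropout=0.0, bias_init="zeros")


class TestStratifiedFolds:
    def test_exact_stratification_when_divisible(self):
        pairs = [(0, i + 1) for i in range(100)]
        labels = [1] * 20 + [0] * 80
        split = stratified_folds(pairs, labels, k=5, seed=0)
        lab = dict(zip(pairs, labels))
        for fold in range(5):
            test = split.test_pairs(fold)
            assert len(test) == 20
            assert sum(lab[p] for p in test) == 4

    def test_every_pair_assigned_once(self):
        pairs = [(0, i + 1) for i in range(23)]
        labels = [1] * 7 + [0] * 16
        split = stratified_folds(pairs, labels, k=5, seed=1)
        assert sorted(split.assignments) == sorted(pairs)
        sizes = [len(split.test_pairs(f)) for f in range(5)]
        assert max(sizes) - min(sizes) <= 1

    def test_deterministic_given_seed(self):
        pairs = [(0, i + 1) for i in range(30)]
        labels = [i % 3 == 0 for i in range(30)]
        s1 = stratified_folds(pairs, labels, k=3, seed=42)
        s2 = stratified_folds(pairs, labels, k=3, seed=42)
        assert s1.assignments == s2.assignments

    def test_fewer_pairs_than_folds(self):
        with pytest.raises(ParameterError):
            stratified_folds([(0, 1), (0, 2)], [0, 1], k=5, seed=0)


class TestConfusionMetrics:
    def test_hand_oracle_at_half(self):
        assert confusion_metrics(LABELS4, SCORES4, 0.5) == (0.5, 0.5, 0.5)

    def test_perfect_separation(self):
        p, r, f = confusion_metrics([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1], 0.5)
        assert (p, r, f) == (1.0, 1.0, 1.0)

    def test_threshold_one_yields_zeros(self):
        assert confusion_metrics(LABELS4, SCORES4, 1.0) == (0.0, 0.0, 0.0)


def brute_force_best_f(labels, scores):
    """Exhaustive sweep over all candidate thresholds."""
    best = (-1.0, None)
    for t in sorted(set(list(scores) + [0.0, 1.0])):
        f = confusion_metrics(labels, scores, t)[2]
        if f > best[0]:
            best = (f, t)
    return best


class TestBestThreshold:
    def test_matches_exhaustive_sweep(self):
        p, r, f, thr = best_threshold_metrics(LABELS4, SCORES4)
        bf_f, bf_t = brute_force_best_f(LABELS4, SCORES4)
        assert f == pytest.approx(bf_f)
        assert thr == pytest.approx(bf_t)

    def test_perfectly_separated_takes_lowest_gap_threshold(self):
        labels = [1, 1, 0, 0]
        scores = [0.9, 0.8, 0.3, 0.1]
        p, r, f, thr = best_threshold_metrics(labels, scores)
        assert f == 1.0
        assert thr == pytest.approx(0.3)  # score > 0.3 captures exactly the positives

    def test_all_scores_equal(self):
        labels = [1, 0, 0, 0]
        scores = [0.4] * 4
        p, r, f, thr = best_threshold_metrics(labels, scores)
        # all-positive prediction: precision 1/4, recall 1 -> F = 0.4
        assert f == pytest.approx(0.4)

    def test_never_beaten_by_any_fixed_threshold(self, rng):
        labels = rng.integers(0, 2, 30)
        labels[0], labels[1] = 0, 1
        scores = rng.random(30).round(2)
        _, _, f_best, _ = best_threshold_metrics(labels, scores)
        for t in np.linspace(0, 1, 101):
            assert confusion_metrics(labels, scores, t)[2] <= f_best + 1e-12


class TestRankingMetrics:
    def test_auc_hand_oracle(self):
        auc, _ = ranking_metrics(LABELS4, SCORES4)
        assert auc == pytest.approx(0.75)

    def test_perfect_ranking(self):
        auc, aupr = ranking_metrics([1, 1, 0, 0], [0.9, 0.8, 0.3, 0.1])
        assert auc == 1.0 and aupr == 1.0

    def test_monotone_transform_invariance(self, rng):
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        scores = rng.random(50)
        a1, _ = ranking_metrics(labels, scores)
        a2, _ = ranking_metrics(labels, scores**3)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(2024)
        labels = np.repeat([0, 1], 1000)
        scores = rng.random(2000)
        auc, _ = ranking_metrics(labels, scores)
        assert 0.45 <= auc <= 0.55

    def test_single_class_undefined(self):
        with pytest.raises(MetricUndefinedError):
            ranking_metrics([1, 1], [0.3, 0.4])


class TestRunCV:
    def test_report_bookkeeping_and_determinism(self, small_benchmark):
        views, Y, _ = small_benchmark
        kw = dict(nn_cfg=FAST_NN, k=3, repeats=1, seed=5)
        r1 = run_cv(views, Y, **kw)
        r2 = run_cv(views, Y, **kw)
        assert len(r1.per_fold) == 3
        assert r1.to_dict() == r2.to_dict()

    def test_fold_f_measure_consistent_with_own_precision_recall(self, small_benchmark):
        views, Y, _ = small_benchmark
        rep = run_cv(views, Y, nn_cfg=FAST_NN, k=3, repeats=1, seed=5)
        for _, row in rep.per_fold.iterrows():
            p, r = row["precision"], row["recall"]
            expected = 2 * p * r / (p + r) if p + r else 0.0
            assert row["f_measure"] == pytest.approx(expected, abs=1e-12)

    def test_global_gip_scope_runs(self, small_benchmark):
        views, Y, _ = small_benchmark
        rep = run_cv(views, Y, nn_cfg=FAST_NN, k=3, repeats=1, seed=5,
                     gip_scope="global")
        assert 0.0 <= rep.auc <= 1.0

    def test_invalid_gip_scope(self, small_benchmark):
        views, Y, _ = small_benchmark
        with pytest.raises(ParameterError):
            run_cv(views, Y, k=3, repeats=1, seed=0, gip_scope="bogus")


class TestPermutationControl:
    def test_permutation_preserves_counts(self, small_benchmark):
        _, Y, _ = small_benchmark
        Yp = permute_interactions(Y, seed=0)
        assert Yp.n_interacting_entries == Y.n_interacting_entries
        assert not np.array_equal(Yp.Y, Y.Y)


class TestNestedCV:
    def test_grid_of_one_returns_that_config(self, small_benchmark):
        views, Y, _ = small_benchmark
        got = tune_nested_cv(views, Y, {"dropout": [0.0]}, base_nn=FAST_NN, seed=2)
        assert got.dropout == 0.0
        assert got.hidden_sizes == FAST_NN.hidden_sizes

    def test_matches_exhaustive_re_evaluation(self, small_benchmark):
        views, Y, _ = small_benchmark
        grids = {"hidden_sizes": [(8,), (16, 8)], "epochs": [2, 8]}
        got = tune_nested_cv(views, Y, grids, base_nn=FAST_NN, seed=2)
        # brute-force re-run of the same loop
        import itertools
        from dataclasses import replace

        best, best_aupr = None, -1.0
        keys = sorted(grids)
        for combo in itertools.product(*(grids[k] for k in keys)):
            cfg = replace(FAST_NN, **dict(zip(keys, combo)))
            rep = run_cv(views, Y, nn_cfg=cfg, k=3, repeats=1, seed=2)
            if rep.aupr > best_aupr:
                best, best_aupr = cfg, rep.aupr
        assert got == best

    def test_empty_grid_rejected(self, small_benchmark):
        views, Y, _ = small_benchmark
        with pytest.raises(ParameterError):
            tune_nested_cv(views, Y, {"dropout": []})
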