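import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ndd import (
    SelectionConfig,
    SimilarityMatrix,
    entropy_rank_filter,
    matrix_affinity,
    matrix_entropy,
    select_similarities,
)
from ndd.exceptions import (
    DegenerateInputError,
    DimensionError,
    ParameterError,
    SelectionEmptyError,
)


def sim(name, arr):
    return SimilarityMatrix(name, np.array(arr, dtype=float))


class TestEntropy:
    def test_uniform_matrix_is_log_m(self):
        for m in (2, 5, 9):
            A = sim("u", np.full((m, m), 0.3))
            assert matrix_entropy(A) == pytest.approx(math.log(m), abs=1e-12)

    def test_one_positive_entry_per_row_is_zero(self):
        A = sim("p", np.eye(4))
        assert matrix_entropy(A) == 0.0

    def test_two_row_hand_oracle(self):
        # rows (0.5, 0.5) and (0.1, 0.9): mean of ln 2 and 0.325083
        A = np.array([[0.5, 0.5], [0.1, 0.9]])
        expected = (math.log(2) + -(0.1 * math.log(0.1) + 0.9 * math.log(0.9))) / 2
        assert matrix_entropy(A) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.509115, abs=1e-6)

    def test_zero_row_contributes_zero_with_warning(self, caplog):
        A = np.array([[0.0, 0.0], [0.5, 0.5]])
        with caplog.at_level("WARNING"):
            e = matrix_entropy(A)
        assert e == pytest.approx(math.log(2) / 2)
        assert "zero-sum" in caplog.text

    def test_all_zero_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            matrix_entropy(sim("0", np.zeros((3, 3))))

    @given(st.integers(2, 7), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_bounds_and_row_rescaling_invariance(self, m, seed):
        rng = np.random.default_rng(seed)
        A = rng.random((m, m)) + 0.01
        A = (A + A.T) / 2
        e = matrix_entropy(SimilarityMatrix("a", A))
        assert 0.0 <= e <= math.log(m) + 1e-12
        # scaling a full row leaves its normalized distribution unchanged,
        # but scaling must keep the matrix symmetric, so compare row-wise
        W = A * 3.7
        assert matrix_entropy(SimilarityMatrix("b", W)) == pytest.approx(e, abs=1e-10)


class TestEntropyRankFilter:
    def test_uniform_view_always_removed(self):
        m = 6
        uniform = sim("uniform", np.full((m, m), 1.0 / m))
        onehot = sim("onehot", np.eye(m))
        assert entropy_rank_filter([uniform, onehot], c1=0.6) == ["onehot"]

    def test_sorted_ascending_by_entropy(self, rng):
        m = 8
        views = []
        for k, spread in enumerate([1, 3, 5]):  # more spread -> more entropy
            A = np.eye(m)
            for d in range(1, spread + 1):
                A += 0.5**d * (np.eye(m, k=d) + np.eye(m, k=-d))
            views.append(sim(f"v{k}", np.clip(A, 0, 1)))
        order = entropy_rank_filter(views, c1=0.99)
        entropies = {v.name: matrix_entropy(v) for v in views}
        assert order == sorted(order, key=lambda n: entropies[n])
        assert order[0] == "v0"

    def test_all_removed_raises(self):
        m = 5
        uniform = sim("u", np.full((m, m), 1.0 / m))
        with pytest.raises(SelectionEmptyError):
            entropy_rank_filter([uniform], c1=0.6)


class TestAffinity:
    def test_self_affinity_is_one(self, rng):
        A = rng.random((4, 4))
        A = sim("a", (A + A.T) / 2)
        assert matrix_affinity(A, A) == 1.0

    def test_two_by_two_hand_oracle(self):
        A = sim("a", [[1, 0], [0, 1]])
        B = sim("b", [[0, 1], [1, 0]])
        # D = sqrt(4 * 1) = 2  ->  S = 1/3
        assert matrix_affinity(A, B) == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_symmetric(self, rng):
        X = rng.random((5, 5))
        Y = rng.random((5, 5))
        A = sim("a", (X + X.T) / 2)
        B = sim("b", (Y + Y.T) / 2)
        assert matrix_affinity(A, B) == matrix_affinity(B, A)

    def test_dimension_mismatch(self):
        with pytest.raises(DimensionError):
            matrix_affinity(sim("a", np.eye(2)), sim("b", np.eye(3)))


def brute_force_selection(views, c1, c2):
    """Independent re-execution of the filter-rank-prune procedure."""
    m = views[0].m
    ent = {v.name: matrix_entropy(v) for v in views}
    ranked = sorted(
        (n for n, e in ent.items() if e <= c1 * math.log(m)),
        key=lambda n: (ent[n], n),
    )
    by_name = {v.name: v for v in views}
    selected = []
    while ranked:
        c = min(ranked, key=lambda n: (ent[n], n))
        selected.append(c)
        ranked = [
            n for n in ranked
            if n != c and matrix_affinity(by_name[c], by_name[n]) <= c2
        ]
    return selected


class TestSelect:
    def test_single_candidate_selected(self):
        v = sim("only", np.eye(3))
        res = select_similarities([v])
        assert res.selected == ("only",)
        assert res.eliminated == {}

    def test_duplicate_eliminated_by_name_tiebreak(self):
        A = np.eye(4) + 0.4 * (np.eye(4, k=1) + np.eye(4, k=-1))
        res = select_similarities([sim("b_copy", A), sim("a_copy", A)])
        assert res.selected == ("a_copy",)
        assert res.eliminated == {"b_copy": "redundant_with:a_copy"}

    def test_matches_brute_force_on_mixed_fixture(self, rng):
        m = 6
        base = np.eye(m) + 0.3 * (np.eye(m, k=1) + np.eye(m, k=-1))
        views = [
            sim("w", base),
            sim("x", np.clip(base + 0.02 * np.ones((m, m)), 0, 1)),  # close to w
            sim("y", np.eye(m)),
            sim("z", np.full((m, m), 1.0 / m)),  # uniform, filtered out
        ]
        cfg = SelectionConfig(c1=0.6, c2=0.6)
        res = select_similarities(views, cfg)
        assert list(res.selected) == brute_force_selection(views, cfg.c1, cfg.c2)
        assert res.eliminated["z"] == "high_entropy"
        # every surviving pair respects the redundancy bound
        by_name = {v.name: v for v in views}
        for a in res.selected:
            for b in res.selected:
                if a != b:
                    assert matrix_affinity(by_name[a], by_name[b]) <= cfg.c2

    def test_deterministic(self, rng):
        m = 5
        views = []
        for n in ("a", "b", "c"):
            band = np.eye(m) + 0.3 * (np.eye(m, k=1) + np.eye(m, k=-1))
            jitter = rng.random((m, m)) * 0.05
            views.append(sim(n, np.clip(band + (jitter + jitter.T) / 2, 0, 1)))
        r1 = select_similarities(views)
        r2 = select_similarities(list(views))
        assert r1.selected == r2.selected
        assert dict(r1.eliminated) == dict(r2.eliminated)

    def test_duplicate_names_rejected(self):
        v = sim("dup", np.eye(3))
        with pytest.raises(ParameterError):
            select_similarities([v, v])

    def test_thresholds_validated(self):
        with pytest.raises(ParameterError):
            SelectionConfig(c1=1.5)
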