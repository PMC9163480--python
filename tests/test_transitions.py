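"""Transition counting, adjusted residuals, Markov estimation."""

import numpy as np
import pytest
from scipy import stats

from conftest import bouts_from_states

from ethoseq.event_log import SOURCE_STATES, TARGET_STATES
from ethoseq.transitions import (TransitionMatrix,
                                 count_transitions, fit_markov,
                                 independence_residuals, pearson_chi_square,
                                 pool_matrices)


def _random_state_lists(rng, n_bouts):
    lists = []
    for _ in range(n_bouts):
        length = int(rng.integers(1, 8))
        states = list(rng.choice(SOURCE_STATES, size=length))
        states.append("end")
        lists.append(states)
    return lists


class TestCountTransitions:
    def test_single_pair(self):
        m = count_transitions(bouts_from_states([["touch", "end"]]))
        assert m.n_transitions == 1
        assert m.counts[m.row_labels.index("touch"),
                        m.col_labels.index("end")] == 1

    def test_repeat_collapse(self):
        m = count_transitions(bouts_from_states([["touch", "touch", "bump", "end"]]),
                              collapse_repeats=True)
        df = m.to_frame()
        assert df.loc["touch", "bump"] == 1
        assert df.loc["bump", "end"] == 1
        assert m.n_transitions == 2

    def test_no_transitions_out_of_end(self):
        m = count_transitions(bouts_from_states([["touch", "end"]] * 5))
        assert "end" not in m.row_labels

    def test_matches_naive_pairwise_recount(self):
        rng = np.random.default_rng(3)
        lists = _random_state_lists(rng, 200)
        m = count_transitions(bouts_from_states(lists), collapse_repeats=True)
        # oracle: naive double loop over adjacent pairs after collapsing
        expected = {}
        for states in lists:
            collapsed = [s for k, s in enumerate(states)
                         if k == 0 or s != states[k - 1]]
            for a, b in zip(collapsed, collapsed[1:]):
                expected[(a, b)] = expected.get((a, b), 0) + 1
        for i, rl in enumerate(m.row_labels):
            for j, cl in enumerate(m.col_labels):
                assert m.counts[i, j] == expected.get((rl, cl), 0)

    def test_count_distributes_over_pooling(self):
        rng = np.random.default_rng(4)
        a = bouts_from_states(_random_state_lists(rng, 50))
        b = bouts_from_states(_random_state_lists(rng, 70))
        whole = count_transitions(a + b)
        pooled = pool_matrices([count_transitions(a), count_transitions(b)])
        assert np.array_equal(whole.counts, pooled.counts)


class TestPoolMatrices:
    def test_elementwise_sum(self):
        m = count_transitions(bouts_from_states([["touch", "end"]]))
        p = pool_matrices([m, m])
        assert p.n_transitions == 2

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pool_matrices([])

    def test_label_mismatch_lists_difference(self):
        m1 = TransitionMatrix(("a", "b"), ("a", "b", "end"), np.zeros((2, 3)))
        m2 = TransitionMatrix(("a", "c"), ("a", "c", "end"), np.zeros((2, 3)))
        with pytest.raises(ValueError, match="b"):
            pool_matrices([m1, m2])

    def test_pooling_commutes_with_permutation(self):
        rng = np.random.default_rng(5)
        ms = [TransitionMatrix(SOURCE_STATES, TARGET_STATES,
                               rng.integers(0, 9, (8, 9))) for _ in range(6)]
        base = pool_matrices(ms).counts
        perm = [ms[i] for i in rng.permutation(6)]
        assert np.array_equal(pool_matrices(perm).counts, base)


class TestIndependenceResiduals:
    def test_perfect_independence_all_zero(self):
        m = TransitionMatrix(("a", "b"), ("x", "y"), [[5, 5], [5, 5]])
        res = independence_residuals(m)
        assert np.allclose(res.adjusted_residual, 0.0)
        assert not res.significant.any()

    def test_diagonal_table_residual_magnitude(self):
        # 2x2 [[20,0],[0,20]]: E = 10 everywhere, both marginals are N/2,
        # so r = (20-10)/sqrt(10 * 0.5 * 0.5) = 10/sqrt(2.5)
        m = TransitionMatrix(("a", "b"), ("x", "y"), [[20, 0], [0, 20]])
        res = independence_residuals(m, alpha=0.05)
        expected_r = 10.0 / np.sqrt(2.5)
        assert np.allclose(np.abs(res.adjusted_residual), expected_r)
        assert res.significant.all()

    def test_empty_matrix_rejected(self):
        m = TransitionMatrix(("a",), ("x",), [[0]])
        with pytest.raises(ValueError):
            independence_residuals(m)

    def test_zero_expected_cells_flagged_not_significant(self):
        m = TransitionMatrix(("a", "b"), ("x", "y"), [[10, 0], [10, 0]])
        with pytest.warns(UserWarning, match="zero expected"):
            res = independence_residuals(m)
        j = res.col_labels.index("y")
        assert not res.significant[:, j].any()

    def test_structural_zeros_excluded_from_testing(self):
        bouts = bouts_from_states([["touch", "bump", "touch", "end"]] * 30)
        m = count_transitions(bouts, collapse_repeats=True)
        res = independence_residuals(m)
        i = res.row_labels.index("touch")
        j = res.col_labels.index("touch")
        assert not res.tested[i, j]
        assert np.isnan(res.adjusted_residual[i, j])

    @pytest.mark.parametrize("size", range(3, 10))
    def test_null_flag_rate_near_alpha(self, size):
        """Source-independent targets: ~5% of cells flagged at alpha=0.05."""
        rng = np.random.default_rng(1000 + size)
        flagged = tested = 0
        for _ in range(150):
            prow = rng.dirichlet(np.full(size, 5.0))
            pcol = rng.dirichlet(np.full(size, 5.0))
            src = rng.choice(size, 800, p=prow)
            tgt = rng.choice(size, 800, p=pcol)
            counts = np.zeros((size, size), dtype=int)
            np.add.at(counts, (src, tgt), 1)
            m = TransitionMatrix(tuple(f"r{i}" for i in range(size)),
                                 tuple(f"c{j}" for j in range(size)), counts)
            res = independence_residuals(m, alpha=0.05)
            ok = res.tested & np.isfinite(res.adjusted_residual)
            flagged += int(res.significant[ok].sum())
            tested += int(ok.sum())
        assert 0.03 <= flagged / tested <= 0.07

    def test_chi_square_matches_scipy_oracle(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(1, 30, size=(5, 6))
        m = TransitionMatrix(tuple(f"r{i}" for i in range(5)),
                             tuple(f"c{j}" for j in range(6)), counts)
        res = independence_residuals(m)
        chi2_ref = stats.chi2_contingency(counts, correction=False).statistic
        assert pearson_chi_square(res) == pytest.approx(chi2_ref, abs=1e-9)

    def test_permutation_method_agrees_on_strong_effect(self):
        m = TransitionMatrix(("a", "b"), ("x", "y"), [[40, 5], [5, 40]])
        res = independence_residuals(m, method="permutation", n_permutations=500,
                                     rng=np.random.default_rng(0))
        assert res.significant.all()

    def test_bonferroni_is_stricter(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(5, 40, size=(6, 6))
        m = TransitionMatrix(tuple(f"r{i}" for i in range(6)),
                             tuple(f"c{j}" for j in range(6)), counts)
        plain = independence_residuals(m, alpha=0.05)
        bonf = independence_residuals(m, alpha=0.05, bonferroni=True)
        assert bonf.significant.sum() <= plain.significant.sum()


class TestFitMarkov:
    def test_even_split(self):
        bouts = bouts_from_states([["touch", "bump", "end"]] * 2
                                  + [["touch", "end"]] * 2)
        mk = fit_markov(count_transitions(bouts))
        assert mk.p("touch", "bump") == pytest.approx(0.5)
        assert mk.p("touch", "end") == pytest.approx(0.5)

    def test_single_transition_is_certain(self):
        mk = fit_markov(count_transitions(bouts_from_states([["chase", "end"]])))
        assert mk.p("chase", "end") == 1.0

    def test_unobserved_rows_flagged_undefined(self):
        mk = fit_markov(count_transitions(bouts_from_states([["touch", "end"]])))
        i = mk.row_labels.index("grapple")
        assert not mk.defined[i]
        assert np.isnan(mk.prob[i]).all()

    def test_rows_sum_to_one_and_are_mle(self):
        rng = np.random.default_rng(11)
        bouts = bouts_from_states(_random_state_lists(rng, 150))
        m = count_transitions(bouts)
        mk = fit_markov(m)
        sums = np.nansum(mk.prob[mk.defined], axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        # local optimality of the multinomial likelihood per row
        counts = m.counts.astype(float)
        for i in np.flatnonzero(mk.defined):
            p = mk.prob[i]
            pos = counts[i] > 0
            base = np.sum(counts[i][pos] * np.log(p[pos]))
            for j in np.flatnonzero(pos):
                for eps in (0.01, -0.01):
                    q = p.copy()
                    if not (0 < q[j] + eps < 1):
                        continue
                    q[j] += eps
                    q = q / q.sum()
                    alt = np.sum(counts[i][pos] * np.log(q[pos]))
                    assert alt <= base + 1e-12
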