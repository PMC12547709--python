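"""Metrics against brute-force oracles; WNS and TOPSIS combiners."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ttegast.metrics import (
    DecisionMatrix,
    auroc_at,
    concordance,
    mae,
    topsis_select,
    weighted_normalised_sum,
)
from ttegast.outcome import DAYS_PER_MONTH


def brute_force_auroc(scores, t, e, horizon):
    pos = [s for s, ti, ei in zip(scores, t, e) if ei == 1 and ti <= horizon]
    neg = [s for s, ti, ei in zip(scores, t, e) if ti > horizon]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_concordance(p, t, e):
    num, den = 0.0, 0
    n = len(t)
    for i in range(n):
        for j in range(n):
            usable = (t[i] < t[j] and e[i] == 1) or (t[i] == t[j] and e[i] == 1 and e[j] == 0)
            if not usable:
                continue
            den += 1
            num += 1.0 if p[i] < p[j] else (0.5 if p[i] == p[j] else 0.0)
    return num / den, den


class TestMae:
    def test_median_of_absolute_errors_in_months(self):
        d = DAYS_PER_MONTH
        pred = np.array([5, 8, 12]) * d
        obs = np.array([5, 10, 18]) * d
        assert mae(pred, obs, [1, 1, 1]) == pytest.approx(2.0)

    def test_perfect_predictions_zero(self):
        assert mae([100, 200], [100, 200], [1, 1]) == 0.0

    def test_censored_excluded(self):
        pred = [100, 999, 200]
        obs = [100, 5, 260]
        assert mae(pred, obs, [1, 0, 1]) == mae([100, 200], [100, 260], [1, 1])

    def test_all_censored_errors(self):
        with pytest.raises(ValueError):
            mae([1.0], [1.0], [0])


class TestAuroc:
    def test_perfect_separation(self):
        s = [0.9, 0.8, 0.1, 0.2]
        t = [100, 200, 500, 600]
        assert auroc_at(s, t, [1, 1, 0, 0], 365) == 1.0

    def test_constant_scores_half(self):
        assert auroc_at([0.5] * 4, [100, 200, 500, 600], [1, 1, 0, 0], 365) == 0.5

    def test_censored_before_horizon_excluded(self):
        # the early-censored subject must not contribute as a negative
        s = [0.9, 0.0, 0.1]
        t = [100, 50, 500]
        e = [1, 0, 0]
        assert auroc_at(s, t, e, 365) == 1.0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(20, 200))
            s = rng.choice(np.round(rng.random(7), 2), n)  # forced ties
            t = rng.choice(np.arange(30, 700, 30), n).astype(float)
            e = (rng.random(n) < 0.6).astype(int)
            if not (((e == 1) & (t <= 365)).any() and (t > 365).any()):
                continue
            assert auroc_at(s, t, e, 365) == pytest.approx(
                brute_force_auroc(s, t, e, 365), abs=1e-12)


class TestConcordance:
    def test_perfect_ordering(self):
        t = [10.0, 20, 30, 40]
        c, n = concordance(t, t, [1, 1, 1, 1])
        assert c == 1.0 and n == 6

    def test_identical_predictions_half(self):
        c, _ = concordance([5.0] * 4, [10.0, 20, 30, 40], [1, 1, 1, 1])
        assert c == 0.5

    def test_matches_brute_force_with_ties_and_censoring(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = 150
            t = rng.choice(np.arange(1, 25), n).astype(float)  # heavy event-time ties
            e = (rng.random(n) < 0.6).astype(int)
            p = rng.choice(np.arange(1, 12), n).astype(float)  # heavy prediction ties
            c, npairs = concordance(p, t, e)
            oc, on = brute_force_concordance(p, t, e)
            assert npairs == on
            assert c == pytest.approx(oc, abs=1e-12)


class TestWeightedNormalisedSum:
    def test_dominating_trial_scores_one(self):
        comp = weighted_normalised_sum([2.0, 4.0], [0.9, 0.7])
        assert comp[0] == 1.0 and comp[1] == 0.0

    def test_weights_three_to_one(self):
        # A best on MAE / worst on AUROC, B the converse
        comp = weighted_normalised_sum([2.0, 4.0], [0.7, 0.9])
        assert comp[0] == pytest.approx(0.75)
        assert comp[1] == pytest.approx(0.25)

    def test_constant_criterion_maps_to_half(self):
        comp = weighted_normalised_sum([3.0, 3.0], [0.6, 0.8])
        assert comp[0] == pytest.approx((3 * 0.5 + 0.0) / 4)
        assert comp[1] == pytest.approx((3 * 0.5 + 1.0) / 4)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6), st.floats(0.1, 50.0), st.floats(-5.0, 5.0))
    def test_invariant_under_affine_rescaling(self, seed, a, b):
        rng = np.random.default_rng(seed)
        m = rng.uniform(1, 5, 6)
        r = rng.uniform(0.5, 0.9, 6)
        base = weighted_normalised_sum(m, r)
        scaled = weighted_normalised_sum(a * m + b, r)
        assert np.allclose(base, scaled, atol=1e-12)


def _oracle_topsis(values, directions, weights):
    V = np.asarray(values, float)
    R = V / np.sqrt((V ** 2).sum(axis=0))
    W = R * weights
    ideal = [W[:, j].max() if directions[j] == 1 else W[:, j].min() for j in range(V.shape[1])]
    anti = [W[:, j].min() if directions[j] == 1 else W[:, j].max() for j in range(V.shape[1])]
    dp = np.sqrt(((W - ideal) ** 2).sum(axis=1))
    dm = np.sqrt(((W - anti) ** 2).sum(axis=1))
    return dm / (dp + dm)


class TestTopsis:
    def _dm(self, values):
        return DecisionMatrix(row_ids=list(range(len(values))),
                              criteria=["mae", "auroc", "conc"],
                              directions=np.array([-1, 1, 1]), values=np.array(values))

    def test_dominating_row_selected_with_closeness_one(self):
        best, c = topsis_select(self._dm([[2.0, 0.9, 0.8], [4.0, 0.6, 0.5]]))
        assert best == 0
        assert c[0] == pytest.approx(1.0)
        assert c[1] == pytest.approx(0.0)

    def test_three_by_three_matches_step_by_step_oracle(self):
        values = [[2, 0.7, 0.65], [3, 0.75, 0.67], [4, 0.8, 0.7]]
        _, c = topsis_select(self._dm(values))
        oracle = _oracle_topsis(values, [-1, 1, 1], np.full(3, 1 / 3))
        assert np.allclose(c, oracle, atol=1e-9)

    def test_row_permutation_permutes_closeness(self):
        values = [[2, 0.7, 0.65], [3, 0.75, 0.67], [4, 0.8, 0.7]]
        _, c1 = topsis_select(self._dm(values))
        _, c2 = topsis_select(self._dm(values[::-1]))
        assert np.allclose(c1, c2[::-1], atol=1e-12)

    def test_random_matrices_match_oracle_and_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            vals = rng.uniform(0.1, 5.0, size=(5, 3))
            _, c = topsis_select(self._dm(vals.tolist()))
            oracle = _oracle_topsis(vals, [-1, 1, 1], np.full(3, 1 / 3))
            assert np.allclose(c, oracle, atol=1e-9)
            assert np.all((c >= 0) & (c <= 1))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            topsis_select(self._dm([[1.0, 0.5, 0.5]]))
        with pytest.raises(ValueError):
            topsis_select(DecisionMatrix(["a", "b"], ["x"], np.array([1]),
                                         np.array([[0.0], [0.0]])))
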