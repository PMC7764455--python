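"""PROMETHEE preference functions, flows, and rank tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ffqopt.promethee import (
    DecisionMatrix,
    PreferenceParams,
    aggregate_ranks,
    flows,
    fractional_ranks,
    pairwise_preferences,
    preference_value,
    rank_alternatives,
    rank_decision_matrix,
)


def oracle_pi(values, maximizing, q, weights):
    """Plain-loop preference index: for each ordered pair and measure,
    orient the difference, apply the V-shaped function, weight-average."""
    n, N = values.shape
    pi = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            total = 0.0
            for j in range(N):
                d = values[a, j] - values[b, j]
                if not maximizing[j]:
                    d = -d
                if d <= 0:
                    p = 0.0
                elif d <= q[j]:
                    p = d / q[j]
                else:
                    p = 1.0
                total += weights[j] * p
            pi[a, b] = total / N
    return pi


def oracle_flows(pi):
    n = len(pi)
    plus = np.array([sum(pi[i, x] for x in range(n) if x != i) / (n - 1) for i in range(n)])
    minus = np.array([sum(pi[x, i] for x in range(n) if x != i) / (n - 1) for i in range(n)])
    return plus, minus, plus - minus


def random_decision(rng, n_alt, n_meas):
    return DecisionMatrix(
        alternatives=tuple(f"M{i}" for i in range(n_alt)),
        measures=tuple(f"q{j}" for j in range(n_meas)),
        maximizing=tuple(bool(rng.integers(0, 2)) for _ in range(n_meas)),
        values=rng.uniform(-2, 2, size=(n_alt, n_meas)),
    )


class TestPreferenceFunction:
    def test_piecewise_branches(self):
        assert preference_value(-0.3, 1.0) == 0.0
        assert preference_value(0.5, 1.0) == 0.5
        assert preference_value(2.0, 1.0) == 1.0

    def test_continuous_and_nondecreasing(self):
        xs = np.linspace(-2, 3, 500)
        ys = preference_value(xs, 1.5)
        assert (np.diff(ys) >= -1e-12).all()
        assert abs(preference_value(1.5, 1.5) - 1.0) < 1e-12

    def test_nonpositive_q_rejected(self):
        with pytest.raises(ValueError):
            preference_value(0.5, 0.0)

    @settings(deadline=None, derandomize=True)
    @given(
        d=st.floats(-10, 10, allow_nan=False),
        q=st.floats(0.01, 10, allow_nan=False),
    )
    def test_bounded_and_one_sided(self, d, q):
        """p(x) stays in [0, 1] and at most one of p(d), p(−d) is positive."""
        p, p_neg = preference_value(d, q), preference_value(-d, q)
        assert 0.0 <= p <= 1.0
        assert min(p, p_neg) == 0.0


class TestPairwisePreferences:
    def test_identical_alternatives_have_zero_preference(self):
        D = DecisionMatrix(("A", "B"), ("q",), (True,), np.array([[1.0], [1.0]]))
        pi = pairwise_preferences(D, PreferenceParams(q=(1.0,)))
        assert (pi.to_numpy() == 0.0).all()

    def test_saturation_when_dominating_beyond_q(self):
        D = DecisionMatrix(("A", "B"), ("q1", "q2"), (True, True),
                           np.array([[5.0, 5.0], [0.0, 0.0]]))
        pi = pairwise_preferences(D, PreferenceParams(q=(1.0, 1.0)))
        assert pi.at["A", "B"] == pytest.approx(1.0)
        assert pi.at["B", "A"] == 0.0

    def test_matches_loop_oracle(self, rng):
        for _ in range(50):
            D = random_decision(rng, int(rng.integers(2, 6)), int(rng.integers(1, 4)))
            q = rng.uniform(0.1, 2.0, size=len(D.measures))
            w = rng.uniform(0.1, 2.0, size=len(D.measures))
            pi = pairwise_preferences(D, PreferenceParams(q=tuple(q), weights=tuple(w)))
            expected = oracle_pi(D.values, list(D.maximizing), q, w)
            np.testing.assert_allclose(pi.to_numpy(), expected, atol=1e-12)

    def test_one_sided_preference(self, rng):
        for _ in range(20):
            D = random_decision(rng, 4, 2)
            # per measure, d and −d cannot both be positive: check measure-wise
            for j in range(2):
                Dj = DecisionMatrix(D.alternatives, (D.measures[j],), (D.maximizing[j],),
                                    D.values[:, [j]])
                pi = pairwise_preferences(Dj, PreferenceParams(q=(1.0,))).to_numpy()
                assert (np.minimum(pi, pi.T) == 0.0).all()

    def test_scale_equivariance(self, rng):
        D = random_decision(rng, 4, 3)
        q = np.array([0.5, 1.0, 2.0])
        pi1 = pairwise_preferences(D, PreferenceParams(q=tuple(q)))
        scaled = D.values.copy()
        scaled[:, 1] *= 7.5
        D2 = DecisionMatrix(D.alternatives, D.measures, D.maximizing, scaled)
        q2 = q.copy()
        q2[1] *= 7.5
        pi2 = pairwise_preferences(D2, PreferenceParams(q=tuple(q2)))
        np.testing.assert_allclose(pi1.to_numpy(), pi2.to_numpy(), atol=1e-12)


class TestFlows:
    def test_two_alternative_hand_example(self):
        pi = pd.DataFrame([[0.0, 0.6], [0.1, 0.0]], index=["A", "B"], columns=["A", "B"])
        fr = flows(pi)
        assert fr.phi_net[0] == pytest.approx(0.5)
        assert fr.phi_net[1] == pytest.approx(-0.5)
        assert list(fr.ranks) == [1.0, 2.0]

    def test_all_zero_preferences_tie_everyone(self):
        fr = flows(np.zeros((4, 4)))
        assert (fr.phi_net == 0.0).all()
        assert (fr.ranks == 2.5).all()

    def test_identical_alternatives_get_fractional_tied_rank(self):
        # two clones beating a third: both rank 1.5, as in the published
        # tables where the two baselines tie on the full questionnaire
        pi = np.array([[0.0, 0.0, 0.8], [0.0, 0.0, 0.8], [0.0, 0.0, 0.0]])
        fr = flows(pi)
        assert list(fr.ranks) == [1.5, 1.5, 3.0]

    def test_conservation_and_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 7))
            pi = rng.uniform(0, 1, size=(n, n))
            np.fill_diagonal(pi, 0.0)
            fr = flows(pi)
            plus, minus, net = oracle_flows(pi)
            np.testing.assert_allclose(fr.phi_plus, plus, atol=1e-12)
            np.testing.assert_allclose(fr.phi_minus, minus, atol=1e-12)
            assert abs(fr.phi_net.sum()) < 1e-9

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            flows(np.zeros((2, 3)))


class TestRanking:
    def test_single_measure_ranking_is_orientation_aware_sort(self, rng):
        for maximizing in (True, False):
            vals = rng.uniform(0, 1, size=(5, 1))
            D = DecisionMatrix(tuple("ABCDE"), ("q",), (maximizing,), vals)
            fr = rank_decision_matrix(D)
            key = -vals[:, 0] if maximizing else vals[:, 0]
            expected = fractional_ranks(-key)
            np.testing.assert_allclose(fr.ranks, expected)

    def test_dominant_alternative_ranks_first(self, rng):
        for _ in range(30):
            D = random_decision(rng, 4, 3)
            vals = D.values.copy()
            # make alternative 0 weakly best everywhere, strictly on measure 0
            for j, mx in enumerate(D.maximizing):
                best = vals[:, j].max() if mx else vals[:, j].min()
                vals[0, j] = best + (0.5 if mx else -0.5) * (j == 0)
            D2 = DecisionMatrix(D.alternatives, D.measures, D.maximizing, vals)
            fr = rank_decision_matrix(D2)
            assert fr.phi_net[0] == fr.phi_net.max()

    def test_planted_winner_tops_avg_column(self):
        """A model strictly better on every measure in every context ranks
        1 everywhere including the aggregate column."""
        records = []
        for subset in ("F0", "F1"):
            for model, f1 in (("good", 0.9), ("mid", 0.6), ("bad", 0.3)):
                for fold in range(3):
                    for measure, v in (("precision", f1), ("recall", f1), ("f1", f1)):
                        records.append(
                            dict(model=model, subset=subset, target="t", fold=fold,
                                 measure=measure, value=v + 0.01 * fold, task="classification")
                        )
        metrics = pd.DataFrame.from_records(records)
        table = rank_alternatives(metrics, "methods_per_subset", "t", "classification")
        assert table.loc["good"].eq(1.0).all()
        swapped = rank_alternatives(metrics, "subsets_per_method", "t", "classification")
        assert set(swapped.index) == {"F0", "F1"}
        assert set(swapped.columns) == {"good", "mid", "bad", "avg"}

    def test_missing_cells_reported(self):
        metrics = pd.DataFrame.from_records(
            [dict(model="a", subset="F0", target="t", fold=0, measure="precision",
                  value=0.5, task="classification"),
             dict(model="b", subset="F0", target="t", fold=0, measure="recall",
                  value=0.5, task="classification")]
        )
        with pytest.raises(ValueError, match="missing metric cells"):
            rank_alternatives(metrics, "methods_per_subset", "t", "classification")


class TestAggregateRanks:
    def _table(self, ranks):
        return pd.DataFrame({"F0": ranks}, index=[f"M{i}" for i in range(len(ranks))])

    def test_single_table_is_fixed_point(self):
        t = self._table([1.0, 2.0, 3.0])
        pd.testing.assert_frame_equal(aggregate_ranks([t]), t)

    def test_hand_arithmetic(self):
        out = aggregate_ranks([self._table([1.0, 2.0, 3.0]), self._table([2.0, 1.0, 3.0])])
        assert list(out["F0"]) == [1.5, 1.5, 3.0]

    def test_target_order_symmetry(self, rng):
        tables = [self._table(list(rng.permutation([1.0, 2.0, 3.0, 4.0]))) for _ in range(3)]
        a = aggregate_ranks(tables)
        b = aggregate_ranks(tables[::-1])
        pd.testing.assert_frame_equal(a, b)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            aggregate_ranks([self._table([1.0, 2.0]), self._table([1.0, 2.0, 3.0])])
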