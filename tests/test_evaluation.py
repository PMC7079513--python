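"""Kaplan-Meier, log-rank and the directed-graph concordance index."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from histosurv.evaluation import (
    concordance_index,
    km_estimate,
    logrank_test,
    partition_by_threshold,
)


def logrank_oracle(ta, da, tb, db):
    """Direct observed-minus-expected summation over event times."""
    times = np.concatenate([ta, tb])
    deltas = np.concatenate([da, db])
    grp = np.concatenate([np.zeros(len(ta)), np.ones(len(tb))])
    O_E, V = 0.0, 0.0
    for t in np.unique(times[deltas == 1]):
        at_risk = times >= t
        n, n1 = at_risk.sum(), (at_risk & (grp == 0)).sum()
        d = ((times == t) & (deltas == 1)).sum()
        d1 = ((times == t) & (deltas == 1) & (grp == 0)).sum()
        O_E += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return O_E**2 / V


class TestKaplanMeier:
    def test_all_censored_flat_at_one(self):
        km = km_estimate([2.0, 3.0, 5.0], [0, 0, 0])
        assert len(km.event_times) == 0
        assert km.survival_at(4.0) == 1.0

    def test_all_events_product_limit(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert np.allclose(km.survival_probabilities, [2 / 3, 1 / 3, 0.0])
        assert np.array_equal(km.at_risk, [3, 2, 1])

    def test_censoring_shrinks_risk_set(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        assert km.survival_at(1.0) == pytest.approx(2 / 3)
        assert km.survival_at(3.0) == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, 40)
        km = km_estimate(times, np.ones(40, int))
        for t in np.quantile(times, [0.2, 0.5, 0.8]):
            assert km.survival_at(t) == pytest.approx((times > t).mean())

    def test_at_risk_table(self):
        km = km_estimate([1.0, 2.0, 3.0, 4.0], [1, 0, 1, 1])
        assert np.array_equal(km.at_risk_table([0.0, 2.5, 5.0]), [4, 2, 0])


class TestLogRank:
    def test_identical_groups_null(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        d = np.array([1, 0, 1, 1, 0])
        res = logrank_test(t, d, t.copy(), d.copy())
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(1)
        ta, tb = rng.exponential(5, 12), rng.exponential(10, 12)
        da = np.ones(12, int)
        r1 = logrank_test(ta, da, tb, da)
        r2 = logrank_test(tb, da, ta, da)
        assert r1.chi_square == pytest.approx(r2.chi_square)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_matches_direct_summation_oracle(self):
        ta = np.array([2.0, 4.0, 5.0, 7.0, 9.0])
        da = np.array([1, 1, 0, 1, 1])
        tb = np.array([1.0, 3.0, 6.0, 8.0, 10.0])
        db = np.array([1, 0, 1, 1, 0])
        res = logrank_test(ta, da, tb, db)
        assert res.chi_square == pytest.approx(
            logrank_oracle(ta, da, tb, db), abs=1e-10)

    def test_p_value_from_chi2_upper_tail(self):
        from scipy.stats import chi2

        ta = np.array([1.0, 2.0, 3.0])
        tb = np.array([10.0, 11.0, 12.0])
        ones = np.array([1, 1, 1])
        res = logrank_test(ta, ones, tb, ones)
        assert res.p_value == pytest.approx(chi2.sf(res.chi_square, 1))
        assert 0 < res.p_value <= 1

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0], [0], [2.0], [0])


class TestConcordance:
    def test_perfect_anti_ordering_is_one(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        res = concordance_index(times, np.ones(4, int), -times)
        assert res.c_index == 1.0
        assert res.comparable_pairs == 6

    def test_enumerated_three_patient_example(self):
        res = concordance_index([1.0, 2.0, 3.0], [1, 1, 1], [3.0, 1.0, 2.0])
        assert res.c_index == pytest.approx(2 / 3)
        assert res.comparable_pairs == 3

    def test_censored_nodes_emit_no_edges(self):
        # patient 0 censored at t=1: pairs (0,1),(0,2) are not comparable
        res = concordance_index([1.0, 2.0, 3.0], [0, 1, 1], [9.0, 2.0, 1.0])
        assert res.comparable_pairs == 1
        assert res.c_index == 1.0

    def test_tied_risks_count_half(self):
        res = concordance_index([1.0, 2.0], [1, 1], [0.5, 0.5])
        assert res.c_index == 0.5

    def test_complement_under_risk_negation(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(5, 30)
        deltas = (rng.random(30) < 0.7).astype(int)
        risks = rng.random(30)
        a = concordance_index(times, deltas, risks).c_index
        b = concordance_index(times, deltas, -risks).c_index
        assert a + b == pytest.approx(1.0)

    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        times = rng.exponential(5, 15)
        deltas = (rng.random(15) < 0.7).astype(int)
        risks = rng.standard_normal(15)
        if deltas.sum() == 0:
            return
        a = concordance_index(times, deltas, risks).c_index
        b = concordance_index(times, deltas, np.exp(2 * risks)).c_index
        assert a == pytest.approx(b)

    def test_agrees_with_lifelines(self, small_cohort):
        from lifelines.utils import concordance_index as ll_cindex

        F, times, deltas = small_cohort
        risks = F[:, 0] - F[:, 1]
        mine = concordance_index(times, deltas, risks).c_index
        # lifelines scores "predicted survival time" = negative risk
        assert mine == pytest.approx(ll_cindex(times, -risks, deltas))

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            concordance_index([5.0, 5.0], [1, 1], [0.1, 0.2])


class TestPartition:
    def test_boundary_goes_low(self):
        low, high = partition_by_threshold(np.array([0.5, 0.7]), 0.5)
        assert low.tolist() == [True, False]
        assert high.tolist() == [False, True]

    def test_degenerate_split_detectable(self):
        low, high = partition_by_threshold(np.array([0.1, 0.2]), 0.5)
        assert not high.any()

    def test_singleton_groups(self):
        low, high = partition_by_threshold(np.array([0.2, 0.7]))
        assert low.sum() == 1 and high.sum() == 1

    def test_out_of_range_risks_rejected(self):
        with pytest.raises(ValueError):
            partition_by_threshold(np.array([1.2]))
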