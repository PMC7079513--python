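"""Risk labelling, Cox partial likelihood, elastic net, selection, stumps."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from histosurv import survival as sv
from histosurv.survival import DAYS_PER_YEAR

YEARS = DAYS_PER_YEAR


def brute_force_partial_loglik(F, times, deltas, beta):
    """Direct summation over events and risk sets (no ties assumed)."""
    eta = np.asarray(F, float) @ beta
    out = 0.0
    for i in range(len(times)):
        if deltas[i] == 1:
            risk = [j for j in range(len(times)) if times[j] >= times[i]]
            out += eta[i] - np.log(np.exp(eta[risk]).sum())
    return out


def penalized_oracle(F, times, deltas, alpha, lam):
    """Generic optimizer for the elastic-net Cox objective via the
    positive/negative split (smooth, box-constrained)."""
    M = F.shape[1]

    def negobj(bp):
        b = bp[:M] - bp[M:]
        pen = lam * (alpha * bp.sum() + 0.5 * (1 - alpha) * (b**2).sum())
        return -sv.cox_partial_loglik(F, times, deltas, b) + pen

    res = minimize(negobj, np.zeros(2 * M), bounds=[(0, None)] * 2 * M,
                   method="L-BFGS-B",
                   options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12})
    return res.x[:M] - res.x[M:]


class TestRiskLabels:
    @staticmethod
    def _table(death, followup):
        return pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(len(death))],
            "days_to_death": death,
            "days_to_last_followup": followup,
        })

    def test_three_year_horizon_rules(self):
        t = self._table(
            death=[2 * YEARS, np.nan, np.nan, 4 * YEARS],
            followup=[np.nan, 4 * YEARS, 2 * YEARS, np.nan],
        )
        labels = sv.label_risk_groups(t)
        assert list(labels) == ["high", "low", "excluded", "low"]

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            sv.label_risk_groups(self._table([-1.0], [np.nan]))


class TestRiskClassifier:
    def test_separable_toy_fits_perfectly(self):
        F = np.array([[-1.0], [-1.2], [1.0], [1.1]])
        labels = np.array(["low", "low", "high", "high"])
        clf = sv.fit_risk_classifier(F, labels)
        pred = clf.predict_risk(F) > 0.5
        assert np.array_equal(pred, [False, False, True, True])

    def test_symmetric_classes_midpoint_is_half(self):
        F = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        labels = np.array([0, 0, 1, 1])
        clf = sv.fit_risk_classifier(F, labels)
        assert clf.predict_risk(np.array([[0.0]]))[0] == pytest.approx(
            0.5, abs=1e-6)

    def test_outputs_bounded(self, small_cohort):
        F, times, deltas = small_cohort
        labels = (times < np.median(times)).astype(int)
        clf = sv.fit_risk_classifier(F, labels)
        r = clf.predict_risk(F * 100)
        assert (r >= 0).all() and (r <= 1).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sv.fit_risk_classifier(np.zeros((3, 2)), np.array([1, 1, 1]))


class TestPartialLoglik:
    def test_two_patients_beta_zero(self):
        val = sv.cox_partial_loglik(np.zeros((2, 1)), [1.0, 2.0], [1, 0],
                                    np.zeros(1))
        assert val == pytest.approx(np.log(0.5))

    def test_beta_zero_equals_minus_log_risk_set_sizes(self):
        rng = np.random.default_rng(0)
        times = rng.permutation(10).astype(float) + 1
        deltas = (rng.random(10) < 0.6).astype(int)
        expected = -sum(np.log((times >= times[i]).sum())
                        for i in range(10) if deltas[i])
        got = sv.cox_partial_loglik(np.zeros((10, 2)), times, deltas,
                                    np.zeros(2))
        assert got == pytest.approx(expected)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        F = rng.standard_normal((5, 1))
        times = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        deltas = np.array([1, 1, 0, 1, 1])
        beta = np.array([0.7])
        assert sv.cox_partial_loglik(F, times, deltas, beta) == pytest.approx(
            brute_force_partial_loglik(F, times, deltas, beta), abs=1e-12)

    def test_invariant_to_column_shift(self, small_cohort):
        F, times, deltas = small_cohort
        beta = np.full(F.shape[1], 0.3)
        a = sv.cox_partial_loglik(F, times, deltas, beta)
        b = sv.cox_partial_loglik(F + 5.0, times, deltas, beta)
        assert a == pytest.approx(b, rel=1e-9)


@pytest.fixture(scope="module")
def tiny():
    rng = np.random.default_rng(42)
    F = rng.standard_normal((20, 3))
    beta = np.array([1.0, -1.0, 0.0])
    times = rng.exponential(1 / np.exp(F @ beta))
    deltas = (rng.random(20) < 0.8).astype(float)
    return F, times, deltas


class TestElasticNet:
    @pytest.mark.parametrize("alpha", [0.0, 0.2, 1.0])
    def test_matches_generic_optimizer(self, tiny, alpha):
        F, times, deltas = tiny
        lam = 0.2 * sv.cox_lambda_max(F, times, deltas, max(alpha, 0.2))
        fit = sv.fit_cox_elastic_net(F, times, deltas, alpha=alpha, lam=lam,
                                     tol=1e-9)
        oracle = penalized_oracle(F, times, deltas, alpha, lam)
        assert np.abs(fit.beta - oracle).max() < 1e-4

    def test_zero_solution_at_lambda_max(self, tiny):
        F, times, deltas = tiny
        lmax = sv.cox_lambda_max(F, times, deltas, 0.2)
        fit = sv.fit_cox_elastic_net(F, times, deltas, alpha=0.2, lam=lmax)
        assert np.array_equal(fit.beta, np.zeros(3))

    def test_path_support_grows_as_lambda_shrinks(self, tiny):
        F, times, deltas = tiny
        fits = sv.cox_path(F, times, deltas, alpha=1.0, n_lambdas=10)
        sizes = [len(f.support) for f in fits]
        assert sizes[0] == 0
        assert sizes == sorted(sizes)

    def test_agrees_with_sksurv_on_lasso_path(self, tiny):
        """Independent cross-check against scikit-survival's coxnet."""
        sksurv = pytest.importorskip("sksurv.linear_model")
        F, times, deltas = tiny
        n = len(times)
        lam = 0.3 * sv.cox_lambda_max(F, times, deltas, 1.0)
        y = np.array([(bool(d), t) for d, t in zip(deltas, times)],
                     dtype=[("event", "?"), ("time", "<f8")])
        # sksurv normalizes the likelihood by n; rescale lambda to match
        m = sksurv.CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=[lam / n], normalize=False,
            tol=1e-9, fit_baseline_model=False)
        m.fit(F, y)
        mine = sv.fit_cox_elastic_net(F, times, deltas, alpha=1.0, lam=lam,
                                      tol=1e-9)
        assert np.abs(m.coef_[:, 0] - mine.beta).max() < 1e-3

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            sv.fit_cox_elastic_net(np.zeros((4, 2)), [1, 2, 3, 4],
                                   [0, 0, 0, 0])


class TestSelectionFrequency:
    def test_top_k_returns_k_ids_with_tie_rule(self):
        prof = sv.SelectionProfile(
            frequency=np.array([5, 9, 9, 1, 0]), repeats=10, folds=5,
            alpha=0.2)
        assert np.array_equal(prof.top_k(3), [1, 2, 0])
        assert len(prof.top_k(30 if False else 5)) == 5

    def test_frequencies_bounded_by_repeats(self, small_cohort):
        F, times, deltas = small_cohort
        prof = sv.selection_frequency(F[:60], times[:60], deltas[:60],
                                      repeats=3, folds=3, seed=0,
                                      n_lambdas=10)
        assert (prof.frequency <= 3).all()
        assert prof.repeats == 3

    def test_strong_features_dominate(self, small_cohort):
        F, times, deltas = small_cohort
        prof = sv.selection_frequency(F, times, deltas, repeats=5, folds=5,
                                      seed=1, n_lambdas=15)
        top = set(prof.top_k(4).tolist())
        assert {0, 1} <= top  # the two truly prognostic features


class TestStump:
    def test_separable_midpoint(self):
        x = np.array([1.0, 2.0, 5.0, 6.0])
        y = np.array([0, 0, 1, 1])
        stump = sv.stump_classifier(x, y)
        assert stump.threshold == 3.5
        assert stump.direction == "greater"
        assert stump.accuracy == 1.0

    def test_constant_feature_majority(self):
        x = np.ones(5)
        y = np.array([1, 1, 1, 0, 0])
        assert sv.stump_classifier(x, y).accuracy == pytest.approx(0.6)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.random(15)
            y = rng.integers(0, 2, 15)
            if len(np.unique(y)) < 2:
                continue
            stump = sv.stump_classifier(x, y)
            best = max(
                ((pred.astype(int) == y).mean())
                for thr in np.concatenate([x - 1e-9, x + 1e-9])
                for pred in ((x > thr), (x <= thr))
            )
            assert stump.accuracy == pytest.approx(best)
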