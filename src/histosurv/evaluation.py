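"""Survival-model evaluation: Kaplan-Meier curves, the two-group log-rank
test, and the directed-graph concordance index.

The c-index is defined over a directed comparison graph G = (V, E): an
edge e_ij exists when patient i is uncensored and t_i < t_j (edges only
originate from uncensored patients; t_j may be a censoring time). A pair
is concordant when the predicted risks satisfy r_i > r_j; tied risks count
one half. c = 0.5 is chance level, 1 is perfect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "KMCurve",
    "LogRankResult",
    "ConcordanceResult",
    "km_estimate",
    "logrank_test",
    "concordance_index",
    "partition_by_threshold",
]


@dataclass
class KMCurve:
    """Product-limit survival estimate with its at-risk bookkeeping."""

    event_times: np.ndarray  # distinct times with >= 1 observed event
    survival_probabilities: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # risk-set size at each event time
    censoring_times: np.ndarray  # times of censored observations
    _fitter: KaplanMeierFitter = field(repr=False, default=None)

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous step function with S(0) = 1."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival_probabilities[idx - 1])

    def at_risk_table(self, ticks: np.ndarray) -> np.ndarray:
        """Number of patients still at risk at the start of each tick, the
        row of counts printed beneath a published KM plot."""
        return np.array([int((self._all_times >= t).sum()) for t in ticks])


def km_estimate(times: np.ndarray, deltas: np.ndarray) -> KMCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod (1 - d_i/n_i)."""
    times = np.asarray(times, float)
    deltas = np.asarray(deltas, int)
    if len(times) == 0:
        raise ValueError("empty sample")
    kmf = KaplanMeierFitter().fit(times, event_observed=deltas)
    table = kmf.event_table
    observed = table["observed"].to_numpy()
    mask = observed > 0
    event_times = table.index.to_numpy(dtype=float)[mask]
    surv = np.array([kmf.predict(t) for t in event_times], dtype=float)
    curve = KMCurve(
        event_times=event_times,
        survival_probabilities=surv,
        at_risk=table["at_risk"].to_numpy()[mask].astype(int),
        censoring_times=times[deltas == 0],
        _fitter=kmf,
    )
    curve._all_times = times
    return curve


@dataclass
class LogRankResult:
    chi_square: float
    degrees_of_freedom: int
    p_value: float

    @property
    def significant(self) -> bool:
        """Conventional 0.05 significance threshold."""
        return self.p_value < 0.05


def logrank_test(
    times_a: np.ndarray, deltas_a: np.ndarray,
    times_b: np.ndarray, deltas_b: np.ndarray,
) -> LogRankResult:
    """Two-group log-rank test (pooled-hypergeometric variance, 1 df)."""
    times_a = np.asarray(times_a, float)
    times_b = np.asarray(times_b, float)
    deltas_a = np.asarray(deltas_a, int)
    deltas_b = np.asarray(deltas_b, int)
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValueError("both groups must be nonempty")
    if deltas_a.sum() + deltas_b.sum() == 0:
        raise ValueError("no events in either group")
    res = _ll_logrank(times_a, times_b, event_observed_A=deltas_a,
                      event_observed_B=deltas_b)
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    return LogRankResult(chi_square=max(chi2, 0.0), degrees_of_freedom=1,
                         p_value=min(max(p, np.nextafter(0, 1)), 1.0))


@dataclass
class ConcordanceResult:
    c_index: float
    comparable_pairs: int


def concordance_index(
    times: np.ndarray, deltas: np.ndarray, risks: np.ndarray
) -> ConcordanceResult:
    """Directed-graph concordance index.

    Edges run from each uncensored patient i to every j with t_i < t_j;
    the pair is concordant when r_i > r_j, and tied risks contribute 1/2.
    Raises when the graph has no edges (nothing is comparable).
    """
    times = np.asarray(times, float)
    deltas = np.asarray(deltas, int)
    risks = np.asarray(risks, float)
    edges = (deltas[:, None] == 1) & (times[:, None] < times[None, :])
    n_edges = int(edges.sum())
    if n_edges == 0:
        raise ValueError("no comparable pairs")
    concordant = int((edges & (risks[:, None] > risks[None, :])).sum())
    tied = int((edges & (risks[:, None] == risks[None, :])).sum())
    return ConcordanceResult(
        c_index=(concordant + 0.5 * tied) / n_edges,
        comparable_pairs=n_edges,
    )


def partition_by_threshold(
    risks: np.ndarray, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Split patients into (low, high) boolean masks at a risk threshold.

    The boundary r == threshold goes to the low group. A warning-worthy
    degenerate split (one empty group) is left to the caller to detect via
    the masks; downstream log-rank then errors cleanly.
    """
    risks = np.asarray(risks, float)
    if risks.size and (risks.min() < 0 or risks.max() > 1):
        raise ValueError("risk scores must lie in [0, 1]")
    high = risks > threshold
    return ~high, high
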