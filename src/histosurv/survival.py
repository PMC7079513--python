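"""Survival modelling: risk-group labels, logistic risk classifier,
penalized Cox proportional hazards, stability feature selection, stumps.

The Cox model assumes hazard h_i(t) = h0(t) * exp(f_i' beta) and estimates
beta by maximizing the Breslow partial log-likelihood

    L(beta) = sum_{i: delta_i = 1} [ f_i' beta - log sum_{j in R_i} exp(f_j' beta) ],

R_i = {j : y_j >= y_i}. For high-dimensional patient vectors the
elastic-net penalized objective

    L_net(beta) = L(beta) - lambda * (alpha * ||beta||_1
                                      + 1/2 * (1 - alpha) * ||beta||_2^2)

is maximized by iteratively reweighted least squares with cyclical
coordinate descent and soft-thresholding, the glmnet strategy. No internal
feature standardization or 1/n scaling is applied: the objective is
exactly the one above, so lambda is on the scale of the summed
log-likelihood.

Feature selection repeats cross-validated lambda choice + a full refit
many times over reshuffled folds and counts how often each feature comes
out with a nonzero coefficient; stably selected features are the most
frequent ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RiskClassifier",
    "CoxFit",
    "SelectionProfile",
    "Stump",
    "DAYS_PER_YEAR",
    "label_risk_groups",
    "fit_risk_classifier",
    "cox_partial_loglik",
    "cox_lambda_max",
    "fit_cox_elastic_net",
    "cox_path",
    "cv_choose_lambda",
    "selection_frequency",
    "stump_classifier",
]

DAYS_PER_YEAR = 365.25
DEFAULT_ALPHA = 0.2


# ---------------------------------------------------------------------------
# risk-group labelling
# ---------------------------------------------------------------------------


def label_risk_groups(
    clinical: pd.DataFrame,
    T1: float = 3 * DAYS_PER_YEAR,
    T2: float = 3 * DAYS_PER_YEAR,
) -> pd.Series:
    """Assign {high, low, excluded} risk-group labels from a clinical table.

    Expects columns ``patient_id``, ``days_to_death`` (NaN when unknown)
    and ``days_to_last_followup``. A patient is *high* risk when the known
    days-to-death is below T1; *low* risk when either days-to-death or
    days-to-last-followup exceeds T2; otherwise *excluded* (in particular
    censored patients whose follow-up ends before T1, about whom the
    horizon says nothing).
    """
    death = clinical["days_to_death"].to_numpy(dtype=float)
    followup = clinical["days_to_last_followup"].to_numpy(dtype=float)
    if np.nanmin(np.concatenate([death, followup])) < 0:
        raise ValueError("negative survival times")
    labels = []
    for d, f in zip(death, followup):
        best = np.nanmax([d, f])
        if np.isfinite(d) and d < T1:
            labels.append("high")
        elif np.isfinite(best) and best > T2:
            labels.append("low")
        else:
            labels.append("excluded")
    return pd.Series(labels, index=clinical["patient_id"].values, name="risk_group")


# ---------------------------------------------------------------------------
# binary risk classifier
# ---------------------------------------------------------------------------


@dataclass
class RiskClassifier:
    """Logistic model scoring patients in [0, 1]; larger = higher risk."""

    weights: np.ndarray
    intercept: float
    classes: tuple

    def predict_risk(self, F: np.ndarray) -> np.ndarray:
        z = np.asarray(F, float) @ self.weights + self.intercept
        return 1.0 / (1.0 + np.exp(-z))


def fit_risk_classifier(
    F: np.ndarray, labels, C: float = 1.0, seed: int = 0
) -> RiskClassifier:
    """l2-regularized logistic regression of high-vs-low risk labels.

    ``labels`` may be strings ('low'/'high') or binary; the positive class
    is 'high' (or the larger value). The regularization is deliberately
    mild (C = 1) because the patient vectors are short and the cohorts
    small.
    """
    from sklearn.linear_model import LogisticRegression

    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("need exactly two classes present")
    if set(uniq) == {"low", "high"}:
        y = (labels == "high").astype(int)
        classes = ("low", "high")
    else:
        y = (labels == uniq[-1]).astype(int)
        classes = tuple(uniq)
    lr = LogisticRegression(C=C, max_iter=5000, random_state=seed)
    lr.fit(np.asarray(F, float), y)
    return RiskClassifier(
        weights=lr.coef_[0].copy(), intercept=float(lr.intercept_[0]),
        classes=classes,
    )


# ---------------------------------------------------------------------------
# Cox partial likelihood and its IRLS ingredients
# ---------------------------------------------------------------------------


def _breslow_terms(eta: np.ndarray, times: np.ndarray, deltas: np.ndarray):
    """Per-distinct-event-time Breslow quantities.

    Returns (event_times u, event counts d_u, log denominators logD_u,
    cumhaz index) where cumhaz index maps each patient to the number of
    distinct event times <= its observed time.
    """
    order = np.argsort(times, kind="stable")
    ts, es, ds = times[order], eta[order], deltas[order]
    m = es.max() if len(es) else 0.0
    ex = np.exp(es - m)
    suffix = np.cumsum(ex[::-1])[::-1]
    uts, first = np.unique(ts, return_index=True)
    d_u = np.array([ds[ts == u].sum() for u in uts], dtype=float)
    D_u = suffix[first]
    keep = d_u > 0
    u, d_u, D_u = uts[keep], d_u[keep], D_u[keep]
    logD = m + np.log(D_u)
    return order, u, d_u, D_u, logD, m


def cox_partial_loglik(
    F: np.ndarray, times: np.ndarray, deltas: np.ndarray, beta: np.ndarray
) -> float:
    """Breslow partial log-likelihood at beta (log of Eq. L)."""
    F = np.atleast_2d(np.asarray(F, float))
    times = np.asarray(times, float)
    deltas = np.asarray(deltas)
    beta = np.asarray(beta, float)
    eta = F @ beta
    _, u, d_u, _, logD, _ = _breslow_terms(eta, times, deltas)
    s = float(eta[deltas == 1].sum())
    return s - float((d_u * logD).sum())


def _irls_weights(eta: np.ndarray, times: np.ndarray, deltas: np.ndarray):
    """Gradient g and diagonal Hessian approximation w of the partial
    log-likelihood with respect to the linear predictor eta (Breslow)."""
    order, u, d_u, D_u, _, m = _breslow_terms(eta, times, deltas)
    ratio1 = np.concatenate([[0.0], np.cumsum(d_u / D_u)])
    ratio2 = np.concatenate([[0.0], np.cumsum(d_u / D_u**2)])
    idx = np.searchsorted(u, times, side="right")
    ex = np.exp(eta - m)
    cumhaz = ex * ratio1[idx]
    g = deltas - cumhaz
    w = cumhaz - ex**2 * ratio2[idx]
    return g, np.maximum(w, 1e-10)


def cox_lambda_max(
    F: np.ndarray, times: np.ndarray, deltas: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Smallest lambda at which the all-zero solution is optimal (alpha>0)."""
    F = np.asarray(F, float)
    g, _ = _irls_weights(np.zeros(len(F)), np.asarray(times, float),
                         np.asarray(deltas, float))
    score = np.abs(F.T @ g).max()
    return float(score / max(alpha, 1e-3))


@dataclass
class CoxFit:
    beta: np.ndarray
    alpha: float
    lam: float
    converged: bool
    n_iterations: int
    loglik: float | None = None

    def predict_risk(self, F: np.ndarray) -> np.ndarray:
        """Linear predictor f' beta (relative log-hazard)."""
        return np.asarray(F, float) @ self.beta

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.beta != 0)


def _soft(x: float, t: float) -> float:
    return np.sign(x) * max(abs(x) - t, 0.0)


def fit_cox_elastic_net(
    F: np.ndarray,
    times: np.ndarray,
    deltas: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    lam: float = 0.0,
    beta_init: np.ndarray | None = None,
    tol: float = 1e-7,
    max_outer: int = 100,
    max_inner: int = 200,
    warn: bool = True,
) -> CoxFit:
    """Maximize the elastic-net-penalized partial likelihood.

    Iteratively reweighted least squares wrapped around cyclical coordinate
    descent with soft-thresholding; convergence when the largest
    coefficient change across an outer iteration drops below ``tol``. At
    lam >= the data-dependent bound :func:`cox_lambda_max` (alpha > 0) the
    zero vector is returned exactly.
    """
    F = np.atleast_2d(np.asarray(F, float))
    times = np.asarray(times, float)
    deltas = np.asarray(deltas, float)
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if deltas.sum() < 1:
        raise ValueError("need at least one event")
    P, M = F.shape
    beta = np.zeros(M) if beta_init is None else np.asarray(beta_init, float).copy()

    l1, l2 = lam * alpha, lam * (1.0 - alpha)
    n_outer = 0
    converged = False
    for n_outer in range(1, max_outer + 1):
        eta = F @ beta
        g, w = _irls_weights(eta, times, deltas)
        z = eta + g / w
        r = z - eta  # working residual
        beta_old_outer = beta.copy()
        wF2 = w @ (F**2)  # sum_i w_i f_im^2 per feature
        for _ in range(max_inner):
            max_delta = 0.0
            for mth in range(M):
                bm = beta[mth]
                rho = float(w @ (r * F[:, mth])) + wF2[mth] * bm
                new = _soft(rho, l1) / (wF2[mth] + l2)
                if new != bm:
                    r = r + F[:, mth] * (bm - new)
                    beta[mth] = new
                    max_delta = max(max_delta, abs(new - bm))
            if max_delta < tol:
                break
        if np.abs(beta - beta_old_outer).max() < tol:
            converged = True
            break
    if not converged and warn:
        warnings.warn(
            f"coordinate descent did not converge in {max_outer} outer iterations"
        )
    beta[np.abs(beta) < 1e-12] = 0.0
    return CoxFit(
        beta=beta, alpha=alpha, lam=lam, converged=converged,
        n_iterations=n_outer,
        loglik=cox_partial_loglik(F, times, deltas, beta),
    )


def cox_path(
    F: np.ndarray,
    times: np.ndarray,
    deltas: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    n_lambdas: int = 50,
    lambda_min_ratio: float = 0.01,
    lambdas: np.ndarray | None = None,
    **fit_kwargs,
) -> list[CoxFit]:
    """Warm-started regularization path from lambda_max downward."""
    if lambdas is None:
        lmax = cox_lambda_max(F, times, deltas, alpha)
        lambdas = np.geomspace(lmax, lambda_min_ratio * lmax, n_lambdas)
    fits: list[CoxFit] = []
    beta = None
    for lam in lambdas:
        fit = fit_cox_elastic_net(
            F, times, deltas, alpha=alpha, lam=float(lam), beta_init=beta,
            **fit_kwargs,
        )
        beta = fit.beta
        fits.append(fit)
    return fits


def cv_choose_lambda(
    F: np.ndarray,
    times: np.ndarray,
    deltas: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 50,
    lambda_min_ratio: float = 0.01,
    rule: str = "min",
) -> float:
    """Pick lambda on a shared log grid by held-out partial likelihood.

    ``rule='min'`` returns the lambda maximizing the mean held-out partial
    log-likelihood across folds; ``rule='1se'`` returns the largest lambda
    whose mean score is within one standard error of that maximum (the
    parsimony rule familiar from glmnet's cross-validation reporting).
    """
    F = np.asarray(F, float)
    times = np.asarray(times, float)
    deltas = np.asarray(deltas, float)
    P = len(times)
    n_events = int(deltas.sum())
    if n_events < folds:
        warnings.warn(f"only {n_events} events; reducing folds to {max(n_events, 2)}")
        folds = max(n_events, 2)
    lmax = cox_lambda_max(F, times, deltas, alpha)
    lambdas = np.geomspace(lmax, lambda_min_ratio * lmax, n_lambdas)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(P)
    fold_of = np.empty(P, dtype=int)
    fold_of[perm] = np.arange(P) % folds

    scores = np.full((folds, n_lambdas), np.nan)
    for fold in range(folds):
        test = fold_of == fold
        train = ~test
        if deltas[test].sum() < 1 or deltas[train].sum() < 1:
            continue
        fits = cox_path(
            F[train], times[train], deltas[train], alpha=alpha, lambdas=lambdas,
            tol=1e-5, max_outer=25, warn=False,
        )
        for li, fit in enumerate(fits):
            scores[fold, li] = cox_partial_loglik(
                F[test], times[test], deltas[test], fit.beta
            )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean = np.nanmean(scores, axis=0)
    if np.all(np.isnan(mean)):
        raise ValueError("cross-validation failed: no fold had events")
    best = int(np.nanargmax(mean))
    if rule == "min":
        return float(lambdas[best])
    if rule != "1se":
        raise ValueError("rule must be 'min' or '1se'")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        se = np.nanstd(scores, axis=0, ddof=1) / np.sqrt(folds)
    ok = np.where(mean >= mean[best] - se[best])[0]
    return float(lambdas[ok[0]])  # lambdas descend, so ok[0] is the largest


# ---------------------------------------------------------------------------
# stability feature selection
# ---------------------------------------------------------------------------


@dataclass
class SelectionProfile:
    frequency: np.ndarray  # selections per feature, one increment per repeat
    repeats: int
    folds: int
    alpha: float
    lambdas_chosen: list = field(default_factory=list)

    def top_k(self, k: int = 30) -> np.ndarray:
        """Indices of the k most frequently selected features (ties ->
        lower feature index)."""
        order = np.lexsort((np.arange(len(self.frequency)), -self.frequency))
        return order[:k]


def selection_frequency(
    F: np.ndarray,
    times: np.ndarray,
    deltas: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    repeats: int = 100,
    folds: int = 10,
    seed: int = 0,
    rule: str = "1se",
    **cv_kwargs,
) -> SelectionProfile:
    """Selection-frequency protocol for stable feature selection.

    Each repeat reshuffles the cross-validation folds, chooses lambda by
    held-out partial likelihood (the parsimonious one-standard-error rule
    by default, so the selection frequencies stay informative rather than
    saturating), refits the elastic net on the full data at that lambda,
    and increments the frequency of every feature with a nonzero
    coefficient (one increment per repeat).
    """
    F = np.asarray(F, float)
    if len(F) < folds:
        raise ValueError("need at least `folds` patients")
    freq = np.zeros(F.shape[1], dtype=int)
    profile = SelectionProfile(frequency=freq, repeats=repeats, folds=folds,
                               alpha=alpha)
    for rep in range(repeats):
        lam = cv_choose_lambda(
            F, times, deltas, alpha=alpha, folds=folds, seed=seed + rep,
            rule=rule, **cv_kwargs,
        )
        fit = fit_cox_elastic_net(F, times, deltas, alpha=alpha, lam=lam,
                                  tol=1e-6, max_outer=50, warn=False)
        freq[fit.support] += 1
        profile.lambdas_chosen.append(lam)
    return profile


# ---------------------------------------------------------------------------
# stump classifier
# ---------------------------------------------------------------------------


@dataclass
class Stump:
    threshold: float
    direction: str  # 'greater': x > threshold -> high risk
    accuracy: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        return (x > self.threshold) if self.direction == "greater" else (
            x <= self.threshold
        )


def stump_classifier(x: np.ndarray, labels) -> Stump:
    """Best single-threshold rule by exhaustive midpoint search.

    ``labels``: 1/'high' = high risk. Candidate thresholds are the
    midpoints of consecutive sorted unique values, plus sentinels outside
    the data range (so a constant feature falls back to the majority
    class). Ties in accuracy go to the smaller threshold, then to the
    'greater' direction.
    """
    x = np.asarray(x, float)
    labels = np.asarray(labels)
    y = (labels == "high").astype(int) if labels.dtype.kind in "UO" else (
        labels.astype(int)
    )
    if len(np.unique(y)) != 2:
        raise ValueError("need both classes present")
    uniq = np.unique(x)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    best = None
    n = len(y)
    for thr in candidates:
        for direction in ("greater", "less"):
            pred = (x > thr) if direction == "greater" else (x <= thr)
            acc = float((pred.astype(int) == y).sum()) / n
            key = (-acc, thr, 0 if direction == "greater" else 1)
            if best is None or key < best[0]:
                best = (key, Stump(float(thr), direction, acc))
    return best[1]
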