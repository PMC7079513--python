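"""Aggregating cellular descriptors into patient-level vectors.

A codebook B (D x M) of prototype descriptors is learned by k-means over
the pooled cells of the training patients. Each cell descriptor x is then
converted to an M-dimensional code c:

* hard vector quantization (BoW): c is the one-hot indicator of the
  nearest codeword;
* locality-constrained linear coding (LLC): restricting to the k nearest
  codewords B_k, c solves  min ||x - B_k c||^2  s.t.  1'c = 1  in closed
  form (center the neighbors at x, solve the k x k Gram system, normalize
  the solution to sum one) and is scattered back into an M-vector.

Codes are pooled over a patient's cells by summation or elementwise max
and l2-normalized, f = f / ||f||_2. Two baselines are included: the
aggregate statistic [mean; median; std] of each descriptor dimension
(length 3D) and cellular voting (the mean of per-cell risk scores).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "Codebook",
    "CodeMatrix",
    "PatientVector",
    "learn_codebook",
    "encode_bow",
    "encode_llc",
    "pool",
    "aggregate_statistic",
    "cellular_voting",
]

DEFAULT_CODEBOOK_SIZE = 256
DEFAULT_LLC_NEIGHBORS = 5


@dataclass
class Codebook:
    B: np.ndarray  # (D, M)
    inertia: float
    seed: int

    @property
    def n_codewords(self) -> int:
        return self.B.shape[1]


@dataclass
class CodeMatrix:
    C: np.ndarray  # (M, N)
    method: str
    k: int | None = None  # LLC support size


@dataclass
class PatientVector:
    f: np.ndarray
    encoding_name: str
    normalized: bool


def learn_codebook(
    X: np.ndarray, M: int = DEFAULT_CODEBOOK_SIZE, seed: int = 0, n_init: int = 4
) -> Codebook:
    """k-means codebook over descriptor columns; requires at least M cells."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] < M:
        raise ValueError(f"need at least M={M} cells, got {X.shape[1]}")
    km = KMeans(n_clusters=M, n_init=n_init, random_state=seed).fit(X.T)
    return Codebook(B=km.cluster_centers_.T.copy(), inertia=float(km.inertia_),
                    seed=seed)


def _nearest(X: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Index of the nearest codeword per column; ties -> lowest index."""
    d2 = (
        (X**2).sum(axis=0)[:, None]
        - 2 * X.T @ B
        + (B**2).sum(axis=0)[None, :]
    )
    return np.argmin(d2, axis=1)  # argmin takes the first minimum on ties


def encode_bow(X: np.ndarray, B: np.ndarray) -> CodeMatrix:
    """Hard VQ: one-hot code at the nearest codeword (Euclidean)."""
    X, B = np.asarray(X, float), np.asarray(B, float)
    if X.shape[0] != B.shape[0]:
        raise ValueError("descriptor/codebook dimension mismatch")
    M, N = B.shape[1], X.shape[1]
    C = np.zeros((M, N))
    C[_nearest(X, B), np.arange(N)] = 1.0
    return CodeMatrix(C=C, method="bow")


def encode_llc(
    X: np.ndarray, B: np.ndarray, k: int = DEFAULT_LLC_NEIGHBORS
) -> CodeMatrix:
    """Locality-constrained linear coding with k nearest codewords.

    Per descriptor x: gather its k nearest codewords B_k, form centered
    differences Z = B_k - x 1', solve (Z'Z) w = 1 and set c = w / 1'w.
    Near-singular Gram systems (duplicate codewords, exact hits) are
    ridge-stabilized with 1e-8 * trace(G) on the diagonal. Each code sums
    to one exactly by construction.
    """
    X, B = np.asarray(X, float), np.asarray(B, float)
    if X.shape[0] != B.shape[0]:
        raise ValueError("descriptor/codebook dimension mismatch")
    M, N = B.shape[1], X.shape[1]
    if not (1 <= k <= M):
        raise ValueError("k must satisfy 1 <= k <= M")
    d2 = (
        (X**2).sum(axis=0)[:, None]
        - 2 * X.T @ B
        + (B**2).sum(axis=0)[None, :]
    )
    C = np.zeros((M, N))
    ones = np.ones(k)
    for i in range(N):
        nn = np.argsort(d2[i], kind="stable")[:k]
        Z = B[:, nn] - X[:, [i]]
        G = Z.T @ Z
        tr = np.trace(G)
        ridge = 1e-8 * tr if tr > 0 else 1e-12
        try:
            cond = np.linalg.cond(G)
        except np.linalg.LinAlgError:  # pragma: no cover
            cond = np.inf
        if not np.isfinite(cond) or cond > 1e12:
            G = G + ridge * np.eye(k)
        w = np.linalg.solve(G, ones)
        C[nn, i] = w / w.sum()
    return CodeMatrix(C=C, method="llc", k=k)


def pool(C: CodeMatrix | np.ndarray, mode: str = "sum",
         normalize: bool = True) -> PatientVector:
    """Pool cell codes into one patient vector; optional l2 normalization."""
    arr = C.C if isinstance(C, CodeMatrix) else np.asarray(C, float)
    if arr.shape[1] < 1:
        raise ValueError("need at least one cell")
    if mode == "sum":
        f = arr.sum(axis=1)
    elif mode == "max":
        f = arr.max(axis=1)
    else:
        raise ValueError(f"unknown pooling mode {mode!r}")
    if normalize:
        norm = np.linalg.norm(f)
        if norm == 0:
            warnings.warn("l2-normalizing a zero vector; returning zeros")
        else:
            f = f / norm
    name = (C.method if isinstance(C, CodeMatrix) else "code") + f"-{mode}"
    return PatientVector(f=f, encoding_name=name, normalized=normalize)


def aggregate_statistic(X: np.ndarray) -> PatientVector:
    """Baseline: [means; medians; population stds] over cells, length 3D."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 1:
        raise ValueError("need at least one cell")
    f = np.concatenate([X.mean(axis=1), np.median(X, axis=1), X.std(axis=1)])
    return PatientVector(f=f, encoding_name="aggregate-statistic",
                         normalized=False)


def cellular_voting(cell_scores: np.ndarray) -> float:
    """Baseline: patient risk = arithmetic mean of per-cell risk scores."""
    cell_scores = np.asarray(cell_scores, dtype=float)
    if cell_scores.size == 0:
        raise ValueError("empty cell score set")
    return float(cell_scores.mean())
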