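"""Cell-center detection from confidence maps.

The detector is trained as a map regressor: each annotated image is paired
with a target confidence map ``y = v * G`` (the binary center-indicator
image convolved with a Gaussian kernel of standard deviation sigma), and a
fully-convolutional network is fit by minimizing the center-weighted
squared loss

    L(y, o) = 1/2 * sum_ij (y_ij + beta * ybar) * (y_ij - o_ij)^2,

where ``ybar`` is the mean of y and beta (default 0.2) keeps background
pixels from dominating the objective. At inference, cell coordinates are
read off the predicted map by non-maximum suppression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._convnet import Adam, Conv2D, ConvNet, ReLU

__all__ = [
    "DetectionLossConfig",
    "DetectorConfig",
    "DetectorModel",
    "DetectionMetrics",
    "make_target_map",
    "weighted_mse_loss",
    "train_detector",
    "predict_map",
    "nms_peaks",
    "detection_metrics",
]


@dataclass
class DetectionLossConfig:
    beta: float = 0.2  # weight constant of the center-weighted loss
    sigma: float = 3.0  # Gaussian std of the target kernel, pixels

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def make_target_map(
    centers: np.ndarray, shape: tuple[int, int], sigma: float = 3.0
) -> np.ndarray:
    """Build the training target y = v * G.

    ``v`` is 1 at each annotated center, 0 elsewhere; ``G`` is an
    unnormalized Gaussian kernel with peak value 1 and standard deviation
    ``sigma``, truncated at 4 sigma. Overlapping kernels sum, as
    convolution dictates, so an isolated cell peaks at exactly 1 at its
    center.
    """
    h, w = shape
    centers = np.asarray(centers, dtype=int).reshape(-1, 2)
    if len(centers) and (
        centers[:, 0].min() < 0
        or centers[:, 0].max() >= h
        or centers[:, 1].min() < 0
        or centers[:, 1].max() >= w
    ):
        raise ValueError("center outside image bounds")
    target = np.zeros((h, w))
    if len(centers) == 0:
        return target
    radius = int(np.ceil(4 * sigma))
    ax = np.arange(-radius, radius + 1)
    kernel = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sigma**2))
    for r, c in centers:
        r0, r1 = max(0, r - radius), min(h, r + radius + 1)
        c0, c1 = max(0, c - radius), min(w, c + radius + 1)
        target[r0:r1, c0:c1] += kernel[
            r0 - r + radius : r1 - r + radius, c0 - c + radius : c1 - c + radius
        ]
    return target


def weighted_mse_loss(y: np.ndarray, o: np.ndarray, beta: float = 0.2) -> float:
    """Center-weighted squared loss 1/2 * sum (y + beta*ybar) (y - o)^2."""
    y = np.asarray(y, dtype=float)
    o = np.asarray(o, dtype=float)
    if y.shape != o.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {o.shape}")
    weights = y + beta * y.mean()
    return float(0.5 * np.sum(weights * (y - o) ** 2))


def _loss_grad(y: np.ndarray, o: np.ndarray, beta: float) -> np.ndarray:
    return (y + beta * y.mean()) * (o - y)


@dataclass
class DetectorConfig:
    """Training configuration of the reference map-regression detector."""

    loss: DetectionLossConfig = field(default_factory=DetectionLossConfig)
    channels: tuple[int, ...] = (8, 4)  # hidden channels of the conv stack
    kernel_sizes: tuple[int, ...] = (9, 9, 5)  # one per conv layer
    n_steps: int = 400
    batch_size: int = 4
    learning_rate: float = 3e-3
    seed: int = 0

    def __post_init__(self):
        if len(self.kernel_sizes) != len(self.channels) + 1:
            raise ValueError("need one kernel size per conv layer")


@dataclass
class DetectorModel:
    """Trained detector: the conv net plus training metadata."""

    net: ConvNet
    config: DetectorConfig
    loss_history: list[float] = field(default_factory=list)

    @property
    def final_loss(self) -> float | None:
        return self.loss_history[-1] if self.loss_history else None


def _build_net(config: DetectorConfig) -> ConvNet:
    rng = np.random.default_rng(config.seed)
    widths = (1,) + tuple(config.channels) + (1,)
    layers: list = []
    for i, k in enumerate(config.kernel_sizes):
        layers.append(Conv2D(widths[i], widths[i + 1], k, rng))
        if i < len(config.kernel_sizes) - 1:
            layers.append(ReLU())
    return ConvNet(layers)


def train_detector(
    images: list[np.ndarray],
    target_maps: list[np.ndarray],
    config: DetectorConfig | None = None,
) -> DetectorModel:
    """Fit the map-regression detector by minibatch Adam on the weighted loss.

    Inputs are grayscale float images in [0, 1] with matching target maps.
    The per-step minibatch loss is recorded in ``loss_history``. A
    non-finite loss aborts with diagnostics rather than training onward.
    """
    if config is None:
        config = DetectorConfig()
    if len(images) == 0:
        raise ValueError("empty training set")
    if len(images) != len(target_maps):
        raise ValueError("images and target maps must align")
    for x, y in zip(images, target_maps):
        if x.shape != y.shape:
            raise ValueError("image/target shape mismatch")

    net = _build_net(config)
    model = DetectorModel(net=net, config=config)
    if config.n_steps == 0:
        return model

    opt = Adam(net.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    beta = config.loss.beta
    n = len(images)
    for step in range(config.n_steps):
        batch = rng.choice(n, size=min(config.batch_size, n), replace=False)
        grads = None
        batch_loss = 0.0
        for idx in batch:
            x, y = images[idx], target_maps[idx]
            o = net.forward(x[None])[0]
            batch_loss += weighted_mse_loss(y, o, beta)
            net.backward(_loss_grad(y, o, beta)[None])
            g = [a.copy() for a in net.grads()]
            grads = g if grads is None else [s + a for s, a in zip(grads, g)]
        scale = 1.0 / (len(batch) * x.size)  # per-pixel scaling for a stable lr
        grads = [g * scale for g in grads]
        if not np.isfinite(batch_loss):
            raise FloatingPointError(
                f"non-finite training loss at step {step}: {batch_loss}"
            )
        opt.step(grads)
        model.loss_history.append(batch_loss / len(batch))
    return model


def predict_map(model: DetectorModel, image: np.ndarray) -> np.ndarray:
    """Predicted confidence map; same shape as the input, deterministic."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    return model.net.forward(image[None])[0]


def nms_peaks(
    confidence: np.ndarray, radius: int = 5, threshold: float | None = None
) -> np.ndarray:
    """Extract cell centers by non-maximum suppression.

    A pixel is kept when it is the maximum of its (2*radius+1)^2
    neighborhood and exceeds ``threshold`` (default 0.3 * map maximum).
    Plateau ties are broken toward the lexicographically smallest
    (row, col); accepted centers are pairwise more than ``radius`` apart in
    Chebyshev distance, matching the square suppression window.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    confidence = np.asarray(confidence, dtype=float)
    if threshold is None:
        threshold = 0.3 * confidence.max()
    footprint = 2 * radius + 1
    local_max = ndimage.maximum_filter(confidence, size=footprint, mode="nearest")
    cand = np.argwhere((confidence >= local_max) & (confidence > threshold))
    if len(cand) == 0:
        return np.empty((0, 2), dtype=int)
    scores = confidence[cand[:, 0], cand[:, 1]]
    order = np.lexsort((cand[:, 1], cand[:, 0], -scores))
    kept: list[np.ndarray] = []
    for i in order:
        p = cand[i]
        if all(max(abs(p[0] - q[0]), abs(p[1] - q[1])) > radius for q in kept):
            kept.append(p)
    kept_arr = np.array(kept, dtype=int)
    return kept_arr[np.lexsort((kept_arr[:, 1], kept_arr[:, 0]))]


@dataclass
class DetectionMetrics:
    precision: float
    recall: float
    f1: float
    tolerance: float
    matched_pairs: int


def detection_metrics(
    predicted: np.ndarray, truth: np.ndarray, tolerance: float = 5.0
) -> DetectionMetrics:
    """Greedy one-to-one matching of predicted to true centers.

    Candidate pairs within ``tolerance`` (Euclidean) are matched in order
    of increasing distance; each center matches at most once. Precision and
    recall default to 1 when both sets are empty, and to 0 when exactly one
    is empty.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    predicted = np.asarray(predicted, dtype=float).reshape(-1, 2)
    truth = np.asarray(truth, dtype=float).reshape(-1, 2)
    n_pred, n_true = len(predicted), len(truth)
    if n_pred == 0 and n_true == 0:
        return DetectionMetrics(1.0, 1.0, 1.0, tolerance, 0)
    if n_pred == 0 or n_true == 0:
        return DetectionMetrics(0.0, 0.0, 0.0, tolerance, 0)

    diff = predicted[:, None, :] - truth[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    pairs = [
        (dist[i, j], i, j)
        for i in range(n_pred)
        for j in range(n_true)
        if dist[i, j] <= tolerance
    ]
    pairs.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    matches = 0
    for _, i, j in pairs:
        if i not in used_p and j not in used_t:
            used_p.add(i)
            used_t.add(j)
            matches += 1
    precision = matches / n_pred
    recall = matches / n_true
    f1 = 0.0 if matches == 0 else 2 * precision * recall / (precision + recall)
    return DetectionMetrics(precision, recall, f1, tolerance, matches)
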