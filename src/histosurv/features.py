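"""Per-cell patch extraction and cellular descriptors.

Each detected cell is represented by the square patch (default 80x80)
cropped around its center, and a descriptor backend maps patches to
fixed-length column vectors, giving the descriptor matrix X of shape
(D, N). Two backends matter scientifically:

* ``hog`` — a gradient-orientation histogram (HOG); sensitive to small
  translations of the cell within the patch;
* ``gap-cnn`` — a small convolutional stack ending in global average
  pooling (GAP); the spatial averaging makes it tolerant to the center
  localization errors a detector inevitably makes.

:func:`translation_robustness` quantifies that difference by re-extracting
descriptors after shifting every center by t pixels in a random direction
and measuring both the descriptor displacement and top-k self-retrieval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist
from skimage.feature import hog as _skimage_hog

from ._convnet import Conv2D, ConvNet, ReLU

__all__ = [
    "PatchSet",
    "DescriptorMatrix",
    "RobustnessReport",
    "HogDescriptor",
    "GapCnnDescriptor",
    "MeanDescriptor",
    "get_descriptor",
    "register_descriptor",
    "extract_patches",
    "compute_descriptors",
    "subsample_cells",
    "translation_robustness",
]

DEFAULT_PATCH_SIZE = 80
DEFAULT_SHIFTS = (1, 3, 5, 7, 9, 11)
DEFAULT_SUBSAMPLE = 2000


@dataclass
class PatchSet:
    patches: np.ndarray  # (N, s, s)
    cell_ids: np.ndarray  # (N,)
    centers: np.ndarray  # (N, 2)

    @property
    def size(self) -> int:
        return self.patches.shape[1]

    def __len__(self) -> int:
        return len(self.patches)


@dataclass
class DescriptorMatrix:
    X: np.ndarray  # (D, N)
    descriptor_name: str
    cell_ids: np.ndarray | None = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.X)):
            raise ValueError("descriptor matrix contains non-finite entries")

    @property
    def dim(self) -> int:
        return self.X.shape[0]

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]


def _extract(
    image: np.ndarray, centers: np.ndarray, size: int, allowance: int
) -> np.ndarray:
    """Crop half-open [r - size//2, r + size//2) windows with reflect padding.

    ``allowance`` extends the admissible center range beyond the image by
    that many pixels (used for translation experiments); centers farther
    out raise.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    centers = np.asarray(centers, dtype=int).reshape(-1, 2)
    if len(centers):
        if (
            centers[:, 0].min() < -allowance
            or centers[:, 0].max() >= h + allowance
            or centers[:, 1].min() < -allowance
            or centers[:, 1].max() >= w + allowance
        ):
            raise ValueError("center outside padded bounds")
    half = size // 2
    pad = half + allowance
    padded = np.pad(image, pad, mode="reflect")
    patches = np.empty((len(centers), size, size))
    for i, (r, c) in enumerate(centers):
        patches[i] = padded[r + pad - half : r + pad - half + size,
                            c + pad - half : c + pad - half + size]
    return patches


def extract_patches(
    image: np.ndarray, centers: np.ndarray, size: int = DEFAULT_PATCH_SIZE
) -> PatchSet:
    """One size x size patch per center; the center sits at index (size//2,
    size//2) of its patch. Borders are reflection-padded so no cell is
    dropped."""
    centers = np.asarray(centers, dtype=int).reshape(-1, 2)
    patches = _extract(image, centers, size, allowance=0)
    return PatchSet(
        patches=patches, cell_ids=np.arange(len(centers)), centers=centers
    )


# ---------------------------------------------------------------------------
# descriptor backends
# ---------------------------------------------------------------------------


class HogDescriptor:
    """Histogram-of-oriented-gradients descriptor of the whole patch."""

    name = "hog"

    def __init__(self, orientations: int = 9, pixels_per_cell: int = 10,
                 cells_per_block: int = 2):
        self.orientations = orientations
        self.pixels_per_cell = pixels_per_cell
        self.cells_per_block = cells_per_block

    def __call__(self, patches: np.ndarray) -> np.ndarray:
        cols = [
            _skimage_hog(
                p,
                orientations=self.orientations,
                pixels_per_cell=(self.pixels_per_cell,) * 2,
                cells_per_block=(self.cells_per_block,) * 2,
                feature_vector=True,
            )
            for p in patches
        ]
        return np.asarray(cols).T


class MeanDescriptor:
    """Global patch mean; fully translation-invariant, D = 1."""

    name = "mean"

    def __call__(self, patches: np.ndarray) -> np.ndarray:
        return patches.reshape(len(patches), -1).mean(axis=1)[None, :]


class GapCnnDescriptor:
    """Small convolutional stack ending in global average pooling.

    conv 3x3 (1 -> hidden) -> ReLU -> 2x2 average pool -> conv 3x3
    (hidden -> dim) -> ReLU -> GAP. Filters are He-initialized from the
    seed and kept fixed as a random projection bank; only the softmax
    risk-group head (a logistic regression on the GAP activations) is
    trained, via :meth:`train_head`. The head's weights double as the
    class weights for class activation maps.
    """

    name = "gap-cnn"

    def __init__(self, dim: int = 64, hidden: int = 16, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.dim = dim
        self.conv1 = Conv2D(1, hidden, 3, rng)
        self.relu = ReLU()
        self.conv2 = Conv2D(hidden, dim, 3, rng)
        self.head = None  # fitted LogisticRegression, optional

    def feature_maps(self, patch: np.ndarray) -> np.ndarray:
        """Final (dim, s/2, s/2) activation maps for one patch."""
        x = self.conv1.forward(np.asarray(patch, dtype=float)[None])
        x = np.maximum(x, 0.0)
        c, h, w = x.shape
        x = x[:, : h - h % 2, : w - w % 2]
        x = x.reshape(c, h // 2, 2, w // 2, 2).mean(axis=(2, 4))
        return np.maximum(self.conv2.forward(x), 0.0)

    def __call__(self, patches: np.ndarray) -> np.ndarray:
        return np.stack(
            [self.feature_maps(p).mean(axis=(1, 2)) for p in patches], axis=1
        )

    def train_head(self, patches: np.ndarray, risk_labels: np.ndarray,
                   C: float = 1.0):
        """Fit the softmax risk-group head on GAP activations."""
        from sklearn.linear_model import LogisticRegression

        feats = self(patches).T
        self.head = LogisticRegression(C=C, max_iter=2000).fit(feats, risk_labels)
        return self

    @property
    def class_weights(self) -> np.ndarray:
        """Head weights over the final feature maps (for CAM)."""
        if self.head is None:
            raise RuntimeError("head not trained; call train_head first")
        return self.head.coef_[0]

    def predict_cell_risk(self, patches: np.ndarray) -> np.ndarray:
        """Per-cell probability of the high-risk class, in [0, 1]."""
        if self.head is None:
            raise RuntimeError("head not trained; call train_head first")
        return self.head.predict_proba(self(patches).T)[:, -1]


_REGISTRY: dict[str, type] = {
    "hog": HogDescriptor,
    "gap-cnn": GapCnnDescriptor,
    "mean": MeanDescriptor,
}


def register_descriptor(name: str, factory) -> None:
    _REGISTRY[name] = factory


def get_descriptor(name: str, **kwargs):
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown descriptor backend {name!r}; known: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[name](**kwargs)


def compute_descriptors(patchset: PatchSet, descriptor="hog") -> DescriptorMatrix:
    """Apply a descriptor backend (name or instance) to every patch."""
    backend = get_descriptor(descriptor) if isinstance(descriptor, str) else descriptor
    X = backend(patchset.patches)
    return DescriptorMatrix(
        X=np.asarray(X, dtype=float),
        descriptor_name=getattr(backend, "name", type(backend).__name__),
        cell_ids=patchset.cell_ids,
    )


def subsample_cells(
    centers: np.ndarray, n: int = DEFAULT_SUBSAMPLE, seed: int = 0
) -> np.ndarray:
    """Uniform sample of at most n centers without replacement (order kept)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    centers = np.asarray(centers).reshape(-1, 2)
    if len(centers) <= n:
        return centers.copy()
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(centers), size=n, replace=False))
    return centers[idx]


# ---------------------------------------------------------------------------
# translation robustness
# ---------------------------------------------------------------------------

_DIRECTIONS = np.array([[0, -1], [0, 1], [-1, 0], [1, 0]])  # left, right, up, down


@dataclass
class RobustnessReport:
    shifts: tuple[int, ...]
    k_list: tuple[int, ...]
    normalized_median_distance: dict = field(default_factory=dict)  # t -> float
    topk_precision: dict = field(default_factory=dict)  # (t, k) -> float


def translation_robustness(
    image: np.ndarray,
    centers: np.ndarray,
    descriptor="hog",
    shifts: tuple[int, ...] = DEFAULT_SHIFTS,
    k_list: tuple[int, ...] = (1, 5, 10),
    size: int = DEFAULT_PATCH_SIZE,
    seed: int = 0,
) -> RobustnessReport:
    """Descriptor stability under simulated center-localization error.

    For each shift t, every center is displaced t pixels in one of the four
    axis directions (drawn per cell with a seeded generator), descriptors
    are recomputed, and the report records (a) the median per-cell
    displacement ||x_i - x_i^t||_2 normalized by the median inter-cell
    descriptor distance of the originals, and (b) top-k self-retrieval
    precision: the fraction of shifted cells whose k nearest original
    descriptors (Euclidean; ties broken by cell index) include their own.
    """
    if any(t < 0 for t in shifts):
        raise ValueError("shifts must be nonnegative")
    backend = get_descriptor(descriptor) if isinstance(descriptor, str) else descriptor
    centers = np.asarray(centers, dtype=int).reshape(-1, 2)
    allowance = int(max(shifts, default=0))
    rng = np.random.default_rng(seed)

    X = backend(_extract(image, centers, size, allowance))
    inter = pdist(X.T)
    med_inter = float(np.median(inter)) if len(inter) else 0.0

    report = RobustnessReport(shifts=tuple(shifts), k_list=tuple(k_list))
    for t in shifts:
        dirs = _DIRECTIONS[rng.integers(0, 4, size=len(centers))]
        shifted = centers + t * dirs
        Xt = backend(_extract(image, shifted, size, allowance))
        disp = np.linalg.norm(X - Xt, axis=0)
        med = float(np.median(disp)) if len(disp) else 0.0
        report.normalized_median_distance[t] = (
            med / med_inter if med_inter > 0 else 0.0
        )
        d = cdist(Xt.T, X.T)
        # stable argsort: ties resolved toward the lower original index
        ranks = np.argsort(d, axis=1, kind="stable")
        for k in k_list:
            hits = [i in ranks[i, :k] for i in range(len(centers))]
            report.topk_precision[(t, k)] = float(np.mean(hits)) if hits else 1.0
    return report
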