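"""Biomarker interpretation: map selected patient-vector features back to
cells and image regions.

Each entry of a BoW/LLC patient vector corresponds to one codebook
cluster, so a feature chosen by the survival model denotes a cell
phenotype. This module assigns cells to clusters, retrieves prototypical
member cells for a feature, overlays the contributing cells on the source
image, and computes class activation maps (CAMs) for the GAP descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .encoding import Codebook, _nearest
from .features import PatchSet

__all__ = [
    "AttentionOverlay",
    "assign_clusters",
    "retrieve_cells_for_feature",
    "highlight_attention_cells",
    "compute_cam",
    "upsample_cam",
    "render_overlay",
]


def assign_clusters(X: np.ndarray, B: Codebook | np.ndarray) -> np.ndarray:
    """Nearest codeword per cell (Euclidean; ties -> lowest index)."""
    B = B.B if isinstance(B, Codebook) else np.asarray(B, float)
    X = np.asarray(X, float)
    if X.shape[0] != B.shape[0]:
        raise ValueError("descriptor/codebook dimension mismatch")
    return _nearest(X, B)


def retrieve_cells_for_feature(
    feature_id: int,
    assignments: np.ndarray,
    patchset: PatchSet,
    codebook: Codebook | np.ndarray,
    X: np.ndarray,
    max_examples: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Gallery of cells assigned to one codebook feature.

    Returns (patches, cell_indices), nearest-to-codeword first, at most
    ``max_examples`` entries. An empty cluster yields an empty gallery.
    """
    B = codebook.B if isinstance(codebook, Codebook) else np.asarray(codebook, float)
    if not (0 <= feature_id < B.shape[1]):
        raise ValueError("feature_id out of range")
    members = np.flatnonzero(np.asarray(assignments) == feature_id)
    if len(members) == 0:
        return patchset.patches[:0], members
    dists = np.linalg.norm(np.asarray(X, float)[:, members] - B[:, [feature_id]],
                           axis=0)
    order = members[np.argsort(dists, kind="stable")][:max_examples]
    return patchset.patches[order], order


@dataclass
class AttentionOverlay:
    image: np.ndarray
    centers: np.ndarray  # highlighted (row, col) centers
    cluster_ids: np.ndarray  # cluster of each highlighted center
    radius: int = 5


def highlight_attention_cells(
    image: np.ndarray,
    centers: np.ndarray,
    assignments: np.ndarray,
    selected_features,
    radius: int = 5,
) -> AttentionOverlay:
    """Overlay marking exactly the cells assigned to the selected features."""
    assignments = np.asarray(assignments)
    selected = np.asarray(sorted(set(int(f) for f in selected_features)))
    mask = np.isin(assignments, selected)
    centers = np.asarray(centers).reshape(-1, 2)
    return AttentionOverlay(
        image=np.asarray(image, float),
        centers=centers[mask],
        cluster_ids=assignments[mask],
        radius=radius,
    )


def compute_cam(
    feature_maps: np.ndarray, class_weights: np.ndarray, rescale: bool = False
) -> np.ndarray:
    """Class activation map: the class-weighted sum of the final feature
    maps, CAM(x, y) = sum_k w_k map_k(x, y); optional min-max rescale to
    [0, 1] for display."""
    feature_maps = np.asarray(feature_maps, float)
    class_weights = np.asarray(class_weights, float)
    if len(class_weights) != feature_maps.shape[0]:
        raise ValueError("need one weight per feature map")
    cam = np.tensordot(class_weights, feature_maps, axes=1)
    if rescale:
        lo, hi = cam.min(), cam.max()
        cam = (cam - lo) / (hi - lo) if hi > lo else np.zeros_like(cam)
    return cam


def upsample_cam(cam: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear upsampling of a CAM to patch resolution."""
    return resize(cam, shape, order=1, mode="reflect", anti_aliasing=False)


def render_overlay(overlay: AttentionOverlay, path: str) -> None:
    """Save the attention overlay as a PNG (circles color-coded by cluster)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(overlay.image, cmap="gray", vmin=0, vmax=1)
    if len(overlay.centers):
        clusters = np.unique(overlay.cluster_ids)
        cmap = plt.get_cmap("tab10")
        for ci, cl in enumerate(clusters):
            pts = overlay.centers[overlay.cluster_ids == cl]
            ax.scatter(pts[:, 1], pts[:, 0], s=(overlay.radius * 4) ** 2,
                       facecolors="none", edgecolors=[cmap(ci % 10)],
                       label=f"cluster {cl}")
        ax.legend(loc="upper right", fontsize=8)
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
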