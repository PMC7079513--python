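"""Back-project selected features onto the image as cell highlights.

Each patient-vector entry corresponds to one codebook cluster, i.e. a
cell phenotype. This example assigns every cell to its nearest codeword,
retrieves the prototypical member cells of one cluster, overlays the
cells of two selected clusters on the source image, and computes a class
activation map (CAM) for one patch from the GAP descriptor's trained
risk head.
"""

import numpy as np

from histosurv.biomarker import (assign_clusters, compute_cam,
                                 highlight_attention_cells,
                                 render_overlay, retrieve_cells_for_feature,
                                 upsample_cam)
from histosurv.encoding import learn_codebook
from histosurv.features import GapCnnDescriptor, compute_descriptors, \
    extract_patches
from histosurv.synthetic import SyntheticImageSpec, generate_cell_image

image, centers, labels = generate_cell_image(
    SyntheticImageSpec(height=160, width=160, n_cells=40,
                       min_center_distance=12, seed=8)
)
patches = extract_patches(image, centers, size=24)
backend = GapCnnDescriptor(dim=16, hidden=8, seed=0)
X = compute_descriptors(patches, backend).X
codebook = learn_codebook(X, M=4, seed=0)

assignments = assign_clusters(X, codebook)
counts = np.bincount(assignments, minlength=4)
print(f"cells per cluster: {counts.tolist()}")

gallery, idx = retrieve_cells_for_feature(0, assignments, patches, codebook,
                                          X, max_examples=5)
print(f"gallery for cluster 0: {len(gallery)} prototypical cells "
      f"(cell ids {idx.tolist()})")

selected = [0, 2]
overlay = highlight_attention_cells(image, centers, assignments, selected)
render_overlay(overlay, "overlay_example.png")
print(f"highlighted {len(overlay.centers)} cells of clusters {selected} "
      "-> overlay_example.png")

backend.train_head(patches.patches, (labels > 0).astype(int))
fmaps = backend.feature_maps(patches.patches[0])
cam = upsample_cam(compute_cam(fmaps, backend.class_weights, rescale=True),
                   (24, 24))
print(f"CAM for the first cell patch: shape {cam.shape}, "
      f"peak attention at {np.unravel_index(cam.argmax(), cam.shape)}")
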