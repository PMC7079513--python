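"""Detect cell centers on a synthetic histology-style image.

Builds a Gaussian target map from known centers, trains the small
fully-convolutional map regressor under the center-weighted squared loss,
extracts peaks by non-maximum suppression and scores them against the
ground truth. Precision/recall near 1 mean nearly every cell was found
within the 5-pixel matching tolerance.
"""

from histosurv import detection as det
from histosurv.synthetic import SyntheticImageSpec, generate_cell_image

train_img, train_centers, _ = generate_cell_image(SyntheticImageSpec(seed=1))
test_img, test_centers, _ = generate_cell_image(SyntheticImageSpec(seed=2))

target = det.make_target_map(train_centers, train_img.shape, sigma=3.0)
model = det.train_detector(
    [train_img], [target],
    det.DetectorConfig(n_steps=150, batch_size=1, seed=0),
)
print(f"training loss {model.loss_history[0]:.1f} -> {model.final_loss:.1f}")

confidence = det.predict_map(model, test_img)
peaks = det.nms_peaks(confidence, radius=5, threshold=0.3 * confidence.max())
metrics = det.detection_metrics(peaks, test_centers, tolerance=5.0)
print(f"detected {len(peaks)} of {len(test_centers)} cells on a held-out image")
print(f"precision {metrics.precision:.3f}, recall {metrics.recall:.3f}, "
      f"F1 {metrics.f1:.3f} at {metrics.tolerance:.0f}-px tolerance")
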