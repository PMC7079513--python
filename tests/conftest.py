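import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_image():
    """One 128x128 synthetic image with 30 known cell centers."""
    from histosurv.synthetic import SyntheticImageSpec, generate_cell_image

    spec = SyntheticImageSpec(height=128, width=128, n_cells=30,
                              min_center_distance=12, seed=11)
    return generate_cell_image(spec)


@pytest.fixture(scope="session")
def clustered_descriptors():
    """Descriptor matrix with 8 well-separated clusters."""
    from histosurv.synthetic import generate_descriptors

    X, labels = generate_descriptors(n_cells=200, n_clusters=8, dim=16,
                                     noise_sd=0.05, seed=3)
    return X, labels


@pytest.fixture(scope="session")
def small_cohort():
    """Simulated cohort with two strong features among eight."""
    from histosurv.synthetic import (SyntheticCohortSpec, cohort_to_arrays,
                                     generate_cohort)

    beta = np.zeros(8)
    beta[0], beta[1] = 1.0, -1.0
    spec = SyntheticCohortSpec(n_patients=200, feature_dim=8,
                               true_coefficients=beta, censoring_rate=0.25,
                               seed=5)
    return cohort_to_arrays(generate_cohort(spec))


@pytest.fixture(scope="session")
def trained_small_detector():
    """A briefly trained detector on one small synthetic image."""
    from histosurv import detection as det
    from histosurv.synthetic import SyntheticImageSpec, generate_cell_image

    img, ctr, _ = generate_cell_image(
        SyntheticImageSpec(height=64, width=64, n_cells=8,
                           min_center_distance=12, seed=21)
    )
    target = det.make_target_map(ctr, img.shape, sigma=3.0)
    cfg = det.DetectorConfig(n_steps=200, batch_size=1, seed=0)
    model = det.train_detector([img], [target], cfg)
    return model, img, ctr, target
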