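"""Synthetic data generators for the survival-imaging pipeline.

Three generators cover the three data domains the pipeline consumes:

* :func:`generate_cell_image` — grayscale histology-style images with known
  cell centers, for testing detection end to end;
* :func:`generate_descriptors` — cellular descriptor matrices with known
  Gaussian-mixture cluster structure, for testing codebook learning and
  encoding;
* :func:`generate_cohort` — survival cohorts with known proportional-hazards
  structure ``h_i(t) = h0 * exp(f_i . beta)``, for testing the penalized Cox
  fitter, feature selection and the evaluation metrics.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "SyntheticImageSpec",
    "SyntheticCohortSpec",
    "SurvivalRecord",
    "generate_cell_image",
    "generate_descriptors",
    "generate_cohort",
    "cohort_to_arrays",
]

MAX_PLACEMENT_ATTEMPTS = 10_000


def _default_class_params(n_classes: int) -> list[dict]:
    """Morphology classes spread in mean radius and intensity.

    Classes are made separable on purpose: downstream tests rely on cluster
    structure in the descriptors being attributable to morphology.
    """
    params = []
    for c in range(n_classes):
        frac = c / max(n_classes - 1, 1)
        params.append(
            {
                "radius_mean": 4.0 + 2.0 * frac,
                "intensity_mean": 0.30 + 0.25 * frac,
                "intensity_sd": 0.03,
                "eccentricity": 0.3 + 0.3 * frac,
            }
        )
    return params


@dataclass
class SyntheticImageSpec:
    """Parameters of one synthetic cell image.

    Intensities live in [0, 1]; cells are rendered as dark elliptical blobs
    on a brighter, lightly textured background, loosely emulating nuclei in
    a hematoxylin channel at 20X.
    """

    height: int = 144
    width: int = 144
    n_cells: int = 50
    radius_range: tuple[float, float] = (3.5, 6.0)
    min_center_distance: float = 10.0
    n_morphology_classes: int = 2
    class_params: list[dict] | None = None
    class_probabilities: tuple[float, ...] | None = None
    noise_sd: float = 0.04
    background_intensity: float = 0.78
    texture_amplitude: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.radius_range[0] > self.radius_range[1]:
            raise ValueError("radius_range must satisfy min <= max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_morphology_classes < 1:
            raise ValueError("need at least one morphology class")
        if self.class_params is None:
            self.class_params = _default_class_params(self.n_morphology_classes)
        elif len(self.class_params) != self.n_morphology_classes:
            raise ValueError("class_params length must equal n_morphology_classes")
        if self.class_probabilities is not None:
            probs = np.asarray(self.class_probabilities, dtype=float)
            if len(probs) != self.n_morphology_classes or not np.isclose(
                probs.sum(), 1.0
            ):
                raise ValueError("class_probabilities must sum to 1, one per class")


@dataclass
class SyntheticCohortSpec:
    """Parameters of one synthetic survival cohort.

    Event times follow an exponential proportional-hazards model with
    per-patient hazard ``baseline_rate * exp(f . true_coefficients)`` and
    standard-normal features f. Censoring combines an independent
    exponential mechanism (rate solved so the expected censored fraction
    matches ``censoring_rate``) and administrative cut-off at
    ``max_followup`` days.
    """

    n_patients: int = 100
    feature_dim: int = 8
    true_coefficients: np.ndarray | None = None
    baseline_rate: float = 1.0 / 1000.0  # events per day; median survival ~2 years
    censoring_rate: float = 0.3
    max_followup: float = np.inf
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.true_coefficients is None:
            self.true_coefficients = np.zeros(self.feature_dim)
        else:
            self.true_coefficients = np.asarray(self.true_coefficients, dtype=float)
            if self.true_coefficients.shape != (self.feature_dim,):
                raise ValueError("true_coefficients must have length feature_dim")


@dataclass
class SurvivalRecord:
    """One patient: feature vector, observed time (days), event indicator."""

    patient_id: str
    features: np.ndarray
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("observed time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event indicator must be 0 or 1")


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def _place_centers(spec: SyntheticImageSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample integer centers pairwise >= min_center_distance apart.

    Keeps a margin of the maximum radius from the borders so blobs stay
    mostly inside the frame. Gives up after MAX_PLACEMENT_ATTEMPTS and
    returns however many were placed.
    """
    margin = int(np.ceil(spec.radius_range[1])) + 1
    lo_r, hi_r = margin, spec.height - margin
    lo_c, hi_c = margin, spec.width - margin
    if lo_r >= hi_r or lo_c >= hi_c:
        raise ValueError("image too small for the requested cell radius")
    centers: list[tuple[int, int]] = []
    attempts = 0
    d2 = spec.min_center_distance**2
    while len(centers) < spec.n_cells and attempts < MAX_PLACEMENT_ATTEMPTS:
        attempts += 1
        r = int(rng.integers(lo_r, hi_r))
        c = int(rng.integers(lo_c, hi_c))
        ok = all((r - rr) ** 2 + (c - cc) ** 2 >= d2 for rr, cc in centers)
        if ok:
            centers.append((r, c))
    return np.asarray(centers, dtype=int).reshape(-1, 2)


def generate_cell_image(
    spec: SyntheticImageSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a synthetic cell image.

    Returns
    -------
    image : (h, w) float array in [0, 1]
    centers : (n, 2) int array of (row, col) blob centers
    class_labels : (n,) int array of morphology-class indices

    Raises
    ------
    RuntimeError
        If fewer than ``spec.n_cells`` centers could be placed at the
        requested ``min_center_distance`` within the attempt budget; the
        message reports how many were placed.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    # lightly textured background: smoothed white noise around the base level
    texture = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=6.0)
    if texture.std() > 0:
        texture = texture / texture.std()
    image = spec.background_intensity + spec.texture_amplitude * texture

    centers = _place_centers(spec, rng)
    if len(centers) < spec.n_cells:
        raise RuntimeError(
            f"placed only {len(centers)} of {spec.n_cells} cells at "
            f"min_center_distance={spec.min_center_distance} within "
            f"{MAX_PLACEMENT_ATTEMPTS} attempts"
        )

    if spec.class_probabilities is not None:
        labels = rng.choice(
            spec.n_morphology_classes, size=len(centers),
            p=np.asarray(spec.class_probabilities, dtype=float),
        )
    else:
        labels = rng.integers(0, spec.n_morphology_classes, size=len(centers))
    rr_grid, cc_grid = np.mgrid[0:h, 0:w]
    lo, hi = spec.radius_range
    for (r0, c0), lab in zip(centers, labels):
        p = spec.class_params[int(lab)]
        radius = float(np.clip(rng.normal(p["radius_mean"], 0.4), lo, hi))
        ecc = p.get("eccentricity", 0.4)
        minor = radius * (1.0 - 0.5 * ecc)
        theta = rng.uniform(0, np.pi)
        intensity = rng.normal(p["intensity_mean"], p.get("intensity_sd", 0.03))

        dr, dc = rr_grid - r0, cc_grid - c0
        u = np.cos(theta) * dr + np.sin(theta) * dc
        v = -np.sin(theta) * dr + np.cos(theta) * dc
        # signed elliptical "distance"; soft edge ~1.2 px wide
        dist = np.sqrt((u / radius) ** 2 + (v / minor) ** 2)
        mask = 1.0 / (1.0 + np.exp(np.clip((dist - 1.0) * radius / 0.6,
                                           -60.0, 60.0)))
        image = image * (1 - mask) + intensity * mask

    if spec.noise_sd > 0:
        image = image + rng.normal(0, spec.noise_sd, size=(h, w))
    return np.clip(image, 0.0, 1.0), centers, labels


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------


def generate_descriptors(
    n_cells: int,
    n_clusters: int,
    dim: int = 64,
    noise_sd: float = 0.1,
    seed: int = 0,
    separation: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw descriptor columns from an isotropic Gaussian mixture.

    Cluster means are random Gaussian vectors rescaled to pairwise
    separation ~``separation`` so that k-means can recover the partition
    when ``noise_sd`` is small. Returns ``(X, labels)`` with
    ``X.shape == (dim, n_cells)``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_clusters > n_cells:
        raise ValueError("n_clusters must be <= n_cells")
    rng = np.random.default_rng(seed)
    means = rng.standard_normal((n_clusters, dim))
    # normalize mean norms so separation is controlled regardless of dim
    means *= separation / np.sqrt(2 * dim)
    labels = rng.integers(0, n_clusters, size=n_cells)
    # guarantee every cluster is populated (pre-condition n_clusters<=n_cells)
    labels[:n_clusters] = np.arange(n_clusters)
    X = means[labels].T.copy()
    if noise_sd > 0:
        X = X + rng.normal(0, noise_sd, size=X.shape)
    return X, labels


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def _solve_censoring_rate(
    hazards: np.ndarray, target: float, max_followup: float
) -> float:
    """Rate c of an Exp(c) censoring time such that the expected censored
    fraction (exponential + administrative at max_followup) equals target.

    With event rate r and censoring rate c the probability the event is
    observed is r/(r+c) * (1 - exp(-(r+c)*maxF)). Solved by bisection on c.
    """

    def censored_fraction(c: float) -> float:
        rc = hazards + c
        observed = hazards / rc * (1.0 - np.exp(-rc * max_followup))
        return float(1.0 - observed.mean())

    floor = censored_fraction(0.0)  # administrative censoring only
    if target <= floor + 1e-12:
        return 0.0
    hi = 10.0 * hazards.max()
    while censored_fraction(hi) < target:
        hi *= 10.0
        if hi > 1e12:
            break
    return float(optimize.brentq(lambda c: censored_fraction(c) - target, 0.0, hi))


def generate_cohort(spec: SyntheticCohortSpec) -> list[SurvivalRecord]:
    """Simulate a survival cohort under the exponential Cox model.

    Event time T_i ~ Exp(baseline_rate * exp(f_i . beta_true)); censoring
    time C_i ~ Exp(c) with c tuned so the expected censored fraction matches
    ``spec.censoring_rate``; observed time = min(T, C, max_followup), event
    indicator 1 iff the event came first.
    """
    rng = np.random.default_rng(spec.seed)
    P, M = spec.n_patients, spec.feature_dim
    F = rng.standard_normal((P, M))
    hazards = spec.baseline_rate * np.exp(F @ spec.true_coefficients)
    event_times = rng.exponential(1.0 / hazards)

    c_rate = _solve_censoring_rate(hazards, spec.censoring_rate, spec.max_followup)
    if c_rate > 0:
        censor_times = rng.exponential(1.0 / c_rate, size=P)
    else:
        censor_times = np.full(P, np.inf)
    cutoff = np.minimum(censor_times, spec.max_followup)
    observed = np.minimum(event_times, cutoff)
    delta = (event_times <= cutoff).astype(int)
    observed = np.maximum(observed, 1e-9)  # times must be strictly positive

    return [
        SurvivalRecord(
            patient_id=f"P{i:04d}",
            features=F[i],
            time=float(observed[i]),
            event=int(delta[i]),
        )
        for i in range(P)
    ]


def cohort_to_arrays(
    records: list[SurvivalRecord],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack a cohort into (F, times, deltas) arrays, F of shape (P, M)."""
    F = np.vstack([r.features for r in records])
    times = np.array([r.time for r in records])
    deltas = np.array([r.event for r in records])
    return F, times, deltas
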