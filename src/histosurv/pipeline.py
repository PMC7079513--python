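"""End-to-end orchestration: simulate -> detect -> featurize -> encode ->
fit -> evaluate -> visualize, from one config, with a run manifest.

The synthetic end-to-end study plants survival signal in cell morphology:
each simulated patient has a latent fraction of "aggressive" morphology
cells, the image is rendered with that class mixture, and event times are
drawn from an exponential proportional-hazards model whose log-hazard is
``effect_size`` times the (centered, rescaled to [-1, 1]) fraction. A
pipeline that detects cells, describes them, encodes class composition
into the patient vector and fits the penalized Cox model can therefore
recover patient risk ordering from pixels alone; with ``effect_size = 0``
the images carry no survival information and held-out concordance must
fall to chance.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import detection, encoding, evaluation, features, io, survival
from .biomarker import assign_clusters, highlight_attention_cells, render_overlay
from .synthetic import SyntheticImageSpec, _solve_censoring_rate, generate_cell_image

logger = logging.getLogger("histosurv.pipeline")

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "null_cindex_replicates"]


@dataclass
class RunConfig:
    """All stage parameters of one synthetic end-to-end run.

    Defaults follow the reference analysis where stated there (loss beta
    0.2, elastic-net alpha 0.2, risk threshold 0.5, three-year risk
    horizon); sizes are desk-scale.
    """

    seed: int = 0
    # cohort
    n_patients: int = 60
    train_fraction: float = 0.5
    effect_size: float = 2.5  # log-hazard range across the morphology mixture
    baseline_rate: float = 1.0 / 1000.0
    censoring_rate: float = 0.25
    # images
    image_size: int = 128
    cells_per_image: int = 40
    noise_sd: float = 0.04
    # detection
    sigma: float = 3.0
    loss_beta: float = 0.2
    nms_radius: int = 5
    nms_threshold_frac: float = 0.3
    detector_train_images: int = 6
    detector_steps: int = 150
    use_true_centers: bool = False
    # features
    descriptor: str = "hog"
    patch_size: int = 24
    subsample: int = 2000
    # encoding
    codebook_size: int = 8
    encode_method: str = "llc"  # llc | bow
    llc_k: int = 5
    pooling: str = "sum"
    # survival
    alpha: float = 0.2
    cv_folds: int = 5
    risk_threshold: float = 0.5
    risk_T1_years: float = 3.0
    risk_T2_years: float = 3.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_patients < 4:
            raise ValueError("need at least 4 patients")
        if self.encode_method not in ("llc", "bow"):
            raise ValueError("encode_method must be 'llc' or 'bow'")


@dataclass
class RunManifest:
    config: dict
    stages: dict = field(default_factory=dict)  # stage -> {params, outputs, seconds}
    metrics: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: dict[str, str], seconds: float,
               **params) -> None:
        self.stages[stage] = {
            "params": params,
            "outputs": {name: io.sha256_file(p) for name, p in outputs.items()},
            "seconds": round(seconds, 3),
        }


def _simulate(cfg: RunConfig, out: Path, manifest: RunManifest):
    t0 = time.time()
    rng = np.random.default_rng(cfg.seed)
    fractions = rng.uniform(0.15, 0.85, size=cfg.n_patients)
    images, centers_list, labels_list = [], [], []
    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    outputs = {}
    for p, frac in enumerate(fractions):
        spec = SyntheticImageSpec(
            height=cfg.image_size, width=cfg.image_size,
            n_cells=cfg.cells_per_image, noise_sd=cfg.noise_sd,
            n_morphology_classes=2, class_probabilities=(1 - frac, frac),
            seed=int(rng.integers(2**31)),
        )
        img, ctr, lab = generate_cell_image(spec)
        images.append(img)
        centers_list.append(ctr)
        labels_list.append(lab)
        io.save_image(img_dir / f"patient_{p:03d}.png", img)
        io.save_centers(img_dir / f"patient_{p:03d}_centers.csv", ctr,
                        class_labels=lab)
        outputs[f"image_{p}"] = img_dir / f"patient_{p:03d}.png"

    # survival from the latent morphology fraction
    lp = cfg.effect_size * (fractions - 0.5) * 2.0
    hazards = cfg.baseline_rate * np.exp(lp)
    event_times = rng.exponential(1.0 / hazards)
    c_rate = _solve_censoring_rate(hazards, cfg.censoring_rate, np.inf)
    censor = (rng.exponential(1.0 / c_rate, cfg.n_patients)
              if c_rate > 0 else np.full(cfg.n_patients, np.inf))
    times = np.maximum(np.minimum(event_times, censor), 1e-9)
    deltas = (event_times <= censor).astype(int)
    ids = [f"P{p:03d}" for p in range(cfg.n_patients)]
    io.save_cohort(out / "clinical.csv", ids, times, deltas,
                   fractions[:, None])
    outputs["clinical"] = out / "clinical.csv"
    manifest.record("simulate", outputs, time.time() - t0,
                    n_patients=cfg.n_patients, effect_size=cfg.effect_size)
    return images, centers_list, times, deltas, ids


def _detect(cfg: RunConfig, images, true_centers, out: Path,
            manifest: RunManifest):
    t0 = time.time()
    if cfg.use_true_centers:
        detected = [np.asarray(c) for c in true_centers]
        manifest.record("detect", {}, time.time() - t0, mode="oracle-centers")
        return detected
    n_train = min(cfg.detector_train_images, len(images))
    targets = [
        detection.make_target_map(true_centers[i], images[i].shape, cfg.sigma)
        for i in range(n_train)
    ]
    model = detection.train_detector(
        images[:n_train], targets,
        detection.DetectorConfig(
            loss=detection.DetectionLossConfig(beta=cfg.loss_beta,
                                               sigma=cfg.sigma),
            n_steps=cfg.detector_steps, seed=cfg.seed,
        ),
    )
    detected = []
    for img in images:
        cmap = detection.predict_map(model, img)
        detected.append(detection.nms_peaks(
            cmap, radius=cfg.nms_radius,
            threshold=cfg.nms_threshold_frac * cmap.max(),
        ))
    det_dir = out / "detections"
    det_dir.mkdir(exist_ok=True)
    outputs = {}
    for p, ctr in enumerate(detected):
        path = det_dir / f"patient_{p:03d}_detected.csv"
        io.save_centers(path, ctr)
        outputs[f"detected_{p}"] = path
    manifest.record("detect", outputs, time.time() - t0,
                    steps=cfg.detector_steps,
                    final_loss=model.final_loss)
    return detected


def run_pipeline(cfg: RunConfig, out_dir) -> RunManifest:
    """Execute the full synthetic study; returns the manifest with metrics.

    Writes every stage artifact (images, centers, descriptors, codebook,
    patient vectors, fit, metrics, overlay) plus ``manifest.json`` under
    ``out_dir``. Fixed config + seed reproduce identical artifact digests.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(cfg))

    images, centers_list, times, deltas, ids = _simulate(cfg, out, manifest)
    detected = _detect(cfg, images, centers_list, out, manifest)

    # featurize
    t0 = time.time()
    backend = features.get_descriptor(cfg.descriptor)
    descr = []
    patchsets = []
    for img, ctr in zip(images, detected):
        ctr = features.subsample_cells(ctr, cfg.subsample, seed=cfg.seed)
        ps = features.extract_patches(img, ctr, size=cfg.patch_size)
        patchsets.append(ps)
        descr.append(features.compute_descriptors(ps, backend).X)
    manifest.record("featurize", {}, time.time() - t0,
                    descriptor=cfg.descriptor, patch_size=cfg.patch_size)

    # encode
    t0 = time.time()
    rng = np.random.default_rng(cfg.seed + 1)
    perm = rng.permutation(cfg.n_patients)
    n_train = int(round(cfg.train_fraction * cfg.n_patients))
    train_idx, test_idx = perm[:n_train], perm[n_train:]
    pooled = np.concatenate([descr[i] for i in train_idx], axis=1)
    codebook = encoding.learn_codebook(pooled, M=cfg.codebook_size,
                                       seed=cfg.seed)
    vectors = []
    for X in descr:
        if cfg.encode_method == "llc":
            C = encoding.encode_llc(X, codebook.B, k=min(cfg.llc_k,
                                                         cfg.codebook_size))
        else:
            C = encoding.encode_bow(X, codebook.B)
        vectors.append(encoding.pool(C, mode=cfg.pooling).f)
    Fmat = np.vstack(vectors)
    io.save_matrix(out / "codebook.npy", codebook.B,
                   meta={"M": cfg.codebook_size, "inertia": codebook.inertia})
    io.save_cohort(out / "patient_vectors.csv", ids, times, deltas, Fmat)
    manifest.record(
        "encode", {"codebook": out / "codebook.npy",
                   "patient_vectors": out / "patient_vectors.csv"},
        time.time() - t0, M=cfg.codebook_size, method=cfg.encode_method,
    )

    # fit + evaluate
    t0 = time.time()
    lam = survival.cv_choose_lambda(
        Fmat[train_idx], times[train_idx], deltas[train_idx],
        alpha=cfg.alpha, folds=cfg.cv_folds, seed=cfg.seed, n_lambdas=30,
        rule="1se",
    )
    fit = survival.fit_cox_elastic_net(
        Fmat[train_idx], times[train_idx], deltas[train_idx],
        alpha=cfg.alpha, lam=lam, warn=False,
    )
    risks_test = fit.predict_risk(Fmat[test_idx])
    try:
        cres = evaluation.concordance_index(times[test_idx], deltas[test_idx],
                                            risks_test)
        cindex = cres.c_index
    except ValueError:
        cindex = float("nan")
    metrics = {"lambda": lam, "n_nonzero": int(len(fit.support)),
               "cindex_test": cindex, "n_train": int(n_train),
               "n_test": int(len(test_idx))}

    # optional classifier route: label risk groups at the 3-year horizon
    import pandas as pd

    T1 = cfg.risk_T1_years * survival.DAYS_PER_YEAR
    T2 = cfg.risk_T2_years * survival.DAYS_PER_YEAR
    clinical = pd.DataFrame({
        "patient_id": ids,
        "days_to_death": np.where(deltas == 1, times, np.nan),
        "days_to_last_followup": np.where(deltas == 0, times, np.nan),
    })
    groups = survival.label_risk_groups(clinical, T1=T1, T2=T2)
    lab_train = groups.iloc[train_idx]
    usable = lab_train != "excluded"
    if usable.sum() >= 4 and len(np.unique(lab_train[usable])) == 2:
        clf = survival.fit_risk_classifier(Fmat[train_idx][usable.to_numpy()],
                                           lab_train[usable].to_numpy())
        r_test = clf.predict_risk(Fmat[test_idx])
        low, high = evaluation.partition_by_threshold(r_test,
                                                      cfg.risk_threshold)
        if low.any() and high.any() and (deltas[test_idx].sum() > 0):
            try:
                lr = evaluation.logrank_test(
                    times[test_idx][low], deltas[test_idx][low],
                    times[test_idx][high], deltas[test_idx][high],
                )
                metrics["logrank_p"] = lr.p_value
            except ValueError:
                pass
    io.save_json(out / "cox_fit.json",
                 {"beta": fit.beta, "alpha": fit.alpha, "lambda": fit.lam,
                  "converged": fit.converged})
    io.save_json(out / "metrics.json", metrics)
    manifest.record("fit_evaluate",
                    {"cox_fit": out / "cox_fit.json",
                     "metrics": out / "metrics.json"},
                    time.time() - t0, alpha=cfg.alpha)
    manifest.metrics = metrics

    # visualize one test patient
    t0 = time.time()
    p0 = int(test_idx[0])
    assignments = assign_clusters(descr[p0], codebook)
    selected = fit.support if len(fit.support) else np.arange(
        min(2, cfg.codebook_size))
    overlay = highlight_attention_cells(images[p0], patchsets[p0].centers,
                                        assignments, selected,
                                        radius=cfg.nms_radius)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        render_overlay(overlay, out / "overlay.png")
    manifest.record("visualize", {"overlay": out / "overlay.png"},
                    time.time() - t0, patient=p0)

    io.save_json(out / "manifest.json", asdict(manifest))
    return manifest


def null_cindex_replicates(
    Fmat: np.ndarray, cfg: RunConfig, n_replicates: int = 20, seed: int = 0
) -> np.ndarray:
    """Held-out c-index distribution when survival is independent of images.

    Re-draws event/censoring times with effect size 0 (so the fixed patient
    vectors carry no survival information), refits the penalized Cox model
    on the training split and evaluates concordance on the held-out split,
    once per replicate.
    """
    rng = np.random.default_rng(seed)
    P = len(Fmat)
    n_train = int(round(cfg.train_fraction * P))
    out = []
    for _ in range(n_replicates):
        times = rng.exponential(1.0 / cfg.baseline_rate, P)
        censor = (rng.exponential(1.0 / (cfg.baseline_rate
                                         * cfg.censoring_rate
                                         / max(1 - cfg.censoring_rate, 1e-9)),
                                  P)
                  if cfg.censoring_rate > 0 else np.full(P, np.inf))
        obs = np.minimum(times, censor)
        deltas = (times <= censor).astype(int)
        perm = rng.permutation(P)
        tr, te = perm[:n_train], perm[n_train:]
        lam = survival.cv_choose_lambda(Fmat[tr], obs[tr], deltas[tr],
                                        alpha=cfg.alpha, folds=cfg.cv_folds,
                                        seed=int(rng.integers(2**31)),
                                        n_lambdas=20, rule="1se")
        fit = survival.fit_cox_elastic_net(Fmat[tr], obs[tr], deltas[tr],
                                           alpha=cfg.alpha, lam=lam,
                                           warn=False)
        risks = fit.predict_risk(Fmat[te])
        try:
            c = evaluation.concordance_index(obs[te], deltas[te], risks).c_index
        except ValueError:
            c = 0.5
        out.append(c)
    return np.asarray(out)
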