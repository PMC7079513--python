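# histosurv

Segmentation-free survival analysis of histopathology images: detect
cells as confidence-map peaks, describe them with patch descriptors,
aggregate the cells of each patient into one vector by bag-of-words /
locality-constrained linear coding, relate those vectors to survival
with an elastic-net-penalized Cox model, and project selected features
back onto the image as candidate biomarkers.

It is written for computational-pathology and biostatistics researchers
who want the full chain — detection, encoding, penalized survival
modelling, evaluation, visualization — as composable, tested library
pieces with a thin CLI, plus synthetic-data generators so every stage can
be exercised and validated without access to clinical slides.

## The model in brief

**Detection.** With `v` the binary image of annotated cell centers and
`G` a Gaussian kernel (std `σ`), the regression target is the confidence
map `y = v∗G`. A fully-convolutional network `o = f(x)` is trained with
the center-weighted loss

```
L(y, o) = ½ Σ_ij (y_ij + β·ȳ)(y_ij − o_ij)²,    β = 0.2,
```

and centers are read off `o` by non-maximum suppression.

**Encoding.** Given cellular descriptors `X = [x_1 … x_N] ∈ R^{D×N}` and
a k-means codebook `B ∈ R^{D×M}`, each cell is coded by hard vector
quantization (BoW) or by LLC, solving per cell

```
min ‖x_i − B_i c_i‖²   s.t.  1ᵀc_i = 1,
```

with `B_i` the k nearest codewords; codes are sum- or max-pooled and
l2-normalized into the patient vector `f`.

**Survival.** For observations `(f_i, y_i, δ_i)` the Cox model
`h_i(t) = h_0(t)·exp(f_iᵀβ)` is fit by maximizing the penalized Breslow
partial log-likelihood

```
L(β) − λ(α‖β‖₁ + ½(1−α)‖β‖₂²),    α = 0.2,
```

via cyclical coordinate descent with warm-started λ paths. Stable
features are found by repeating cross-validated λ choice + refit over
reshuffled folds and counting nonzero coefficients. Models are scored by
Kaplan-Meier curves with log-rank tests and by the directed-graph
concordance index (edges from each uncensored patient `i` to every `j`
with `t_i < t_j`; concordant when `r_i > r_j`, ties ½).

## Worked example

`examples/04_cox_elastic_net.py` simulates a 300-patient cohort with two
truly prognostic features (log-hazard ratios +1 and −1) among ten, fits
the elastic net at a cross-validated penalty on 200 patients and
evaluates on the held-out 100:

```
chosen lambda 10.21; converged in 14 outer iterations
coefficients: [ 0.887 -0.925  0.12  -0.164 -0.007  0.     0.063  0.     0.111  0.068]
(features 0 and 1 carry the signal; expect +/- with the rest small)
held-out c-index 0.777 over 3615 comparable pairs (0.5 = chance)
log-rank chi2 43.15, p = 5.07e-11 (significant at 0.05)
low-risk group: S(500 days) = 0.91
high-risk group: S(500 days) = 0.31
```

The two planted features come back large with the right signs and the
rest shrink toward zero; the held-out concordance of 0.78 and the
log-rank separation of the median-split risk groups (91% vs 31% survival
at 500 days) show the fitted risk scores order patients correctly.

The other examples cover one capability each: `01` detector training and
NMS (F1 ≈ 0.98 on a held-out synthetic image), `02` descriptor
translation robustness (HOG vs GAP), `03` codebook/BoW/LLC/pooling, `05`
selection frequencies, `06` cluster galleries, overlays and CAMs, `07`
the full pipeline from a single config. The same stages are scriptable
via the CLI:

```bash
histosurv simulate --out sim --n-cells 50 --seed 1
histosurv featurize --image sim/image.png --centers sim/centers.csv \
    --descriptor hog --out X.npy
histosurv encode --descriptors X.npy --method llc-sum --m 64 --out f.npy
histosurv run --out run1 --seed 1     # full synthetic study
```

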