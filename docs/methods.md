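# Methods

`histosurv` implements a segmentation-free survival-analysis workflow for
histopathology images: cells are *detected* (not segmented), described by
patch-level descriptors, aggregated into one vector per patient, and
linked to survival outcomes with a penalized Cox model. This note records
the models, the defaults and why, the numerical choices, and what the
synthetic data can and cannot establish.

## Cell detection as confidence-map regression

Ground truth is a set of annotated cell centers. The regression target is
`y = v * G`: the binary center-indicator image convolved with an
isotropic Gaussian of standard deviation `sigma` (default 3 px, exposed
in config). The kernel has peak amplitude 1 and is truncated at 4*sigma;
overlapping kernels are summed, as convolution dictates, so an isolated
cell peaks at exactly 1 at its center and nearby cells reinforce rather
than clip each other.

A detector `o = f(x)` is trained by minimizing the center-weighted
squared loss

    L(y, o) = 1/2 * sum_ij (y_ij + beta * ybar) * (y_ij - o_ij)^2,

with `ybar` the mean of `y` and `beta = 0.2` by default. The weight term
keeps the vast, uninformative background from dominating the objective:
pixels near centers (large `y_ij`) carry weight ~1 while background
pixels carry only `beta * ybar`. A degenerate corollary, tested
explicitly: when `y` is identically zero every weight vanishes and the
loss is 0 regardless of the prediction.

The reference backend is a small fully-convolutional network (two hidden
conv layers, 9x9/9x9/5x5 kernels with 8 and 4 channels, ReLU), written
directly on numpy/scipy with manual backpropagation and Adam. A plain
conv stack was chosen over an encoder–decoder because at the ~21-px
receptive field needed for nucleus-scale blobs, down/upsampling buys
nothing and the flat architecture trains on one CPU core in about two
minutes for the 25-image study; the backend is pluggable behind
`train_detector`/`predict_map` for anything larger. Training is
full-image minibatch Adam (batch 4, lr 3e-3) on the loss above; gradients
are rescaled per pixel so the learning rate is insensitive to image size.

Centers are read off the predicted map by non-maximum suppression: keep
pixels that are maxima of their `(2r+1)^2` neighborhood (default r = 5)
and exceed a threshold (default 0.3 x map maximum). Plateau ties keep the
lexicographically smallest (row, col); accepted peaks are pairwise more
than `r` apart in Chebyshev distance, the metric consistent with the
square suppression window. Coordinates are 0-based integers; no sub-pixel
refinement.

Detection quality is scored by greedy one-to-one matching in increasing
distance order, a pair matching when within the tolerance (default 5 px);
precision/recall conventions for empty sets are defined (1 when both sets
empty, 0 when exactly one is).

## Cellular descriptors

An 80x80 patch is cropped around each retained center (the center at
index (40, 40) of a half-open window; borders are reflection-padded so no
detection is dropped). When more cells are detected than needed, a
seeded uniform subsample (default 2000 cells) is taken.

Two descriptor backends matter scientifically:

* `hog` — a gradient-orientation histogram of the whole patch
  (skimage's HOG, 9 orientations, 10-px cells, 2x2 blocks). Sensitive to
  where the cell sits in the patch.
* `gap-cnn` — a small convolutional stack ending in global average
  pooling: conv 3x3 -> ReLU -> 2x2 average pool -> conv 3x3 -> ReLU ->
  GAP. The convolutional filters are He-initialized from a seed and kept
  fixed as a random projection bank; only the softmax risk-group head (a
  logistic regression on the GAP activations) is trained. Training the
  full stack end to end on large cohorts is out of scope at desk scale;
  fixed random filters preserve the property under study — GAP's spatial
  averaging — while keeping the backend deterministic and fast. The head
  weights double as class weights for class activation maps.

The translation-robustness analysis quantifies the difference: for each
shift t in {1, 3, 5, 7, 9, 11} px, every center is displaced t pixels in
a per-cell random axis direction, descriptors are recomputed, and the
report records (a) the median per-cell displacement ||x - x_t||_2
normalized by the median inter-cell descriptor distance (a
median-over-median convention) and (b) top-k self-retrieval precision
(k in {1, 5, 10} by default; Euclidean distances, ties broken toward the
lower cell index). On synthetic images the HOG curve rises steeply with t
while the GAP curve stays several-fold lower at t >= 5 — the property
that makes GAP-style descriptors forgiving of small detection errors.

## Patient-level aggregation

A codebook `B` (D x M, default M = 256) is learned by k-means over the
pooled training cells (seeded, 4 restarts, inertia logged). Cells are
encoded per column:

* hard VQ (BoW): one-hot at the nearest codeword, ties to the lowest
  index;
* LLC: restrict to the k nearest codewords (default k = 5), solve
  `min ||x - B_k c||^2 s.t. 1'c = 1` in closed form — center the
  neighbors at x, solve the k x k Gram system `(Z'Z) w = 1`, normalize w
  to sum one — and scatter into an M-vector. Near-singular Gram systems
  (duplicate codewords, exact codeword hits) get a ridge of
  1e-8 * trace(G) on the diagonal; the sum-to-one constraint holds
  exactly by construction. At k = 1 the constraint forces c = 1 and LLC
  reduces to hard VQ; for k >= 1 the VQ solution is feasible, so the LLC
  reconstruction error is never worse.

Codes are pooled by summation or elementwise max and l2-normalized
(`f = f / ||f||_2`); normalizing an exact zero vector returns zeros with
a warning. Two baselines are provided: the aggregate statistic
[means; medians; standard deviations] over cells (population
divide-by-N std; length 3D; not l2-normalized, mirroring its usual use),
and cellular voting (patient risk = arithmetic mean of per-cell risk
scores).

## Survival modelling

Patients are labelled for classifier training on a horizon T1 = T2 = 3
years (365.25 days/year): *high* risk if the known days-to-death is
below T1, *low* if days-to-death or days-to-last-follow-up exceeds T2,
otherwise *excluded* (notably censored patients whose follow-up ends
before the horizon). The binary risk classifier is an l2-regularized
logistic regression (C = 1) emitting r in [0, 1], larger = higher risk;
r = 0.5 partitions test patients into groups for the log-rank test
(boundary to the low group), while the raw r is used for concordance.

The Cox model assumes hazard `h_i(t) = h0(t) exp(f_i' beta)`. The Breslow
partial log-likelihood (ties handled by Breslow's approximation,
log-sum-exp stabilized) is penalized as

    L_net(beta) = L(beta) - lambda * (alpha ||beta||_1
                                      + 1/2 (1 - alpha) ||beta||_2^2),

alpha = 0.2 by default. Maximization follows the glmnet strategy:
iteratively reweighted least squares around the current linear predictor
with cyclical coordinate descent and soft-thresholding on the quadratic
approximation, warm starts along a path of 50 lambdas log-spaced over
[0.01 lambda_max, lambda_max]. `lambda_max = max_m |sum_i f_im g_i(0)| /
alpha` is the exact threshold at which the zero vector satisfies the KKT
conditions, and the fitter returns beta = 0 identically there.
Convergence is declared when the largest coefficient change in an outer
iteration falls below 1e-7 (tests use down to 1e-9); IRLS weights are
floored at 1e-10. Deliberately **no** internal feature standardization
and **no** 1/n likelihood scaling are applied — the objective is exactly
the one above, so lambda lives on the scale of the summed log-likelihood
(cross-checks against scikit-survival's coxnet rescale lambda by n
accordingly).

Cross-validation scores each lambda by the partial log-likelihood of the
held-out fold under the train-fold coefficients. Two selection rules are
exposed: `min` (the maximizer of the mean held-out score — the default
for single fits) and `1se` (the largest lambda within one standard error
of the maximum, glmnet's familiar parsimony companion).

The selection-frequency protocol repeats, for each of `repeats` rounds
(default 100): reshuffle the folds (default 10), choose lambda by CV,
refit on all data at that lambda, and increment the count of every
feature with a nonzero coefficient — one increment per repeat, since
there is one refit per repeat. `top_k` (default 30) returns the most
frequent features, ties to the lower index. Inside this protocol the
`1se` rule is the default: with the `min` rule and a mostly-ridge penalty
(alpha = 0.2) the refit support is large and nearly identical across
repeats, so the binary frequencies saturate at the ceiling and the
ranking degenerates into tie-breaking; the parsimonious rule restores the
churn among null features that makes frequencies informative. Single
fits keep `min`.

The univariate stump classifier searches all midpoints of consecutive
sorted unique feature values (plus sentinels outside the range, so a
constant feature falls back to the majority class) over both directions,
maximizing training accuracy; ties go to the smaller threshold, then to
the `x > threshold -> high` direction.

## Evaluation

Kaplan-Meier curves use the product-limit estimator (backed by
lifelines), reporting survival probabilities at event times, risk-set
sizes, censoring marks and an at-risk table at caller-chosen ticks. The
two-group log-rank test uses the pooled-hypergeometric variance with 1
degree of freedom (also via lifelines; hand-computed product-limit values
and a direct observed-minus-expected summation serve as independent
oracles in the test suite), with 0.05 as the conventional significance
threshold.

The concordance index follows the directed-graph formulation: an edge
runs from patient i to patient j when i is uncensored and t_i < t_j
(edges only originate from uncensored patients; tied times give no
edge). An edge is concordant when r_i > r_j; tied risks count one half
(the standard Harrell convention — the strict definition leaves ties
unspecified). c = (concordant + 0.5 * ties) / edges; an empty graph is an
error, not a default value. Useful identities tested: c(r) + c(-r) = 1
without risk ties, and invariance under strictly monotone transforms of
r.

## Biomarker interpretation

Each patient-vector entry is one codebook cluster, hence a cell
phenotype. The module assigns cells to nearest codewords (ties to the
lower index), retrieves gallery cells for a feature ordered
nearest-to-codeword first, overlays the cells of the selected features on
the source image (all cells of the selected clusters are marked — circle
of NMS radius, color-coded by cluster), and computes class activation
maps CAM(x, y) = sum_k w_k map_k(x, y) from the GAP backend's head
weights, optionally min-max rescaled and bilinearly upsampled to patch
resolution.

## Synthetic data: what it emulates and what it does not

* **Images** — dark elliptical blobs (soft sigmoid edges, per-class mean
  radius/intensity/eccentricity) on a brighter, smoothly textured
  background with Gaussian pixel noise, loosely a hematoxylin channel at
  20X. Centers are placed by rejection sampling with a pairwise
  minimum-distance constraint (cap 10,000 attempts; a shortfall raises
  with the count placed). Morphology classes differ in size and
  intensity by construction so that descriptors are class-separable.
  Not modelled: staining variability, overlapping/clumped nuclei,
  stromal texture, compression artifacts — so detector scores here are
  an upper bound on real-slide behaviour, and passing tests show the
  machinery is correct, not that it transfers to H&E.
* **Descriptors** — isotropic Gaussian mixtures with controllably
  separated means; cluster labels returned for oracle checks.
* **Cohorts** — features standard normal; event times exponential with
  hazard `baseline_rate * exp(f' beta_true)` (default baseline 1/1000
  days, median survival ~2 years); censoring is an independent
  exponential whose rate is solved numerically (bisection on the closed-
  form observed-event probability) so the expected censored fraction hits
  the requested value, combined with administrative cut-off at
  `max_followup`. At beta_true = 0 the event times are exactly
  exponential, which the test suite verifies by Kolmogorov–Smirnov at
  the 1% level (P = 5000).

The end-to-end pipeline plants signal by giving each simulated patient a
latent fraction of "aggressive-morphology" cells (uniform on
[0.15, 0.85]); images are rendered with that class mixture and the
log-hazard is `effect_size` times the centered, rescaled fraction.
Recovering held-out concordance above chance therefore requires every
stage — detection, description, encoding, fitting — to preserve the
morphology-composition signal. With effect_size = 0 the images carry no
survival information and held-out concordance must return to chance,
which is checked over 20 survival re-simulations at fixed patient
vectors.

## Problem sizes and other fixed choices

Study sizes used by the test suite and examples are chosen once as
desk-scale analogues: detection uses 20 training + 5 held-out images of
144x144 px with 50 cells each (the smallest canvas that packs 50 centers
at pairwise distance >= 10); the selection-frequency study uses 63
patients (the size of the reference training cohort) with 2 strong
features among 64 over 20 repeats x 5 folds; the end-to-end study uses
60 patients, 40 cells per 128-px image, an M = 8 codebook and a 50/50
train/test split; oracle comparisons for the elastic net use P = 20,
M = 3 and sign-recovery uses 20 cohorts of P = 500. Time is measured in
days throughout; years convert at 365.25 days.

## Known limitations

* The reference detector and the fixed-filter GAP backend are desk-scale
  stand-ins for large pretrained networks; absolute descriptor quality on
  real tissue is out of scope, only the structural properties
  (translation tolerance, cluster separability) are exercised.
* Efron's tie correction, time-dependent covariates and multi-group
  (>2) log-rank tests are not implemented.
* The elastic-net fitter is dense and cyclic without active-set
  screening; it is comfortable to a few hundred features, not tens of
  thousands.
* `partition_by_threshold` can produce an empty group (flagged via the
  returned masks); downstream log-rank then raises rather than guessing.
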