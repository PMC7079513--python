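"""Aggregate per-cell descriptors into one patient-level vector.

Learns a k-means codebook from pooled cells, encodes each cell by hard
vector quantization (BoW) and by locality-constrained linear coding
(LLC, affine combination of the 5 nearest codewords), pools over cells
and l2-normalizes. Also shows the aggregate-statistic baseline
[mean; median; std] whose length is 3 x descriptor dimension.
"""

import numpy as np

from histosurv.encoding import (aggregate_statistic, encode_bow, encode_llc,
                                learn_codebook, pool)
from histosurv.synthetic import generate_descriptors

X, _ = generate_descriptors(n_cells=500, n_clusters=8, dim=32, noise_sd=0.3,
                            seed=0)
codebook = learn_codebook(X, M=16, seed=0)
print(f"codebook: {codebook.n_codewords} codewords, "
      f"k-means inertia {codebook.inertia:.1f}")

bow = encode_bow(X, codebook.B)
llc = encode_llc(X, codebook.B, k=5)
print(f"LLC column sums: {llc.C.sum(axis=0).min():.12f} .. "
      f"{llc.C.sum(axis=0).max():.12f}  (constraint: exactly 1)")

err_bow = np.linalg.norm(X - codebook.B @ bow.C)
err_llc = np.linalg.norm(X - codebook.B @ llc.C)
print(f"reconstruction error: BoW {err_bow:.2f}, LLC {err_llc:.2f} "
      "(LLC is never worse)")

for name, cm in [("bow-sum", bow), ("llc-sum", llc)]:
    f = pool(cm, mode="sum").f
    print(f"{name}: patient vector length {len(f)}, ||f||_2 = "
          f"{np.linalg.norm(f):.6f}")
f_max = pool(llc, mode="max").f
print(f"llc-max: first entries {np.round(f_max[:4], 3)}")

agg = aggregate_statistic(X)
print(f"aggregate statistic: length {len(agg.f)} (= 3 x {X.shape[0]})")
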