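"""Derive cell-type markers, build a signature, and deconvolve bulk mixtures.

Simulates negative-binomial counts for 4 replicated cell types with planted
16-fold markers, applies the four-fold marker rule (log2FC >= 2 and
p.adj < 0.05 against every other type), builds the mean-expression signature
matrix, then recovers mixing fractions of noisy synthetic bulk samples by
non-negative least squares.
"""

import numpy as np

import colxnet as cx
from colxnet.io import ExpressionMatrix, Unit

cfg = cx.SimConfig(seed=2)
counts, labels, truth = cx.simulate_celltype_counts(cfg)
norm, size_factors = cx.median_of_ratios_normalize(counts)

table = cx.define_celltype_markers(norm, labels)
print("markers per type:", {t: len(g) for t, g in table.markers.items()})
print("anchor gene is a BMSC marker:", table.is_marker("COL10A1", "BMSC"))

signature = cx.build_signature_matrix(norm, labels, table.markers)
print(f"signature matrix: {signature.shape[0]} marker genes x "
      f"{signature.shape[1]} cell types")

profiles = ExpressionMatrix(list(signature.index), list(signature.columns),
                            signature.to_numpy(), Unit.RSEM)
truth_fractions = np.random.default_rng(8).dirichlet(np.ones(4), 100)
bulk = cx.simulate_mixtures(profiles, truth_fractions,
                            noise_sd=0.1 * float(signature.to_numpy().mean()),
                            seed=8)
fractions = cx.impute_fractions(signature, bulk)
rel = fractions[[f"{t}_rel" for t in signature.columns]].to_numpy()
mae = np.abs(rel - truth_fractions).mean()
print(f"mean absolute error of recovered relative fractions: {mae:.4f} "
      "(at 10% noise; < 0.05 indicates reliable deconvolution)")
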