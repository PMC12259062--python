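"""Simulate raw paired RNA/ADT counts, QC-filter, and normalize.

Emits negative-binomial counts from a latent expression model, applies the
standard cell/gene filters, then library-size + log1p + z-transform for RNA
and per-cell centered log-ratio + z-transform for ADT.
"""

import numpy as np

from triomed import SimConfig, normalize_adt, normalize_rna, qc_filter, simulate_citeseq

ds, truth = simulate_citeseq(SimConfig(
    n_samples={"healthy": 3, "severe": 3}, cells_per_sample=80,
    n_ict=6, n_background=20, n_decoy_proteins=5,
    emission="negative_binomial", seed=0,
))
print(f"simulated: {ds.n_cells} cells x {len(ds.gene_names)} genes, "
      f"{len(ds.protein_names)} proteins (raw counts)")

filtered = qc_filter(ds, min_genes=10, min_cells=5, max_mito=0.05)
print(f"after QC:  {filtered.n_cells} cells x {len(filtered.gene_names)} genes")

normed = normalize_rna(filtered)
normed = normalize_adt(normed)
print(f"RNA layer: {normed.rna_layer}; per-gene mean/sd = "
      f"{normed.rna.to_numpy().mean():.2e} / {normed.rna.to_numpy().std(axis=0).mean():.3f}")

clr = normalize_adt(filtered, zscore=False)
print(f"CLR row sums (should be ~0): max |sum| = "
      f"{np.abs(clr.adt.sum(axis=1)).max():.2e}")
# Each cell's protein panel is compositional: tag counts compete for reads,
# so the CLR removes the per-cell depth component before z-scoring.
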