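"""Expand a surface-protein panel into analysis trios.

Loads the packaged example 30-protein ADT panel (CD3, HLA-DR and CD16 map
to 3, 3 and 6 subunit coding genes; the rest are single-subunit) and an
example intracellular-transport (ICT) gene list, then forms every
(protein, coding gene, ICT gene) trio measured in a given RNA matrix.
"""

from importlib import resources

from triomed import build_pairs, build_trios, load_ict_genes, load_protein_map

data = resources.files("triomed.data")
pmap = load_protein_map(data / "example_protein_map.tsv")
ict = load_ict_genes(data / "example_ict_genes.tsv")

pairs = build_pairs(pmap, list(pmap))
print(f"{len(pmap)} proteins -> {len(pairs)} protein-gene pairs "
      f"(multi-subunit: CD3 x3, HLA-DR x3, CD16 x6)")

# pretend the RNA matrix measured every ICT gene plus all coding genes
measured = sorted(ict | {g for _, g in pairs})
catalog = build_trios(pairs, ict, measured)
print(f"{len(ict)} ICT genes -> {len(catalog)} trios "
      f"(self-trios where the ICT gene IS the coding gene are excluded)")

selfless = build_trios(pairs, ict, measured, exclude_self=False)
print(f"without self-trio exclusion: {len(selfless)} "
      f"({len(selfless) - len(catalog)} self-collisions, e.g. TFRC for CD71)")
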