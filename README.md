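# triomed

Trio regression and mediation analysis of cell-surface protein regulation by
intracellular-transport (ICT) gene expression, for paired RNA/ADT (CITE-seq)
single-cell data.

## The problem

A cell's surface proteome is not a simple readout of transcription: a protein
can be over- or under-represented at the membrane while its coding gene's
mRNA is unchanged, because secretion, recycling and degradation are
controlled by a large machinery of intracellular-transport genes (ER→Golgi
trafficking, endocytosis, lysosomal routing).  CITE-seq measures both sides
in the same cell — transcriptome plus an antibody-derived-tag (ADT) panel of
surface proteins — which makes this post-transcriptional layer quantifiable.

`triomed` decomposes the question into **trios** (surface protein *m*, one
of its coding genes *g*, one ICT gene *t*) and runs a four-stage analysis:

1. **Trio regression.**  Within one phenotype group, a mixed-effects model

   `E_{m,c} = η₀ + η₁·X_{g,c} + η₂·X_{t,c} + Σζ·V + (1|s_c) + ε`

   with a per-sample random intercept (cells from one donor are not
   independent) tests, via a Wald z on η₂, whether the ICT gene predicts
   protein abundance beyond the coding gene's own transcription.  Trios
   significant at Benjamini–Hochberg FDR < 0.05 are *putative transport
   trios* (PTTs).

2. **Single-exposure mediation.**  Per PTT and a binary phenotype contrast
   D ∈ {0,1}:

   `E = φ₀ + α·X_t + ς` and `D = ω₀ + β·E + δ·X_t + ξ`

   giving direct effect δ, indirect effect α·β, and total δ + α·β (exactly
   the OLS(D ~ X_t) slope in the no-covariate case).  Genes with a
   significant indirect and/or direct effect (Sobel test, level 0.05) are
   disease-associated ICT (daICT) genes, classed full / partial / none.

3. **Regularized multi-exposure mediation.**  All strong exposures
   (|η₂| > 0.1) of one protein enter jointly, with the L1 penalty
   `λ·r^(1/4)·(Σ|α_t| + Σ|δ_t|)`; β and the intercepts are never
   penalized.  λ is selected by minimum BIC over a grid on [0.005, 0.03];
   the sparsity pattern at λ* classifies each gene (full / partial / null /
   dropped).

4. **Regulatory network.**  A signed directed acyclic graph over
   {ICT genes, coding gene, protein, phenotype}: full-mediation genes point
   at the protein, partial at protein and phenotype, null at the phenotype
   only; the protein→phenotype edge is always present.  Exported as
   GraphML, DOT or a TSV edge list.

A synthetic-data generator with planted effects (`triomed.simulate`) makes
every stage testable without external downloads.

## Worked example

`examples/` contains one short script per capability.  For instance, the
trio scan on a fixture that plants a single active ICT gene (η₂ = 1 on
`ICT000`, σ_u = 0.5, 8 samples × 100 cells):

```sh
$ python examples/03_ptt_scan.py
ict_gene   eta1    eta2      p    fdr  is_ptt  sigma_u2
  ICT000 0.5123  0.9409 0.0000 0.0000    True    0.3826
  ICT001 0.5208 -0.0352 0.4925 0.7470   False    0.3634
  ...
PTTs called: 1 (planted: ICT000 with eta2=1)
full vs reduced R^2 for the (PROT1, CODG1) pair: 0.150 vs 0.101
```

The planted trio is the only PTT; its η₂ estimate (0.94) recovers the unit
effect, the variance component (0.38) tracks the planted σ_u² = 0.25–0.4
range for this draw, and the full model explains more protein variance than
the reduced model without the ICT term.  The sparse path
(`examples/05_sparse_mediation_path.py`) shows BIC selecting a λ that keeps
the three planted exposures of twenty while β survives unpenalized.

The same workflow is available from a shell:

```sh
triomed simulate --fixture one-strong-trio --seed 1 --out run/data
triomed ptt --dataset run/data --catalog run/trios.tsv --group healthy --out run/ptt
triomed mediate-multi --dataset run/data --ptt-table run/ptt/ptt_table.tsv \
        --protein PROT1 --reference healthy --case severe --out run/multi
triomed network --classification run/multi/classification.tsv \
        --protein PROT1 --format graphml --out run/net.graphml
```

## Layout

```
src/triomed/      library (dataset, io, preprocess, de, trios, ptt,
                  mediation, sparse_mediation, network, simulate, cli)
examples/         narrative scripts, one per capability
tests/            pytest suite incl. statistical acceptance checks
scripts/          acceptance.py
docs/methods.md   modeling assumptions, defaults, numerical choices
```
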