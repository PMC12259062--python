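# Methods

## Data model and preprocessing

A `CiteSeqDataset` holds a cells × genes RNA matrix and a cells × proteins
ADT matrix in identical cell order, with per-cell metadata (`sample_id`,
`phenotype`, optional numeric covariates).  Phenotype labels map to numeric
codes (alphabetical 0, 1, … unless supplied).

QC applies three filters **in a fixed order**: cells with fewer than
`min_genes` (default 100) detected genes, then genes detected in fewer than
`min_cells` (default 5) of the *surviving* cells, then cells whose
mitochondrial count fraction (genes matching the `MT-` prefix, configurable)
exceeds `max_mito` (default 5%).  All three thresholds are strict
("fewer than" / "over"), so a cell with exactly 100 genes or exactly 5%
mitochondrial counts is retained.  The order matters — the gene filter
changes the denominator of the mitochondrial fraction — and is
regression-tested rather than assumed interchangeable.

RNA normalization is library-size scaling to 10,000 counts per cell +
`log1p`, then a per-gene z-transform across all cells.  The scale factor is
the de-facto convention of the standard single-cell toolchain; it is
configurable.  Genes that are constant after the log step (up to a 1e-12
relative tolerance) are set to zero and recorded in
`zero_variance_genes` rather than dropped, so matrix shapes stay stable.

ADT normalization is the centered log-ratio, computed **within each cell
across proteins** with pseudocount +1: the tag counts of a small panel
compete for per-cell sequencing depth and are therefore compositional.  A
per-protein margin is available as an alternative for comparison.  A
per-protein z-transform follows.  Z-transformation is computed on the whole
dataset, not per phenotype group; per-group analyses subset cells *after*
normalization (a per-group flag exists for the alternative order, which the
data format cannot itself decide).

Differential tests (proteins → DEPs, genes → DEGs) use the two-sided
Wilcoxon rank-sum test with BH adjustment across tested features
(significance at FDR < 0.05).  Groups of ≤ 50 cells without ties use the
exact null distribution; otherwise the normal approximation with tie
correction.

## Trio catalog

Trios are the cartesian product of (protein, subunit coding gene) pairs
with the ICT genes present in the RNA matrix.  Multi-subunit proteins
contribute one pair per subunit (the packaged example panel maps CD3 to
CD3D/CD3G/CD3E, HLA-DR to HLA-DRA/DRB1/DRB5, CD16 to the six FCGR genes; 30
proteins → 39 pairs).  Self-trios — an ICT-annotated gene paired with
itself as coding gene (e.g. TFRC for CD71) — are excluded by default, on
the grounds that a gene should not be modeled as its own transport
regulator; the flag `exclude_self=False` restores them.  Gene symbols match
case-sensitively by default with optional uppercase normalization.

## Trio regression (mixed model)

Per trio and phenotype group, `E ~ 1 + X_g + X_t + V + (1|sample)` is fitted
by **restricted maximum likelihood** (statsmodels `MixedLM`).  The p-value
on η₂ is a Wald z-test; REML degrees-of-freedom corrections
(Satterthwaite-style) are deliberately not the default since group sizes in
this design are hundreds of cells.  Numerical details:

- The optimizer retries (default, then Powell, then Nelder–Mead) and keeps
  the converged candidate with the best restricted likelihood; MixedLM's
  quasi-Newton path occasionally stalls on a spurious boundary iterate with
  the variance component exactly zero.
- If the fitted σ_u² is at (numerical) zero, the fixed effects and their
  standard errors are recomputed by OLS — the exact GLS limit at σ_u² = 0.
- Constant predictors within a group raise a "degenerate predictor" error;
  groups need ≥ 2 samples.
- Non-convergent or singular fits stay in the output with
  `converged=False` but are **excluded from the BH family**: an invalid
  p-value would distort the FDR of valid ones.  Counts are reported.

R² is the squared Pearson correlation between observed values and fitted
values *including* the predicted sample intercepts (a conditional R²);
this choice is a package convention where marginal and conditional versions
are both defensible.

The full-vs-reduced comparison aggregates, per (protein, coding gene) pair,
the maximum η₁, the minimum p(η₁) and the mean R² across the pair's trios,
against the reduced model `E ~ 1 + X_g + V + (1|sample)`.  The compared
p-value is p(η₁) in both models — the reduced model has no η₂ — keeping
the paired comparison on the same coefficient.

## Single-exposure mediation

Two OLS regressions on the cells of a two-group contrast (reference coded
0, case 1): `E ~ X_t` and `D ~ E + X_t`.  The outcome equation is linear
despite binary D (a linear-probability reading with Gaussian errors); this
is what makes the decomposition `total = δ + α·β` exact and equal to the
OLS(D ~ X_t) slope.  A logistic outcome option is intentionally absent from
the default path because the identity fails there.  The indirect-effect
p-value is the Sobel delta-method test,
`se = sqrt(α²·se(β)² + β²·se(α)²)`, with a seeded percentile bootstrap
(default 999 resamples) as an option; in well-powered simulations the two
agree in their rejection decision.  No random effects enter here or in the
multi-exposure model — the sample structure is absorbed in the trio
regression stage only.  Module-level p-values are used at level 0.05
without multiplicity adjustment by default (BH is available via
`bh_adjust`), matching the convention that daICT calling is a screening
step.

Classification: **full** if only the indirect effect is significant,
**partial** if both, **none** if only the direct, otherwise not daICT.
When scanning a PTT table the (protein, ICT gene) keys are deduplicated —
the mediator equation does not involve the coding gene, so trios differing
only in subunit gene give the same model.  When two groups both contribute
PTT sets, the default seeding is their union.

## Regularized multi-exposure mediation

Exposures and the mediator are z-scored so λ is scale-free; coefficients
are reported on the standardized scale.  The objective is

    (1/2n)‖E − φ₀ − Xα‖² + (1/2n)‖D − ω₀ − Xδ − βE‖²
        + λ·w(1,r)·(Σ|α_t| + Σ|δ_t|),   w(1,r) = r^(1/4)

with β and the intercepts unpenalized.  Because the two squared-error terms
share no parameters, the joint minimizer is exactly the combination of two
independently penalized least-squares problems; both the decoupled and an
interleaved joint coordinate-descent path are implemented and tested to
agree to 1e-10.  The solver is cyclic coordinate descent with
soft-thresholding on centered data (convergence when the largest
coefficient update is < 1e-7, cap 10⁴ sweeps; a debug flag asserts the
objective never increases within a sweep).  At λ = 0 it reproduces OLS; at
large λ every penalized coefficient is exactly zero while β reduces to the
simple mediator-outcome slope.

The λ grid defaults to 11 evenly spaced points on [0.005, 0.03]
(configurable), swept ascending with warm starts.  Model selection is by

    BIC = n·log(RSS_mediator/n) + n·log(RSS_outcome/n) + k·log(n),

k = (#nonzero penalized coefficients) + 3, using the standard lasso
degrees-of-freedom result (nonzero count).  Ties break toward the smaller
λ, preserving candidates for the module comparison.  The nonzero count is
expected to be non-increasing in λ and is monitored (logged, not raised —
warm starts plus finite tolerance can produce harmless inversions on
near-tied data).  No debiasing refit is performed on the selected support
by default (a refit flag is future work); classification reads the sparsity
pattern directly: full (α_t·β ≠ 0, δ_t = 0), partial (both nonzero), null
(only δ_t ≠ 0), dropped (both zero).  The regularized fit deliberately
carries no p-values.

The Module II / Module III comparison cross-tabulates per-gene classes
(rows: single-exposure; columns: regularized; NA for genes present in only
one analysis) and summarizes |α·β| and |δ| from the single-exposure fits
for genes retained vs dropped by the penalty.

## Network construction

One protein, one contrast: nodes are typed; the protein→phenotype edge is
always drawn (weight β).  Full-mediation genes get gene→protein (weight
α_t); partial get both gene→protein and gene→phenotype (δ_t); null only
gene→phenotype; dropped genes are omitted entirely.  The coding gene enters
with gene→protein (weight η₁) only when flagged significant (trio model or
differential expression).  Signs and the red/blue color attribute follow
coefficient signs.  The rules admit no cycles; acyclicity is asserted.
Exports: GraphML and TSV edge lists round-trip losslessly; DOT is
write-only.

## Synthetic data

The generator emulates the generative assumptions of the modeling stack —
standard-normal latent expression, a Gaussian sample random intercept on
protein abundance, linear links — not the full texture of real scRNA-seq
(no dropout, no library-size gradients beyond the optional
negative-binomial emission with dispersion 0.5, i.e. var = μ + 0.5μ²).
Passing tests therefore demonstrate correctness of the estimators under
their own assumptions, calibration of the tests, and recovery of planted
structure; they do not certify behavior under real-data artifacts such as
ambient contamination or cell-type mixture.

Binary phenotypes are assigned at the **sample** level (as in a multi-donor
study) with effect sizes realized as group shifts in the exposure and
protein channels; exact coefficient recovery is only well-posed in the
`continuous_latent` mode, where D = ω₀ + Σδ_t·X_t + β·E + ξ is emitted
per cell, and that mode is what the solver-recovery tests use.

Registered fixtures (deterministic in name + seed):

- `tiny-null` — 2×2 samples × 50 cells, no planted effects.
- `one-strong-trio` — 8 samples × 100 cells, one η₂ = 1 trio among ten
  ICT genes, σ_u = 0.5.
- `sparse-mediation-20` — 8 samples × 250 cells (n = 2000), 20 exposures
  of which 3 are active (α = 0.5, δ = 0.4, β = 0.5), continuous outcome.

Simulation sizes elsewhere (500 null replicates at 6 samples × 100 cells
for calibration; 200 replicates at 8 × 150 for coverage; 50 seeds of the
20-exposure fixture for support recovery) were chosen as the smallest
designs at which the Monte-Carlo error is comfortably inside the asserted
bands.

## Known limitations

- Mediation stages ignore the sample hierarchy; with few samples and strong
  donor effects, per-cell p-values there are anti-conservative.
- The L1 penalty can drop weak-but-real exposures; the module comparison
  table is the intended recovery aid.
- The linear-probability outcome model can predict outside [0, 1]; it is
  kept for the exactness of the effect decomposition.
- WNN clustering, cell-type annotation, batch correction and enrichment
  analysis are upstream/downstream of this package: cells arrive
  pre-labeled, and gene lists leave as plain TSV.
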