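"""Quality control and normalization for paired RNA/ADT matrices.

QC removes, in this fixed order: (1) cells with fewer than ``min_genes``
detected genes, (2) genes detected in fewer than ``min_cells`` of the
remaining cells, (3) cells whose mitochondrial count fraction exceeds
``max_mito``.  The order matters (the gene filter changes which counts the
mitochondrial fraction sees) and is regression-tested.

RNA normalization is library-size scaling to ``scale_factor`` + log1p, then a
per-gene z-transform.  ADT normalization is the centered log-ratio (CLR)
within each cell across proteins — ADT panels are compositional: tag counts
compete for sequencing depth within a cell — then a per-protein z-transform.
"""

from __future__ import annotations

import numpy as np

from .dataset import CiteSeqDataset, DatasetError, _as_float

__all__ = ["qc_filter", "normalize_rna", "normalize_adt", "zscore_columns"]


def _require_counts(ds: CiteSeqDataset, layer_attr: str) -> None:
    if getattr(ds, layer_attr) != "counts":
        raise DatasetError(f"expected raw counts, got layer {getattr(ds, layer_attr)!r}")


def qc_filter(
    ds: CiteSeqDataset,
    min_genes: int = 100,
    min_cells: int = 5,
    max_mito: float = 0.05,
    mito_prefix: str = "MT-",
) -> CiteSeqDataset:
    """Apply the three standard cell/gene filters, in order.

    A cell with exactly ``min_genes`` detected genes is retained (the
    threshold is "fewer than"), a gene present in exactly ``min_cells``
    cells is retained, and a cell at exactly ``max_mito`` mitochondrial
    fraction is retained (the threshold is "over").
    """
    _require_counts(ds, "rna_layer")
    rna = ds.rna

    detected = (rna > 0).sum(axis=1)
    cell_mask = (detected >= min_genes).to_numpy()
    if not cell_mask.any():
        raise DatasetError("all cells removed by the detected-gene filter")
    ds = ds.subset_cells(cell_mask)

    per_gene = (ds.rna > 0).sum(axis=0)
    gene_mask = per_gene >= min_cells
    rna = ds.rna.loc[:, gene_mask]

    mito_cols = [g for g in rna.columns if g.startswith(mito_prefix)]
    totals = rna.sum(axis=1)
    if len(mito_cols):
        frac = rna[mito_cols].sum(axis=1) / totals.replace(0, np.nan)
        frac = frac.fillna(0.0)
    else:
        frac = totals * 0.0
    keep = (frac <= max_mito).to_numpy()
    if not keep.any():
        raise DatasetError("all cells removed by the mitochondrial filter")

    from dataclasses import replace

    return replace(
        ds,
        rna=rna.loc[keep],
        adt=ds.adt.loc[keep],
        obs=ds.obs.loc[keep],
    )


def zscore_columns(values: np.ndarray, tol: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Z-transform columns; (numerically) constant columns become all-zero.

    Returns the transformed array and a boolean mask of constant columns;
    constancy is judged relative to the column mean so that values equal up
    to floating-point rounding count as constant.
    """
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    constant = sd <= tol * np.maximum(1.0, np.abs(mu))
    sd_safe = np.where(constant, 1.0, sd)
    out = (values - mu) / sd_safe
    out[:, constant] = 0.0
    return out, constant


def normalize_rna(ds: CiteSeqDataset, scale_factor: float = 10_000.0, zscore: bool = True) -> CiteSeqDataset:
    """Library-size normalize + log1p, then per-gene z-transform.

    Per cell: counts / total * scale_factor, then log1p.  Genes constant
    across cells after the log step are zeroed and recorded in
    ``zero_variance_genes``.
    """
    _require_counts(ds, "rna_layer")
    counts = _as_float(ds.rna).to_numpy()
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = int((totals == 0).sum())
        raise DatasetError(f"{bad} cells have zero total RNA counts; run qc_filter first")
    lognorm = np.log1p(counts / totals[:, None] * scale_factor)
    flagged: list[str] = []
    if zscore:
        lognorm, constant = zscore_columns(lognorm)
        flagged = [g for g, c in zip(ds.rna.columns, constant) if c]

    from dataclasses import replace

    rna = ds.rna.copy()
    rna.iloc[:, :] = lognorm
    return replace(ds, rna=rna, rna_layer="normalized", zero_variance_genes=flagged)


def normalize_adt(ds: CiteSeqDataset, zscore: bool = True, margin: str = "cell") -> CiteSeqDataset:
    """Centered log-ratio transform of ADT counts, then per-protein z-transform.

    ``margin="cell"`` (default) centers log1p(counts) within each cell
    across proteins; ``margin="protein"`` centers within each protein
    across cells (the alternative convention, provided for comparison).
    With ``zscore=False`` the returned layer tag is ``"clr"`` and per-cell
    CLR values sum to zero exactly.
    """
    _require_counts(ds, "adt_layer")
    counts = _as_float(ds.adt).to_numpy()
    logc = np.log1p(counts)
    if margin == "cell":
        clr = logc - logc.mean(axis=1, keepdims=True)
    elif margin == "protein":
        clr = logc - logc.mean(axis=0, keepdims=True)
    else:
        raise DatasetError(f"unknown CLR margin {margin!r}")
    layer = "clr"
    if zscore:
        clr, _ = zscore_columns(clr)
        layer = "normalized"

    from dataclasses import replace

    adt = ds.adt.copy()
    adt.iloc[:, :] = clr
    return replace(ds, adt=adt, adt_layer=layer)
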