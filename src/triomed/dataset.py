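"""Paired RNA/ADT single-cell dataset container.

A CITE-seq experiment measures, in each cell, the whole transcriptome (RNA
counts) and a panel of surface proteins via antibody-derived tags (ADT
counts).  :class:`CiteSeqDataset` keeps the two modalities row-aligned with a
per-cell metadata table carrying the sample of origin (cells from one donor
are not independent), a phenotype label, and optional numeric covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

REQUIRED_METADATA_COLUMNS = ("sample_id", "phenotype")


class DatasetError(ValueError):
    """Raised when a dataset violates its structural invariants."""


@dataclass
class CiteSeqDataset:
    """Row-aligned RNA and ADT matrices plus per-cell metadata.

    Parameters
    ----------
    rna
        Cells x genes matrix.  Raw counts or normalized values; the
        ``rna_layer`` tag records which.
    adt
        Cells x proteins matrix, same cell order as ``rna``.
    obs
        Per-cell metadata indexed by cell id with at least ``sample_id``
        and ``phenotype`` columns; any additional numeric columns are
        available as model covariates.
    rna_layer, adt_layer
        One of ``"counts"``, ``"normalized"`` or ``"clr"`` describing the
        current state of each matrix.
    phenotype_codes
        Mapping from phenotype label to a numeric code used by downstream
        models.  Defaults to alphabetical 0, 1, 2, ...
    zero_variance_genes
        Genes whose values were constant at normalization time and were
        zeroed out (flagged rather than dropped).
    """

    rna: pd.DataFrame
    adt: pd.DataFrame
    obs: pd.DataFrame
    rna_layer: str = "counts"
    adt_layer: str = "counts"
    phenotype_codes: dict[str, int] = field(default_factory=dict)
    zero_variance_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.phenotype_codes:
            labels = sorted(pd.unique(self.obs["phenotype"].astype(str)))
            self.phenotype_codes = {lab: i for i, lab in enumerate(labels)}
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        for col in REQUIRED_METADATA_COLUMNS:
            if col not in self.obs.columns:
                raise DatasetError(f"metadata missing required column {col!r}")
        if not (self.rna.index.equals(self.adt.index) and self.rna.index.equals(self.obs.index)):
            raise DatasetError("rna, adt and obs must share an identical cell ordering")
        if self.rna.index.has_duplicates:
            raise DatasetError("duplicate cell ids")
        if self.rna.columns.has_duplicates:
            raise DatasetError("duplicate gene names")
        if self.adt.columns.has_duplicates:
            raise DatasetError("duplicate protein names")
        sample = self.obs["sample_id"].astype(str)
        if (sample.str.len() == 0).any() or sample.isna().any():
            raise DatasetError("sample_id must be non-empty for every cell")
        labels = set(self.obs["phenotype"].astype(str))
        missing = labels - set(self.phenotype_codes)
        if missing:
            raise DatasetError(f"phenotype labels without numeric codes: {sorted(missing)}")
        codes = [self.phenotype_codes[lab] for lab in labels]
        if len(set(codes)) != len(codes):
            raise DatasetError("phenotype codes must be distinct per label")

    # ------------------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.rna.shape[0]

    @property
    def gene_names(self) -> list[str]:
        return list(self.rna.columns)

    @property
    def protein_names(self) -> list[str]:
        return list(self.adt.columns)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.rna.index)

    @property
    def covariate_names(self) -> list[str]:
        """Numeric metadata columns other than the required ones."""
        out = []
        for col in self.obs.columns:
            if col in REQUIRED_METADATA_COLUMNS:
                continue
            if pd.api.types.is_numeric_dtype(self.obs[col]):
                out.append(col)
        return out

    def phenotype_numeric(self) -> pd.Series:
        return self.obs["phenotype"].astype(str).map(self.phenotype_codes)

    def subset_cells(self, mask) -> "CiteSeqDataset":
        """Return a dataset restricted to the cells selected by ``mask``."""
        return replace(
            self,
            rna=self.rna.loc[mask],
            adt=self.adt.loc[mask],
            obs=self.obs.loc[mask],
        )

    def subset_phenotype(self, *labels: str) -> "CiteSeqDataset":
        mask = self.obs["phenotype"].astype(str).isin([str(l) for l in labels])
        if not mask.any():
            raise DatasetError(f"no cells with phenotype in {labels}")
        return self.subset_cells(mask.to_numpy())

    def to_anndata(self):
        """Export as an :class:`anndata.AnnData` with ADT in ``obsm['protein']``."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.rna.to_numpy(dtype=float),
            obs=self.obs.copy(),
            var=pd.DataFrame(index=self.rna.columns),
        )
        adata.obsm["protein"] = self.adt.to_numpy(dtype=float)
        adata.uns["protein_names"] = list(self.adt.columns)
        adata.uns["rna_layer"] = self.rna_layer
        adata.uns["adt_layer"] = self.adt_layer
        return adata


def _as_float(df: pd.DataFrame) -> pd.DataFrame:
    return df.astype(np.float64, copy=False)
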