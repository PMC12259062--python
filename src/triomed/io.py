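"""Readers and writers for paired RNA/ADT matrices and cell metadata.

Two on-disk encodings are supported for each modality:

``mtx``
    A directory with ``matrix.mtx`` (Matrix Market triplet, features x cells,
    the 10x convention), ``features.tsv`` (one feature name per line) and
    ``barcodes.tsv`` (one cell id per line).
``tsv``
    A dense table, cells in rows (first column ``cell_id``), features in
    columns.

Metadata is a TSV with required columns ``cell_id``, ``sample_id``,
``phenotype``; any extra numeric columns become model covariates.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .dataset import CiteSeqDataset, DatasetError

__all__ = ["load_citeseq", "write_citeseq", "read_matrix", "write_matrix"]


def _detect_format(path: str | os.PathLike) -> str:
    p = Path(path)
    if p.is_dir():
        return "mtx"
    if p.suffix in {".tsv", ".txt", ".csv"}:
        return "tsv"
    raise DatasetError(f"unknown format for {path!s}; expected an MTX directory or a .tsv file")


def read_matrix(path: str | os.PathLike, format: str = "infer") -> pd.DataFrame:
    """Read one modality into a cells x features DataFrame."""
    if format == "infer":
        format = _detect_format(path)
    if format == "mtx":
        d = Path(path)
        mat = scipy.io.mmread(d / "matrix.mtx")
        features = pd.read_csv(d / "features.tsv", header=None, sep="\t")[0].astype(str)
        barcodes = pd.read_csv(d / "barcodes.tsv", header=None, sep="\t")[0].astype(str)
        dense = np.asarray(scipy.sparse.coo_matrix(mat).todense(), dtype=float)
        if dense.shape != (len(features), len(barcodes)):
            raise DatasetError(
                f"dimension mismatch in {path!s}: matrix is {dense.shape}, "
                f"features={len(features)}, barcodes={len(barcodes)}"
            )
        df = pd.DataFrame(dense.T, index=barcodes, columns=features)
        df.index.name = None
        df.columns.name = None
        return df
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str).rename(None)
        df.columns = df.columns.astype(str).rename(None)
        return df.astype(float)
    raise DatasetError(f"unknown format {format!r}")


def write_matrix(df: pd.DataFrame, path: str | os.PathLike, format: str) -> None:
    if format == "mtx":
        d = Path(path)
        d.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(d / "matrix.mtx"), scipy.sparse.csr_matrix(df.to_numpy().T))
        pd.Series(df.columns).to_csv(d / "features.tsv", sep="\t", header=False, index=False)
        pd.Series(df.index).to_csv(d / "barcodes.tsv", sep="\t", header=False, index=False)
    elif format == "tsv":
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        out = df.copy()
        out.index.name = "cell_id"
        out.to_csv(path, sep="\t")
    else:
        raise DatasetError(f"unknown format {format!r}")


def load_citeseq(
    rna_path: str | os.PathLike,
    adt_path: str | os.PathLike,
    metadata_path: str | os.PathLike,
    format: str = "infer",
    rna_layer: str = "counts",
    adt_layer: str = "counts",
    phenotype_codes: dict[str, int] | None = None,
) -> CiteSeqDataset:
    """Load and align RNA, ADT and metadata into one dataset.

    Cell order follows the RNA matrix; the ADT matrix and metadata are
    reindexed to it.  Cells present in the matrices but absent from the
    metadata are an error (unannotated cells), as are RNA/ADT cell-set
    mismatches.
    """
    rna = read_matrix(rna_path, format)
    adt = read_matrix(adt_path, format)

    if set(rna.index) != set(adt.index):
        raise DatasetError(
            f"dimension mismatch: RNA has {rna.shape[0]} cells, ADT has {adt.shape[0]}; "
            "cell id sets differ"
        )
    adt = adt.loc[rna.index]

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"cell_id": str, "sample_id": str})
    if "cell_id" not in meta.columns:
        raise DatasetError("metadata missing required column 'cell_id'")
    if meta["cell_id"].duplicated().any():
        raise DatasetError("duplicate cell ids in metadata")
    meta = meta.set_index("cell_id")
    missing = rna.index.difference(meta.index)
    if len(missing):
        raise DatasetError(f"unannotated cells: {len(missing)} cells missing from metadata "
                           f"(first: {missing[0]})")
    obs = meta.loc[rna.index]

    return CiteSeqDataset(
        rna=rna, adt=adt, obs=obs,
        rna_layer=rna_layer, adt_layer=adt_layer,
        phenotype_codes=dict(phenotype_codes) if phenotype_codes else {},
    )


def write_citeseq(ds: CiteSeqDataset, out_dir: str | os.PathLike, format: str = "tsv") -> dict[str, str]:
    """Write a dataset to ``out_dir``; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if format == "mtx":
        rna_path, adt_path = out / "rna", out / "adt"
    elif format == "tsv":
        rna_path, adt_path = out / "rna.tsv", out / "adt.tsv"
    else:
        raise DatasetError(f"unknown format {format!r}")
    write_matrix(ds.rna, rna_path, format)
    write_matrix(ds.adt, adt_path, format)
    meta = ds.obs.copy()
    meta.index.name = "cell_id"
    meta_path = out / "metadata.tsv"
    meta.to_csv(meta_path, sep="\t")
    return {"rna": str(rna_path), "adt": str(adt_path), "metadata": str(meta_path)}
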