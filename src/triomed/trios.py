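"""Trio catalog construction.

The unit of analysis is a *trio*: a surface protein ``m``, one of its coding
(subunit) genes ``g``, and an intracellular-transport (ICT) gene ``t``.
Multi-subunit proteins contribute one (protein, gene) pair per subunit —
e.g. CD3 maps to CD3D/CD3G/CD3E, HLA-DR to HLA-DRA/DRB1/DRB5 and CD16 to the
six FCGR genes — and the catalog is the cartesian product of these pairs with
the ICT genes measured in the RNA matrix, minus self-trios (``t == g``) by
default: a coding gene that happens to carry transport annotation should not
be modeled as its own transport regulator.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "Trio",
    "TrioCatalog",
    "load_ict_genes",
    "load_protein_map",
    "build_pairs",
    "build_trios",
]


class TrioError(ValueError):
    pass


@dataclass(frozen=True)
class Trio:
    protein: str
    coding_gene: str
    ict_gene: str


@dataclass
class TrioCatalog:
    trios: list[Trio]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.trios)) != len(self.trios):
            raise TrioError("duplicate trios in catalog")

    def __len__(self) -> int:
        return len(self.trios)

    def __iter__(self):
        return iter(self.trios)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t.protein, t.coding_gene, t.ict_gene) for t in self.trios],
            columns=["protein", "coding_gene", "ict_gene"],
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def proteins(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trios:
            seen.setdefault(t.protein)
        return list(seen)


def _file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def load_ict_genes(path, column: str = "gene_symbol", uppercase: bool = False) -> set[str]:
    """Load the ICT gene list from a TSV; deduplicated.

    ``uppercase=True`` normalizes symbol case (off by default: HGNC symbols
    are case-sensitive in principle).
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[0] == 0:
        raise TrioError(f"empty ICT gene list: {path}")
    if column not in df.columns:
        if df.shape[1] == 1:
            column = df.columns[0]
        else:
            raise TrioError(f"ICT list {path} has no column {column!r}")
    genes = df[column].astype(str)
    if uppercase:
        genes = genes.str.upper()
    return set(genes)


def load_protein_map(path) -> dict[str, list[str]]:
    """Load the protein -> coding-gene (subunit) map.

    TSV with columns ``protein`` and ``gene_symbol``, one row per subunit;
    row order defines subunit order.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("protein", "gene_symbol"):
        if col not in df.columns:
            raise TrioError(f"protein map {path} missing column {col!r}")
    out: dict[str, list[str]] = {}
    for prot, gene in zip(df["protein"].astype(str), df["gene_symbol"].astype(str)):
        genes = out.setdefault(prot, [])
        if gene in genes:
            raise TrioError(f"duplicate subunit gene {gene} for protein {prot}")
        genes.append(gene)
    return out


def build_pairs(protein_map: dict[str, list[str]], measured_proteins: list[str]) -> list[tuple[str, str]]:
    """One (protein, coding gene) pair per measured protein subunit."""
    pairs = []
    for m in measured_proteins:
        if m not in protein_map:
            raise TrioError(f"protein {m!r} missing from the protein-gene map")
        genes = protein_map[m]
        if not genes:
            raise TrioError(f"protein {m!r} has no coding genes in the map")
        pairs.extend((m, g) for g in genes)
    return pairs


def build_trios(
    pairs: list[tuple[str, str]],
    ict_genes: set[str],
    rna_gene_names: list[str] | set[str],
    exclude_self: bool = True,
    provenance: dict[str, str] | None = None,
) -> TrioCatalog:
    """Cartesian product of pairs with the measured ICT genes.

    ICT genes absent from the RNA matrix are dropped before the product;
    with ``exclude_self`` trios whose ICT gene equals the coding gene are
    removed.
    """
    usable = sorted(ict_genes & set(rna_gene_names))
    trios = [
        Trio(m, g, t)
        for (m, g) in pairs
        for t in usable
        if not (exclude_self and t == g)
    ]
    if not trios:
        warnings.warn("trio catalog is empty", stacklevel=2)
    return TrioCatalog(trios, provenance=dict(provenance or {}))
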