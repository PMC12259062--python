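"""Signed directed regulatory network for one surface protein and phenotype.

Nodes are typed (ICT gene, coding gene, protein, phenotype).  The protein and
the phenotype are always connected (the network is only built for proteins
associated with the phenotype).  Mediation classes determine the ICT edges:
full -> gene-to-protein; partial -> gene-to-protein and gene-to-phenotype;
null -> gene-to-phenotype; dropped genes are omitted.  The coding gene enters
with an edge to the protein only if its transcription was significantly
associated with protein abundance in the trio model or it is differentially
expressed.  Edge signs follow coefficient signs (red = positive,
blue = negative in the exported color attribute); weights are the
standardized coefficients of the model that defined the edge.  The graph is
acyclic by construction.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .dataset import DatasetError

__all__ = ["build_network", "export_network", "read_edge_list", "expected_edge_count"]

PHENOTYPE_NODE = "phenotype"


def _sign(x: float) -> str:
    return "+" if x >= 0 else "-"


def _color(x: float) -> str:
    return "red" if x >= 0 else "blue"


def _add_edge(net: nx.DiGraph, u: str, v: str, weight: float, provenance: str) -> None:
    net.add_edge(u, v, weight=float(weight), sign=_sign(weight),
                 color=_color(weight), provenance=provenance)


def build_network(
    protein: str,
    classification_table: pd.DataFrame | None,
    beta: float | None = None,
    coding_gene_stats: dict | None = None,
    contrast: str = "",
    phenotype_label: str = PHENOTYPE_NODE,
) -> nx.DiGraph:
    """Assemble the directed graph for one protein and one contrast.

    ``classification_table`` needs columns ``ict_gene``, ``class``,
    ``alpha``, ``delta`` and (if ``beta`` is not given) ``beta``.
    ``coding_gene_stats`` is ``{"gene": ..., "eta1": ..., "significant": bool}``;
    the coding-gene edge is drawn only when ``significant`` is true.
    """
    net = nx.DiGraph(protein=protein, contrast=contrast)
    net.add_node(protein, node_type="protein")
    net.add_node(phenotype_label, node_type="phenotype")

    empty = classification_table is None or len(classification_table) == 0
    if beta is None:
        if empty:
            beta = 0.0
        elif "beta" not in classification_table.columns:
            raise DatasetError("beta not provided and absent from classification table")
        else:
            beta = float(classification_table["beta"].iloc[0])
    _add_edge(net, protein, phenotype_label, beta, "beta")

    rows = [] if empty else classification_table.to_dict("records")
    for row in rows:
        cls = row["class"]
        gene = row["ict_gene"]
        alpha = float(row["alpha"])
        delta = float(row["delta"])
        if cls == "dropped" or cls == "not_daICT":
            continue
        net.add_node(gene, node_type="ict_gene", mediation=cls)
        if cls in ("full", "partial"):
            _add_edge(net, gene, protein, alpha, "alpha")
        if cls in ("partial", "null", "none"):
            _add_edge(net, gene, phenotype_label, delta, "delta")

    if coding_gene_stats and coding_gene_stats.get("significant"):
        g = coding_gene_stats["gene"]
        net.add_node(g, node_type="coding_gene")
        _add_edge(net, g, protein, float(coding_gene_stats.get("eta1", 0.0)), "eta1")

    assert nx.is_directed_acyclic_graph(net)
    return net


def expected_edge_count(n_full: int, n_partial: int, n_null: int, coding_edge: bool = False) -> int:
    """Edge-count identity: full + 2*partial + null + protein->phenotype (+ coding)."""
    return n_full + 2 * n_partial + n_null + 1 + int(coding_edge)


def export_network(net: nx.DiGraph, path, format: str = "tsv") -> str:
    """Write the network as GraphML, DOT, or a TSV edge list."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "dot":
        lines = ["digraph regulatory {"]
        for node, attrs in net.nodes(data=True):
            lines.append(f'  "{node}" [node_type="{attrs.get("node_type", "")}"];')
        for u, v, attrs in net.edges(data=True):
            lines.append(
                f'  "{u}" -> "{v}" [color={attrs["color"]}, weight={attrs["weight"]:.6g}, '
                f'label="{attrs["provenance"]}"];'
            )
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "tsv":
        rows = [
            (u, v, a["sign"], a["weight"], a["provenance"],
             net.nodes[u].get("node_type", ""), net.nodes[v].get("node_type", ""))
            for u, v, a in net.edges(data=True)
        ]
        pd.DataFrame(rows, columns=[
            "source", "target", "sign", "weight", "provenance",
            "source_type", "target_type",
        ]).to_csv(path, sep="\t", index=False)
    else:
        raise DatasetError(f"unknown export format {format!r}")
    return str(path)


def read_edge_list(path) -> nx.DiGraph:
    """Read back a TSV edge list written by :func:`export_network`."""
    df = pd.read_csv(path, sep="\t")
    net = nx.DiGraph()
    for row in df.itertuples(index=False):
        net.add_node(row.source, node_type=row.source_type)
        net.add_node(row.target, node_type=row.target_type)
        net.add_edge(row.source, row.target, weight=float(row.weight),
                     sign=row.sign, color=_color(float(row.weight)),
                     provenance=row.provenance)
    return net
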