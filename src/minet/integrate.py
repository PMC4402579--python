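"""Rule-based integration of the evidence networks.

The integrated network is a typed multigraph over miRNA and gene nodes.
Assembly starts from the union of the seed eQTLs, the miRNA-target
interactions and the selected PPI expansion edges; the multitask model's
correlation subnetworks and eQTLs are then merged under three rules:

* a miRNA-correlation edge is added whenever at least one endpoint is
  already in the network (the absent partner joins as a new node);
* a gene-correlation edge is added only when BOTH genes are already
  present (no new nodes);
* a multitask eQTL edge is added only when BOTH endpoints are already
  present.

Parallel edges of different types between one node pair are retained.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import pandas as pd

EDGE_TYPES = ("eqtl", "target", "ppi", "mirna_corr", "gene_corr", "mtlasso_eqtl")

_ENDPOINT_TYPES = {
    "eqtl": ("mirna", "gene"),
    "target": ("mirna", "gene"),
    "mtlasso_eqtl": ("mirna", "gene"),
    "ppi": ("gene", "gene"),
    "gene_corr": ("gene", "gene"),
    "mirna_corr": ("mirna", "mirna"),
}


def _add_node(net: nx.MultiGraph, node: str, node_type: str) -> None:
    if node in net and net.nodes[node]["node_type"] != node_type:
        raise ValueError(
            f"node {node!r} used as both "
            f"{net.nodes[node]['node_type']} and {node_type}"
        )
    net.add_node(node, node_type=node_type)


def _add_edge(net: nx.MultiGraph, a: str, b: str, edge_type: str, **attrs) -> bool:
    """Typed edge insert, deduplicated on (a, b, edge_type)."""
    type_a, type_b = _ENDPOINT_TYPES[edge_type]
    _add_node(net, a, type_a)
    _add_node(net, b, type_b)
    if net.has_edge(a, b, key=edge_type):
        return False
    net.add_edge(a, b, key=edge_type, edge_type=edge_type, **attrs)
    return True


def check_types(net: nx.MultiGraph) -> None:
    """Assert the endpoint-type discipline of every edge."""
    for a, b, key, data in net.edges(keys=True, data=True):
        edge_type = data["edge_type"]
        want = set(_ENDPOINT_TYPES[edge_type])
        got = {net.nodes[a]["node_type"], net.nodes[b]["node_type"]}
        if edge_type in ("eqtl", "target", "mtlasso_eqtl"):
            if got != {"mirna", "gene"}:
                raise AssertionError(f"{edge_type} edge {a}-{b} endpoints {got}")
        elif got != want:
            raise AssertionError(f"{edge_type} edge {a}-{b} endpoints {got}")


def assemble_initial(
    eqtls: pd.DataFrame,
    target_interactions: pd.DataFrame,
    ppi_expansion_edges: list[tuple[str, str]],
) -> nx.MultiGraph:
    """Union of the three expansion-phase evidence sources.

    ``eqtls`` is the seed rows of the association table (mirna_id,
    gene_id, and optionally beta/fdr); ``target_interactions`` has
    mirna_id/gene_id; PPI edges are gene pairs.  Nodes are typed by the
    side of the interaction they appear on.
    """
    net: nx.MultiGraph = nx.MultiGraph()
    for row in eqtls.itertuples(index=False):
        attrs = {}
        if hasattr(row, "beta"):
            attrs["beta"] = float(row.beta)
        if hasattr(row, "fdr"):
            attrs["fdr"] = float(row.fdr)
        _add_edge(net, str(row.mirna_id), str(row.gene_id), "eqtl", **attrs)
    for row in target_interactions.itertuples(index=False):
        _add_edge(net, str(row.mirna_id), str(row.gene_id), "target")
    for a, b in ppi_expansion_edges:
        _add_edge(net, str(a), str(b), "ppi")
    check_types(net)
    return net


def merge_mirna_correlations(
    net: nx.MultiGraph, mirna_corr_edges: list[tuple[str, str, float]]
) -> nx.MultiGraph:
    """Add miRNA co-expression edges anchored by at least one member.

    The rule is deliberately asymmetric: if one endpoint is already in
    the network the other is ADDED as a new miRNA node along with the
    edge; edges with neither endpoint present are ignored.
    """
    merged = net.copy()
    for a, b, r in mirna_corr_edges:
        if a in merged or b in merged:
            _add_edge(merged, a, b, "mirna_corr", r=float(r))
    check_types(merged)
    return merged


def merge_gene_correlations(
    net: nx.MultiGraph, gene_corr_edges: list[tuple[str, str, float]]
) -> nx.MultiGraph:
    """Add gene co-expression edges only between existing members.

    Unlike the miRNA rule, no new nodes are introduced: the edge is kept
    iff both genes are already in the network.
    """
    merged = net.copy()
    for a, b, r in gene_corr_edges:
        if a in merged and b in merged:
            _add_edge(merged, a, b, "gene_corr", r=float(r))
    check_types(merged)
    return merged


def merge_mtlasso_eqtls(
    net: nx.MultiGraph, mtlasso_eqtls: pd.DataFrame
) -> nx.MultiGraph:
    """Add multitask eQTL edges between existing members only.

    ``mtlasso_eqtls`` has columns mirna_id/gene_id/coefficient; an edge
    is added iff both endpoints are already present, carrying the fitted
    coefficient as an attribute.
    """
    merged = net.copy()
    for row in mtlasso_eqtls.itertuples(index=False):
        a, b = str(row.mirna_id), str(row.gene_id)
        if a in merged and b in merged:
            _add_edge(merged, a, b, "mtlasso_eqtl", coefficient=float(row.coefficient))
    check_types(merged)
    return merged


def annotate(
    net: nx.MultiGraph,
    gene_lists: dict[str, list[str]],
    mirna_lists: dict[str, list[str]],
) -> dict[str, dict]:
    """Overlap of the network's nodes with named annotation lists.

    Returns, per list, the overlap count and the sorted overlapping IDs,
    alongside the network's own node tallies.  Empty lists yield zero
    counts with a warning.
    """
    genes = {n for n, d in net.nodes(data=True) if d["node_type"] == "gene"}
    mirnas = {n for n, d in net.nodes(data=True) if d["node_type"] == "mirna"}
    report: dict[str, dict] = {
        "n_genes": len(genes),
        "n_mirnas": len(mirnas),
        "gene_lists": {},
        "mirna_lists": {},
    }
    for section, universe, lists in (
        ("gene_lists", genes, gene_lists),
        ("mirna_lists", mirnas, mirna_lists),
    ):
        for name, ids in lists.items():
            if not ids:
                warnings.warn(f"annotation list {name!r} is empty")
            overlap = sorted(universe & set(ids))
            report[section][name] = {"count": len(overlap), "ids": overlap}
    return report


def annotate_components(
    components: dict[str, nx.MultiGraph],
    gene_lists: dict[str, list[str]],
    mirna_lists: dict[str, list[str]],
) -> pd.DataFrame:
    """Tabulate annotation overlaps across named component networks.

    One row per (component, list) with node tallies — the integrated
    network alongside its constituent parts, in the style of a summary
    table of cancer-associated members per component.
    """
    rows = []
    for component, net in components.items():
        report = annotate(net, gene_lists, mirna_lists)
        for kind in ("gene_lists", "mirna_lists"):
            for list_name, entry in report[kind].items():
                rows.append(
                    {
                        "component": component,
                        "list_kind": kind.removesuffix("_lists"),
                        "list_name": list_name,
                        "n_genes": report["n_genes"],
                        "n_mirnas": report["n_mirnas"],
                        "overlap_count": entry["count"],
                        "overlap_ids": ",".join(entry["ids"]),
                    }
                )
    return pd.DataFrame(rows)


def export(net: nx.MultiGraph, path: str | Path, fmt: str) -> None:
    """Write the network as SIF, GraphML or an edge-attribute TSV.

    SIF uses the edge type as the relation token ("A eqtl B"), one line
    per edge.  GraphML carries node_type and every edge attribute and
    round-trips through :func:`read_graphml` to an identical network.
    """
    path = Path(path)
    if fmt == "sif":
        with open(path, "w") as handle:
            for a, b, data in sorted(
                net.edges(data=True), key=lambda e: (e[0], e[2]["edge_type"], e[1])
            ):
                handle.write(f"{a}\t{data['edge_type']}\t{b}\n")
    elif fmt == "graphml":
        nx.write_graphml(net, path, named_key_ids=True, edge_id_from_attribute="edge_type")
    elif fmt == "tsv":
        rows = [
            {"source": a, "target": b, **data}
            for a, b, data in sorted(
                net.edges(data=True), key=lambda e: (e[0], e[2]["edge_type"], e[1])
            )
        ]
        columns = ["source", "target", "edge_type", "beta", "fdr", "r", "coefficient"]
        frame = pd.DataFrame(rows)
        frame = frame.reindex(columns=[c for c in columns if c in frame.columns])
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    else:
        raise ValueError(f"unknown export format: {fmt!r}")


def read_graphml(path: str | Path) -> nx.MultiGraph:
    """Read back a GraphML export as a typed multigraph."""
    graph = nx.read_graphml(path, force_multigraph=True)
    rekeyed: nx.MultiGraph = nx.MultiGraph()
    for node, data in graph.nodes(data=True):
        rekeyed.add_node(node, **data)
    for a, b, data in graph.edges(data=True):
        rekeyed.add_edge(a, b, key=data["edge_type"], **data)
    return rekeyed
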