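"""Bipartite miRNA-gene interaction network built from an interaction matrix."""
from __future__ import annotations

import networkx as nx

from .stats import InteractionMatrix


def build_network(matrix: InteractionMatrix, mirna_subset=None) -> nx.Graph:
    """Bipartite graph: edge (miRNA, gene) iff the count cell is positive.

    Edge weight is the site count; isolated genes are kept as nodes so the
    gene side always mirrors the matrix rows.  A miRNA node's degree equals
    its genes-hit multiplicity.
    """
    if mirna_subset is None:
        mirnas = list(matrix.counts.columns)
    else:
        mirnas = [matrix.resolve_mirna(m) for m in mirna_subset]
    net = nx.Graph()
    net.add_nodes_from(mirnas, bipartite="mirna")
    net.add_nodes_from(matrix.counts.index, bipartite="gene")
    for m in mirnas:
        col = matrix.counts[m]
        for g, count in col.items():
            if count > 0:
                net.add_edge(m, g, weight=int(count))
    return net


def _ordered_nodes(net: nx.Graph):
    mirnas = sorted(n for n, d in net.nodes(data=True) if d.get("bipartite") == "mirna")
    genes = sorted(n for n, d in net.nodes(data=True) if d.get("bipartite") == "gene")
    return mirnas, genes


def export_network(net: nx.Graph, path, fmt: str = "edgelist") -> None:
    """Write the network deterministically (miRNAs then genes, lexicographic).

    ``edgelist`` is a TSV (mirna_id, gene_id, weight); ``graphml`` keeps the
    bipartite node attribute so a round-trip read recovers the structure.
    """
    mirnas, genes = _ordered_nodes(net)
    if fmt == "edgelist":
        with open(path, "w") as fh:
            fh.write("mirna_id\tgene_id\tweight\n")
            for m in mirnas:
                for g in sorted(net.neighbors(m)):
                    fh.write(f"{m}\t{g}\t{net.edges[m, g]['weight']}\n")
    elif fmt == "graphml":
        ordered = nx.Graph()
        for m in mirnas:
            ordered.add_node(m, bipartite="mirna")
        for g in genes:
            ordered.add_node(g, bipartite="gene")
        for m in mirnas:
            for g in sorted(net.neighbors(m)):
                ordered.add_edge(m, g, weight=int(net.edges[m, g]["weight"]))
        nx.write_graphml(ordered, path)
    else:
        raise ValueError("fmt must be 'edgelist' or 'graphml'")


def read_network(path, fmt: str = "edgelist") -> nx.Graph:
    if fmt == "graphml":
        net = nx.read_graphml(path)
        relabeled = nx.Graph()
        for n, d in net.nodes(data=True):
            relabeled.add_node(str(n), bipartite=d.get("bipartite"))
        for a, b, d in net.edges(data=True):
            relabeled.add_edge(str(a), str(b), weight=int(d["weight"]))
        return relabeled
    if fmt != "edgelist":
        raise ValueError("fmt must be 'edgelist' or 'graphml'")
    import pandas as pd
    df = pd.read_csv(path, sep="\t")
    net = nx.Graph()
    for row in df.itertuples(index=False):
        net.add_node(str(row.mirna_id), bipartite="mirna")
        net.add_node(str(row.gene_id), bipartite="gene")
        net.add_edge(str(row.mirna_id), str(row.gene_id), weight=int(row.weight))
    return net
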