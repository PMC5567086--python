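"""Interaction subnetwork construction and degree counting.

Given a list of input genes (e.g. the mutated genes of a cohort) and a
directed interaction edge list, the subnetwork keeps (i) direct edges
between two input genes and (ii) "linker" nodes: non-input genes lying on
a directed path of length two between input genes, in any direction
combination (a->x->b, a->x<-b, a<-x->b, a<-x<-b with a, b input).  Longer
indirect connections are excluded.  Connectivity is then summarised per
node as in-degree, out-degree and their sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .io import InteractionEdgeList

__all__ = ["SignalNetwork", "build_network", "degrees"]


@dataclass
class SignalNetwork:
    """Directed subnetwork over input genes plus linker nodes."""

    graph: nx.DiGraph  # nodes carry origin="input"|"linker"

    @property
    def input_genes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["origin"] == "input"}

    @property
    def linkers(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["origin"] == "linker"}


def build_network(gene_list, edges: InteractionEdgeList) -> SignalNetwork:
    """Build the signal subnetwork for a gene list.

    Every input gene becomes a node (possibly isolated).  An edge of the
    repository is kept iff both endpoints are input genes, or one endpoint
    is an input gene and the other is a linker: a non-input node adjacent
    (in any direction) to >= 2 distinct input genes through repository
    edges, i.e. on a length-2 path between input genes.
    """
    inputs = set(gene_list)
    if not inputs:
        raise ValueError("gene list must be non-empty")
    g = nx.DiGraph()
    g.add_nodes_from(inputs, origin="input")

    # input neighbours of every non-input node, ignoring edge direction
    touched: dict[str, set[str]] = {}
    for src, dst, _ in edges.edges:
        if src in inputs and dst not in inputs:
            touched.setdefault(dst, set()).add(src)
        elif dst in inputs and src not in inputs:
            touched.setdefault(src, set()).add(dst)
    linkers = {x for x, nbrs in touched.items() if len(nbrs) >= 2}

    for x in linkers:
        g.add_node(x, origin="linker")
    for src, dst, rel in edges.edges:
        src_ok = src in inputs or src in linkers
        dst_ok = dst in inputs or dst in linkers
        if not (src_ok and dst_ok):
            continue
        if src in linkers and dst in linkers:
            continue  # linker-linker edges are not part of any length-2 path
        g.add_edge(src, dst, relation=rel)
    return SignalNetwork(graph=g)


def degrees(net: SignalNetwork) -> pd.DataFrame:
    """Per-node in-degree, out-degree and total degree (in + out).

    Anti-parallel edge pairs contribute to both counts, so a node joined
    to one partner in both directions has degree 2.
    """
    g = net.graph
    rows = [
        {
            "GENE": n,
            "ORIGIN": g.nodes[n]["origin"],
            "IN_DEGREE": g.in_degree(n),
            "OUT_DEGREE": g.out_degree(n),
            "DEGREE": g.in_degree(n) + g.out_degree(n),
        }
        for n in g.nodes
    ]
    df = pd.DataFrame(rows, columns=["GENE", "ORIGIN", "IN_DEGREE", "OUT_DEGREE", "DEGREE"])
    return df.sort_values(["DEGREE", "GENE"], ascending=[False, True]).reset_index(
        drop=True
    )
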