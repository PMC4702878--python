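"""PTM regulatory-network assembly from pathways and PPIs.

A query protein set is mapped onto user-supplied pathway membership;
protein-protein interaction (PPI) edges incident to the queries pull in
additional partners, which may flag new candidate pathway members.
Node attributes record whether a protein was a query, whether it mapped
to a pathway, and which PTM types it carries; edges are labelled
"pathway" or "ppi".  The graph is a :class:`networkx.Graph` and exports
to GraphML (lossless attributes), SIF, or a plain edge TSV for use in
Cytoscape-style viewers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from ptmstructkit.structio import SiteRecord

__all__ = ["PTMNetwork", "build_network", "export_graph"]


@dataclass
class PTMNetwork:
    """A built PTM regulatory network (thin wrapper over networkx)."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges


def build_network(
    queries: list[str],
    ptm_sites: list[SiteRecord],
    pathway_members: dict[str, set[str]],
    pathway_edges: list[tuple[str, str]],
    ppi_edges: list[tuple[str, str]],
) -> PTMNetwork:
    """Assemble the network for a query protein set.

    Nodes are the queries, the members of every pathway touched by a
    query, and the PPI partners of queries.  Pathway edges between two
    included members are kept with kind "pathway"; PPI edges incident to
    at least one query are kept with kind "ppi".  The result does not
    depend on input row order, and empty inputs yield an empty network.
    """
    g = nx.Graph()
    query_set = set(queries)

    touched_members: set[str] = set()
    member_pathways: dict[str, set[str]] = {}
    for pathway, members in pathway_members.items():
        if query_set & members:
            touched_members |= members
            for m in members:
                member_pathways.setdefault(m, set()).add(pathway)

    ppi_partners = {
        other
        for a, b in ppi_edges
        for q, other in ((a, b), (b, a))
        if q in query_set
    }

    ptm_types: dict[str, set[str]] = {}
    for site in ptm_sites:
        ptm_types.setdefault(site.accession, set()).add(site.ptm_type)

    for node in sorted(query_set | touched_members | ppi_partners):
        g.add_node(
            node,
            is_query=node in query_set,
            pathway_mapped=node in touched_members,
            has_ptm=node in ptm_types,
            ptm_types=",".join(sorted(ptm_types.get(node, ()))),
            pathways=",".join(sorted(member_pathways.get(node, ()))),
        )
    for a, b in pathway_edges:
        if a in touched_members and b in touched_members and a in g and b in g:
            g.add_edge(a, b, kind="pathway")
    for a, b in ppi_edges:
        if a in query_set or b in query_set:
            # a pathway edge between the same pair takes precedence
            if not g.has_edge(a, b):
                g.add_edge(a, b, kind="ppi")
    return PTMNetwork(graph=g)


def export_graph(net: PTMNetwork, path: str | Path, format: str = "graphml") -> None:
    """Write the network to ``path`` as graphml, sif, or edge-tsv.

    GraphML preserves all node/edge attributes; SIF writes one
    ``source kind target`` line per edge; edge-tsv writes a
    ``source  target  kind`` header and rows.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net.graph, path)
    elif format == "sif":
        lines = [
            f"{a} {d.get('kind', 'edge')} {b}" for a, b, d in net.graph.edges(data=True)
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "edge-tsv":
        rows = ["source\ttarget\tkind"] + [
            f"{a}\t{b}\t{d.get('kind', '')}" for a, b, d in net.graph.edges(data=True)
        ]
        path.write_text("\n".join(rows) + "\n")
    else:
        raise ValueError(f"unknown export format {format!r}")
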