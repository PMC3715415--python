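"""Co-complex / interaction graph construction and statistics.

Complexes with no unique members are removed in a single pass evaluated
against the original set, then all within-complex pairwise relationships
are expanded into an undirected simple graph.  Protein-level graphs can
be projected to the orthologous-group level, keeping per-edge provenance
(the protein pairs that realized each OG edge).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx

from .model import ComplexSet, DataError, InteractionNetwork, OrthologMap


@dataclass(frozen=True)
class NetworkStats:
    n_complexes: int | None
    n_proteins: int
    n_pairs: int
    average_degree: float
    n_components: int
    average_component_size: float

    def to_dict(self) -> dict:
        return {
            "n_complexes": self.n_complexes,
            "n_proteins": self.n_proteins,
            "n_pairs": self.n_pairs,
            "average_degree": self.average_degree,
            "n_components": self.n_components,
            "average_component_size": self.average_component_size,
        }


def remove_covered_complexes(cs: ComplexSet) -> tuple[ComplexSet, list[str]]:
    """Drop complexes whose members all occur in other complexes.

    Coverage is judged once, against the original set: a complex is kept
    iff at least one member appears in no *other* original complex.
    Returns the filtered set and the sorted list of removed IDs.
    """
    if len(cs) == 0:
        raise DataError("empty complex set")
    membership: dict[str, int] = {}
    for cid in cs:
        for member in cs[cid]:
            membership[member] = membership.get(member, 0) + 1
    kept = ComplexSet()
    removed: list[str] = []
    for cid in cs:
        if any(membership[m] == 1 for m in cs[cid]):
            kept.add(cid, cs[cid])
        else:
            removed.append(cid)
    return kept, sorted(removed)


def complexes_to_pairs(cs: ComplexSet) -> InteractionNetwork:
    """All within-complex pairwise relationships, deduplicated."""
    net = InteractionNetwork(level="protein")
    for cid in cs:
        for u, v in combinations(sorted(cs[cid]), 2):
            net.add_edge(u, v)
    return net


def project_to_ogs(net: InteractionNetwork, om: OrthologMap) -> InteractionNetwork:
    """Collapse a protein-level graph to OG level.

    Every node must be mapped.  Edges between two proteins of the same
    OG (in-paralog interactions) produce no OG edge but are counted in
    ``intra_og_edges``.  Each OG edge records the protein pairs behind
    it, which the open-triangle duplication call needs.
    """
    if net.level != "protein":
        raise DataError("project_to_ogs expects a protein-level network")
    unmapped = [n for n in net.nodes if n not in om]
    if unmapped:
        raise DataError(f"unmapped proteins in network: {sorted(unmapped)[:5]}")
    out = InteractionNetwork(level="og")
    for node in net.nodes:
        out.add_node(om[node])
    for u, v in net.edges():
        og_u, og_v = om[u], om[v]
        if og_u == og_v:
            out.intra_og_edges += 1
            continue
        out.add_edge(og_u, og_v, provenance=(u, v))
    return out


def network_stats(net: InteractionNetwork,
                  cs: ComplexSet | None = None) -> NetworkStats:
    """Node/edge/degree/component statistics of an interaction graph."""
    if net.n_nodes == 0:
        raise DataError("empty network")
    n_nodes = net.n_nodes
    n_edges = net.n_edges
    components = list(nx.connected_components(net.graph))
    return NetworkStats(
        n_complexes=len(cs) if cs is not None else None,
        n_proteins=n_nodes,
        n_pairs=n_edges,
        average_degree=2.0 * n_edges / n_nodes,
        n_components=len(components),
        average_component_size=n_nodes / len(components),
    )
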