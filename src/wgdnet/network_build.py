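"""Assembly of the directed enzyme-enzyme network from filtered reactions.

An enzyme A interacts with enzyme B (edge A→B) when some product metabolite
of a reaction catalyzed by A is a substrate metabolite of a reaction
catalyzed by B.  A reversible reaction is considered in both orientations.
When a single reversible reaction shared by two enzymes lets the same
metabolite serve as substrate and product of the same enzyme, the pair is
stored once as a *bidirectional* edge; opposite directional links that arise
from two different reactions stay as two directional edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .reaction_io import EnzymeGeneMap, ReactionRecord

__all__ = [
    "InteractionEdge",
    "MetabolicNetwork",
    "CentralityRecord",
    "DIRECTIONAL",
    "BIDIRECTIONAL",
    "build_enzyme_network",
    "weak_components",
    "compute_degrees",
    "write_edge_list_tsv",
    "to_graphml",
]

logger = logging.getLogger(__name__)

DIRECTIONAL = "directional"
BIDIRECTIONAL = "bidirectional"


@dataclass(frozen=True)
class InteractionEdge:
    """A directed or bidirectional enzyme-enzyme interaction.

    Bidirectional edges are stored once with canonical (sorted) endpoint
    order.  ``shared_metabolites`` records the metabolites mediating the
    interaction.
    """

    source: str
    target: str
    kind: str
    shared_metabolites: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("self-interactions are not stored")
        if self.kind not in (DIRECTIONAL, BIDIRECTIONAL):
            raise ValueError(f"unknown edge kind {self.kind!r}")
        if self.kind == BIDIRECTIONAL and self.source > self.target:
            raise ValueError("bidirectional edges use canonical endpoint order")

    @property
    def endpoints(self) -> tuple[str, str]:
        return (self.source, self.target)


@dataclass(frozen=True)
class CentralityRecord:
    """Per-enzyme degree (and optionally betweenness) summary."""

    enzyme_id: str
    in_degree: int
    out_degree: int
    betweenness: float | None = None


@dataclass
class MetabolicNetwork:
    """Directed enzyme network with directional and bidirectional edges."""

    enzymes: set[str]
    edges: list[InteractionEdge] = field(default_factory=list)
    gene_map: dict[str, EnzymeGeneMap] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for e in self.edges:
            if e.source not in self.enzymes or e.target not in self.enzymes:
                raise ValueError(f"edge endpoint not among enzymes: {e}")
        keys = [(e.source, e.target, e.kind) for e in self.edges]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (source, target, kind) edge")

    @property
    def n_enzymes(self) -> int:
        return len(self.enzymes)

    @property
    def directional_count(self) -> int:
        return sum(1 for e in self.edges if e.kind == DIRECTIONAL)

    @property
    def bidirectional_count(self) -> int:
        return sum(1 for e in self.edges if e.kind == BIDIRECTIONAL)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_pairs(self) -> list[tuple[str, str]]:
        """One (source, target) pair per stored edge (each edge counted once)."""
        return [(e.source, e.target) for e in self.edges]

    def to_networkx(self, traverse_bidirectional: bool = True) -> nx.DiGraph:
        """Directed simple graph; bidirectional edges become two arcs when
        ``traverse_bidirectional`` (default), else only the canonical arc."""
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.enzymes))
        for e in self.edges:
            g.add_edge(e.source, e.target)
            if e.kind == BIDIRECTIONAL and traverse_bidirectional:
                g.add_edge(e.target, e.source)
        return g

    def undirected_projection(self) -> nx.Graph:
        """Simple undirected projection (kinds collapsed, reciprocals merged)."""
        g = nx.Graph()
        g.add_nodes_from(sorted(self.enzymes))
        for e in self.edges:
            g.add_edge(e.source, e.target)
        return g

    def largest_component_nodes(self) -> set[str]:
        g = self.undirected_projection()
        if g.number_of_nodes() == 0:
            return set()
        return set(max(nx.connected_components(g), key=len))

    def subnetwork(self, nodes: Iterable[str]) -> "MetabolicNetwork":
        keep = set(nodes)
        return MetabolicNetwork(
            enzymes=keep & self.enzymes,
            edges=[e for e in self.edges if e.source in keep and e.target in keep],
            gene_map={k: v for k, v in self.gene_map.items() if k in keep},
        )


def build_enzyme_network(
    reactions: Iterable[ReactionRecord],
    enzyme_map: Mapping[str, EnzymeGeneMap],
) -> MetabolicNetwork:
    """Derive enzyme-enzyme interactions from currency-filtered reactions.

    For every metabolite, producers (enzyme, reaction) are linked to
    consumers; reversible reactions act in both orientations.  A pair of
    enzymes that both catalyze the same reversible reaction exchanges a
    metabolite in both directions through that single reaction and is stored
    as one bidirectional edge; other opposite links stay directional.
    Self-loops are discarded.
    """
    reactions = list(reactions)
    catalysts: dict[str, set[str]] = {}
    for enz, rec in enzyme_map.items():
        for rid in rec.catalyzed_reaction_ids:
            catalysts.setdefault(rid, set()).add(enz)

    producers: dict[str, set[tuple[str, str]]] = {}
    consumers: dict[str, set[tuple[str, str]]] = {}
    bidir_mets: dict[tuple[str, str], set[str]] = {}
    seen_reactions: set[str] = set()
    for rxn in reactions:
        enzymes = catalysts.get(rxn.reaction_id, set())
        if not enzymes:
            continue
        if not rxn.substrates or not rxn.products:
            continue  # currency filtering emptied one side
        orientations = [(rxn.substrates, rxn.products)]
        if rxn.is_reversible:
            orientations.append((rxn.products, rxn.substrates))
        # pathway-duplicate reaction lines would double provenance only;
        # the (enzyme, reaction) link sets below deduplicate naturally
        for subs, prods in orientations:
            for enz in enzymes:
                for m in subs:
                    consumers.setdefault(m, set()).add((enz, rxn.reaction_id))
                for m in prods:
                    producers.setdefault(m, set()).add((enz, rxn.reaction_id))
        if rxn.is_reversible and len(enzymes) >= 2 and rxn.reaction_id not in seen_reactions:
            ordered = sorted(enzymes)
            for i, a in enumerate(ordered):
                for b in ordered[i + 1 :]:
                    bidir_mets.setdefault((a, b), set()).update(
                        rxn.substrates | rxn.products
                    )
        seen_reactions.add(rxn.reaction_id)

    directed_mets: dict[tuple[str, str], set[str]] = {}
    for m, prods in producers.items():
        cons = consumers.get(m)
        if not cons:
            continue
        for (a, _ra) in prods:
            for (b, _rb) in cons:
                if a == b:
                    continue
                pair = (a, b) if a < b else (b, a)
                if m in bidir_mets.get(pair, ()):
                    continue
                directed_mets.setdefault((a, b), set()).add(m)

    enzymes = set(enzyme_map)
    edges: list[InteractionEdge] = []
    for (a, b), mets in sorted(bidir_mets.items()):
        edges.append(InteractionEdge(a, b, BIDIRECTIONAL, frozenset(mets)))
    for (a, b), mets in sorted(directed_mets.items()):
        edges.append(InteractionEdge(a, b, DIRECTIONAL, frozenset(mets)))
    return MetabolicNetwork(enzymes=enzymes, edges=edges, gene_map=dict(enzyme_map))


def weak_components(network: MetabolicNetwork) -> list[MetabolicNetwork]:
    """Weakly connected components, ordered by size (nodes) descending."""
    if not network.enzymes:
        return []
    g = network.undirected_projection()
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), sorted(c)))
    return [network.subnetwork(c) for c in comps]


def compute_degrees(network: MetabolicNetwork) -> dict[str, CentralityRecord]:
    """Distinct-neighbor in/out degrees.

    A bidirectional edge contributes to both the in- and the out-degree of
    both endpoints; parallel shared metabolites never multiply-count.
    """
    in_nbrs: dict[str, set[str]] = {e: set() for e in network.enzymes}
    out_nbrs: dict[str, set[str]] = {e: set() for e in network.enzymes}
    for e in network.edges:
        out_nbrs[e.source].add(e.target)
        in_nbrs[e.target].add(e.source)
        if e.kind == BIDIRECTIONAL:
            out_nbrs[e.target].add(e.source)
            in_nbrs[e.source].add(e.target)
    return {
        enz: CentralityRecord(enz, len(in_nbrs[enz]), len(out_nbrs[enz]))
        for enz in network.enzymes
    }


def write_edge_list_tsv(network: MetabolicNetwork) -> str:
    rows = ["source\ttarget\tkind\tmetabolites"]
    for e in network.edges:
        rows.append(
            f"{e.source}\t{e.target}\t{e.kind}\t"
            + ";".join(sorted(e.shared_metabolites))
        )
    return "\n".join(rows) + "\n"


def to_graphml(network: MetabolicNetwork, path: str) -> None:
    g = nx.DiGraph()
    g.add_nodes_from(sorted(network.enzymes))
    for e in network.edges:
        g.add_edge(e.source, e.target, kind=e.kind)
        if e.kind == BIDIRECTIONAL:
            g.add_edge(e.target, e.source, kind=e.kind)
    nx.write_graphml(g, path)
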