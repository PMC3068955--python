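"""Gene-centric metabolic network construction.

A metabolic reconstruction is first represented as a directed
*reaction-centric* graph: reaction ``R1`` points to ``R2`` whenever a
non-currency metabolite appears among the products of ``R1`` and the
substrates of ``R2``.  This graph is then projected onto the genes whose
products catalyse the reactions, giving the directed *gene-centric*
network on which effective subnetworks and coherence statistics are
computed.

Currency metabolites (ATP, cofactors and other ubiquitous compounds)
would otherwise connect almost everything to everything; they can be
excluded either from an explicit list or by a degree heuristic that
flags the most highly connected metabolites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "Metabolite",
    "Reaction",
    "ReactionNetwork",
    "GeneNetwork",
    "MappingVariant",
    "build_reaction_adjacency",
    "project_to_genes",
    "flag_currency_by_degree",
    "intersect_gene_networks",
]


class MappingVariant(str, Enum):
    """Rule translating reaction-level adjacency into gene-level edges.

    ALL_MULTIPLICITIES
        Every ordered gene pair across a reaction edge becomes an edge.
    EXCLUDE_SHARED_GENE_LINKS
        Reaction edges whose two reactions share a gene are dropped
        entirely (ambiguous attribution).
    SINGLE_DISTINCT_GENES
        Only reaction edges where both reactions carry exactly one gene,
        and these differ, are used.
    """

    ALL_MULTIPLICITIES = "all"
    EXCLUDE_SHARED_GENE_LINKS = "exclude-shared"
    SINGLE_DISTINCT_GENES = "single-distinct"


@dataclass(frozen=True)
class Metabolite:
    id: str
    is_currency: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("metabolite id must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """A reaction with flattened gene association.

    Gene associations are flattened to the union of gene ids; AND/OR
    Boolean structure (complexes vs isozymes) is deliberately not kept.
    ``local_currency`` lists metabolites treated as currency only for
    this reaction's adjacency tests (per-reaction currency annotation).
    """

    id: str
    substrates: frozenset[str]
    products: frozenset[str]
    reversible: bool = False
    genes: frozenset[str] = frozenset()
    pathways: frozenset[str] = frozenset()
    local_currency: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("reaction id must be non-empty")
        object.__setattr__(self, "substrates", frozenset(self.substrates))
        object.__setattr__(self, "products", frozenset(self.products))
        object.__setattr__(self, "genes", frozenset(self.genes))
        object.__setattr__(self, "pathways", frozenset(self.pathways))
        object.__setattr__(self, "local_currency", frozenset(self.local_currency))


@dataclass
class ReactionNetwork:
    """Directed reaction adjacency over a set of reactions.

    ``graph`` is a :class:`networkx.DiGraph` on reaction ids; it is a
    pure function of ``reactions`` and ``currency_ids`` and is rebuilt,
    never mutated in place.
    """

    reactions: dict[str, Reaction]
    metabolites: dict[str, Metabolite]
    currency_ids: frozenset[str]
    graph: nx.DiGraph

    @property
    def reaction_ids(self) -> list[str]:
        return sorted(self.reactions)

    def metabolite_degree(self, met_id: str) -> int:
        """Number of distinct reactions in which the metabolite appears."""
        return sum(
            1
            for r in self.reactions.values()
            if met_id in r.substrates or met_id in r.products
        )


@dataclass
class GeneNetwork:
    """Directed network on metabolic genes.

    Isolated genes (attached to retained reactions but gaining no edge)
    are kept as nodes: they matter for the coherence null model, whose
    sampling universe is the full node set.  ``source``/``variant``
    record how the network was built so that flux-activity filtering can
    re-run the projection on a reaction subset.
    """

    graph: nx.DiGraph
    variant: MappingVariant
    provenance: str = ""
    source: ReactionNetwork | None = None

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    def neighbor_sets(self) -> dict[str, set[str]]:
        """Undirected neighbourhoods (union of in- and out-neighbours)."""
        und = self.graph.to_undirected(as_view=False)
        return {n: set(und.neighbors(n)) for n in und.nodes}


def _effective_sides(reaction: Reaction, currency: frozenset[str]) -> tuple[set[str], set[str]]:
    excluded = currency | reaction.local_currency
    return set(reaction.substrates) - excluded, set(reaction.products) - excluded


def build_reaction_adjacency(
    reactions: Iterable[Reaction],
    currency_ids: Iterable[str] = (),
    metabolites: Mapping[str, Metabolite] | None = None,
) -> ReactionNetwork:
    """Build the directed reaction-centric graph.

    An edge ``R1 -> R2`` exists iff some non-currency metabolite is both
    a product of ``R1`` and a substrate of ``R2``, after expanding every
    reversible reaction into both of its orientations.  Self-edges are
    never created.  When reactions carry pathway labels, adjacency is
    additionally restricted to reaction pairs sharing at least one
    label (pathway-scoped construction).

    Parameters
    ----------
    reactions
        Reactions with unique ids.
    currency_ids
        Metabolites excluded from mediating any adjacency.
    metabolites
        Optional pre-declared metabolite table.  When given, every
        substrate/product must be declared in it.

    Raises
    ------
    ValueError
        On duplicate reaction ids, undeclared metabolites, or currency
        ids that reference no known metabolite.
    """
    reaction_map: dict[str, Reaction] = {}
    for r in reactions:
        if r.id in reaction_map:
            raise ValueError(f"duplicate reaction id: {r.id!r}")
        reaction_map[r.id] = r

    seen_mets: set[str] = set()
    for r in reaction_map.values():
        seen_mets |= r.substrates | r.products
    if metabolites is not None:
        undeclared = seen_mets - set(metabolites)
        if undeclared:
            raise ValueError(
                "reactions reference undeclared metabolites: "
                + ", ".join(sorted(undeclared))
            )
        met_map = dict(metabolites)
    else:
        met_map = {m: Metabolite(m) for m in sorted(seen_mets)}

    currency = frozenset(currency_ids)
    unknown_currency = currency - set(met_map)
    if unknown_currency:
        raise ValueError(
            "currency ids not among declared metabolites: "
            + ", ".join(sorted(unknown_currency))
        )
    met_map = {
        m: Metabolite(m, is_currency=(m in currency)) for m in met_map
    }

    # Orientation expansion: (outputs, inputs) pairs per reaction.
    orient: dict[str, list[tuple[set[str], set[str]]]] = {}
    for rid, r in reaction_map.items():
        subs, prods = _effective_sides(r, currency)
        sides = [(prods, subs)]
        if r.reversible:
            sides.append((subs, prods))
        orient[rid] = sides

    any_pathways = any(r.pathways for r in reaction_map.values())

    graph = nx.DiGraph()
    graph.add_nodes_from(sorted(reaction_map))
    rids = sorted(reaction_map)
    for r1 in rids:
        for r2 in rids:
            if r1 == r2:
                continue
            if any_pathways and not (
                reaction_map[r1].pathways & reaction_map[r2].pathways
            ):
                continue
            linked = any(
                out1 & in2
                for out1, _ in orient[r1]
                for _, in2 in orient[r2]
            )
            if linked:
                graph.add_edge(r1, r2)

    return ReactionNetwork(
        reactions=reaction_map,
        metabolites=met_map,
        currency_ids=currency,
        graph=graph,
    )


def project_to_genes(
    net: ReactionNetwork,
    variant: MappingVariant | str = MappingVariant.ALL_MULTIPLICITIES,
    provenance: str = "",
) -> GeneNetwork:
    """Project the reaction graph onto genes.

    Reactions without gene association (spontaneous or orphan) are
    skipped.  Node set = genes of every retained reaction, so genes can
    be isolated nodes.  Self-edges (one gene catalysing two consecutive
    reactions) are dropped.
    """
    try:
        variant = MappingVariant(variant)
    except ValueError as exc:
        raise ValueError(f"unknown mapping variant: {variant!r}") from exc

    gene_graph = nx.DiGraph()

    def retained(r: Reaction) -> bool:
        if not r.genes:
            return False
        if variant is MappingVariant.SINGLE_DISTINCT_GENES:
            return len(r.genes) == 1
        return True

    for r in net.reactions.values():
        if retained(r):
            gene_graph.add_nodes_from(r.genes)

    for r1, r2 in net.graph.edges:
        g1s = net.reactions[r1].genes
        g2s = net.reactions[r2].genes
        if not g1s or not g2s:
            continue
        if variant is MappingVariant.EXCLUDE_SHARED_GENE_LINKS:
            if g1s & g2s:
                continue
        elif variant is MappingVariant.SINGLE_DISTINCT_GENES:
            if len(g1s) != 1 or len(g2s) != 1 or g1s == g2s:
                continue
        for g1 in g1s:
            for g2 in g2s:
                if g1 != g2:
                    gene_graph.add_edge(g1, g2)

    return GeneNetwork(
        graph=gene_graph, variant=variant, provenance=provenance, source=net
    )


def flag_currency_by_degree(net: ReactionNetwork, fraction: float) -> set[str]:
    """Flag the highest-degree metabolites as currency.

    Returns the ``ceil(fraction * n_metabolites)`` metabolite ids of
    highest degree, where degree counts the distinct reactions a
    metabolite appears in (either side; a reversible reaction counts
    once).  Ties at the cutoff are broken by lexicographic id order, so
    the result is deterministic.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    mets = sorted(net.metabolites)
    if not mets:
        return set()
    k = math.ceil(fraction * len(mets))
    ranked = sorted(mets, key=lambda m: (-net.metabolite_degree(m), m))
    return set(ranked[:k])


def intersect_gene_networks(nets: Sequence[GeneNetwork]) -> GeneNetwork:
    """Intersection of gene networks from independent reconstructions.

    Node set = intersection of node sets; an edge survives only if it is
    present, with the same direction, in every input.  Gene id
    namespaces must already be harmonised by the caller.
    """
    if len(nets) < 2:
        raise ValueError("need at least 2 networks to intersect")
    common_nodes = set.intersection(*(n.nodes for n in nets))
    common_edges = set.intersection(*(n.edges for n in nets))
    graph = nx.DiGraph()
    graph.add_nodes_from(sorted(common_nodes))
    graph.add_edges_from(
        (u, v) for u, v in common_edges if u in common_nodes and v in common_nodes
    )
    return GeneNetwork(
        graph=graph,
        variant=nets[0].variant,
        provenance=" ∩ ".join(n.provenance or "?" for n in nets),
        source=None,
    )
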