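import networkx as nx
import numpy as np
import pytest

from metcoherence.coherence import ExpressionCalls
from metcoherence.network import (
    GeneNetwork,
    MappingVariant,
    Reaction,
    build_reaction_adjacency,
)


def make_gene_network(edges, extra_nodes=()) -> GeneNetwork:
    """Gene network straight from an edge list (plus isolated nodes)."""
    graph = nx.DiGraph()
    graph.add_edges_from(edges)
    graph.add_nodes_from(extra_nodes)
    return GeneNetwork(graph=graph, variant=MappingVariant.ALL_MULTIPLICITIES)


def random_gene_network(rng: np.random.Generator, n_nodes: int, p_edge: float) -> GeneNetwork:
    graph = nx.DiGraph()
    nodes = [f"g{i}" for i in range(n_nodes)]
    graph.add_nodes_from(nodes)
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j and rng.random() < p_edge:
                graph.add_edge(nodes[i], nodes[j])
    return GeneNetwork(graph=graph, variant=MappingVariant.ALL_MULTIPLICITIES)


def calls_for(genes, signs=None, universe=()) -> ExpressionCalls:
    """Calls marking ``genes`` significant (sign +1 unless given)."""
    signs = signs or {}
    calls = {g: (True, signs.get(g, 1)) for g in genes}
    for g in universe:
        calls.setdefault(g, (False, None))
    return ExpressionCalls(calls=calls)


def random_reactions(rng: np.random.Generator, n_reactions: int, n_metabolites: int,
                     max_genes: int = 2, p_reversible: float = 0.2,
                     gene_pool: int | None = None) -> list[Reaction]:
    mets = [f"m{i}" for i in range(n_metabolites)]
    gene_pool = gene_pool or max(2, n_reactions)
    reactions = []
    for r in range(n_reactions):
        n_s = int(rng.integers(1, 3))
        n_p = int(rng.integers(1, 3))
        subs = set(rng.choice(mets, size=n_s, replace=False))
        prods = set(rng.choice(mets, size=n_p, replace=False))
        n_g = int(rng.integers(1, max_genes + 1))
        genes = set(rng.choice([f"g{i}" for i in range(gene_pool)], size=n_g, replace=False))
        reactions.append(Reaction(
            id=f"r{r}", substrates=frozenset(subs), products=frozenset(prods),
            reversible=bool(rng.random() < p_reversible), genes=frozenset(genes),
        ))
    return reactions


@pytest.fixture
def chain_reactions():
    """A -> B -> C two-reaction chain, one gene each."""
    return [
        Reaction(id="R1", substrates=frozenset({"A"}), products=frozenset({"B"}),
                 genes=frozenset({"g1"})),
        Reaction(id="R2", substrates=frozenset({"B"}), products=frozenset({"C"}),
                 genes=frozenset({"g2"})),
    ]


@pytest.fixture
def path_network():
    """Directed path a -> b -> c -> d as a gene network."""
    return make_gene_network([("a", "b"), ("b", "c"), ("c", "d")])


def brute_force_reaction_adjacency(reactions, currency):
    """Oracle: double loop over ordered reaction pairs."""
    currency = set(currency)
    edges = set()
    for r1 in reactions:
        for r2 in reactions:
            if r1.id == r2.id:
                continue
            sides1 = [(r1.products, r1.substrates)]
            if r1.reversible:
                sides1.append((r1.substrates, r1.products))
            sides2 = [(r2.substrates, r2.products)]
            if r2.reversible:
                sides2.append((r2.products, r2.substrates))
            for out1, _ in sides1:
                for in2, _ in sides2:
                    if (set(out1) - currency) & (set(in2) - currency):
                        edges.add((r1.id, r2.id))
    return edges


def brute_force_projection(reactions, reaction_edges, variant):
    """Oracle: independent gene projection for each mapping variant."""
    genes_of = {r.id: set(r.genes) for r in reactions}
    edges = set()
    for r1, r2 in reaction_edges:
        g1s, g2s = genes_of[r1], genes_of[r2]
        if not g1s or not g2s:
            continue
        if variant == "exclude-shared" and g1s & g2s:
            continue
        if variant == "single-distinct" and not (
            len(g1s) == 1 and len(g2s) == 1 and g1s != g2s
        ):
            continue
        edges |= {(a, b) for a in g1s for b in g2s if a != b}
    nodes = set()
    for r in reactions:
        if not r.genes:
            continue
        if variant == "single-distinct" and len(r.genes) != 1:
            continue
        nodes |= set(r.genes)
    return nodes, edges


def brute_force_connected_count(nodes, edges, members):
    """Oracle: count members touched by an edge inside the member set."""
    members = set(members)
    touched = set()
    for u, v in edges:
        if u in members and v in members and u != v:
            touched.add(u)
            touched.add(v)
    return len(touched & members)
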