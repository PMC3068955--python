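"""Synthetic toy metabolisms, expression calls, TRNs and FBA models.

Every pipeline stage is testable without external data.  The generator
mimics the statistical structure of the real inputs: linear pathway
chains over private metabolites with a few promiscuously attached
currency hubs (the toy metabolism); differential-expression call sets
with a *planting fraction* ``p`` interpolating between the null (genes
picked uniformly) and fully pathway-contiguous selection (the toy
"wild-type vs NAP-mutant" contrast); a signed TF->metabolic-gene
network with companion fully consistent and sign-shuffled call
generators; and a small stoichiometric model with substitutable and
essential nutrients whose biomass optimum is known in closed form.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .coherence import ExpressionCalls
from .fba import FluxModel, MediumDefinition
from .network import GeneNetwork, Reaction, ReactionNetwork, build_reaction_adjacency
from .trn import ACTIVATION, DUAL, REPRESSION, TRN, TRNEdge

__all__ = [
    "SyntheticSpec",
    "BACKGROUND_PRESET",
    "generate_toy_metabolism",
    "plant_coherent_expression",
    "generate_background_calls",
    "generate_toy_trn",
    "consistent_trn_calls",
    "shuffled_trn_calls",
    "augment_calls_with_tf",
    "generate_toy_fba_model",
    "write_input_bundle",
]

# Four genetic backgrounds: the wild type converts supercoiling changes
# into pathway-coherent expression; NAP mutants degrade that coupling,
# the double mutant most strongly.
BACKGROUND_PRESET: dict[str, float] = {
    "wildtype": 0.8,
    "fis": 0.35,
    "hns": 0.35,
    "fis_hns": 0.1,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Defaults give ~15 pathways of 4-8 reactions (≈90 metabolic genes),
    2 currency hubs touching ~30% of reactions, 25 significant genes
    per background and a mostly coherent within-walk sign model.
    """

    n_pathways: int = 15
    pathway_length_min: int = 4
    pathway_length_max: int = 8
    n_currency_hubs: int = 2
    hub_attachment_rate: float = 0.3
    genes_per_reaction_max: int = 1
    n_significant: int = 25
    planting_fraction: float = 0.8
    sign_coherent_prob: float = 0.9
    n_tfs: int = 12
    n_trn_targets: int = 40
    activation_fraction: float = 0.6
    dual_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pathways < 1:
            raise ValueError("need at least one pathway")
        if not 0 <= self.planting_fraction <= 1:
            raise ValueError("planting fraction must lie in [0, 1]")
        if self.pathway_length_min < 2 or self.pathway_length_max < self.pathway_length_min:
            raise ValueError("invalid pathway length range")
        if self.n_significant < 1 or self.n_tfs < 1 or self.genes_per_reaction_max < 1:
            raise ValueError("counts must be positive")


def generate_toy_metabolism(spec: SyntheticSpec) -> tuple[ReactionNetwork, set[str]]:
    """Pathway chains plus currency hubs.

    Each pathway is a linear chain of reactions over private
    metabolites; currency hubs are added to both sides of a random
    fraction of reactions (the way ATP/ADP pairs ride along real
    reactions), creating spurious adjacency unless flagged as currency.
    Returns the reaction network built WITHOUT currency removal plus
    the ground-truth hub id set.
    """
    rng = np.random.default_rng(spec.seed)
    reactions: list[Reaction] = []
    hub_ids = {f"hub{h:02d}" for h in range(spec.n_currency_hubs)}

    gene_counter = 0
    for p in range(spec.n_pathways):
        length = int(
            rng.integers(spec.pathway_length_min, spec.pathway_length_max + 1)
        )
        mets = [f"m{p:03d}_{i:02d}" for i in range(length + 1)]
        for i in range(length):
            n_genes = int(rng.integers(1, spec.genes_per_reaction_max + 1))
            genes = frozenset(
                f"g{gene_counter + j:04d}" for j in range(n_genes)
            )
            gene_counter += n_genes
            subs, prods = {mets[i]}, {mets[i + 1]}
            for hub in sorted(hub_ids):
                if rng.random() < spec.hub_attachment_rate:
                    subs.add(hub)
                    prods.add(hub)
            reactions.append(
                Reaction(
                    id=f"r{p:03d}_{i:02d}",
                    substrates=frozenset(subs),
                    products=frozenset(prods),
                    reversible=False,
                    genes=genes,
                )
            )
    net = build_reaction_adjacency(reactions)
    return net, hub_ids


def plant_coherent_expression(
    net: GeneNetwork,
    k: int,
    p: float,
    seed: int = 0,
    sign_coherent_prob: float = 0.9,
    background: str = "",
) -> ExpressionCalls:
    """Significant-gene calls with tunable pathway coherence.

    ``ceil(p*k)`` significant genes are collected by seeded random
    walks along the network's edges (pathway-contiguous selection); the
    remainder is drawn uniformly from the not-yet-selected nodes.  At
    ``p=0`` this reduces exactly to the size-matched null sampler:
    a uniform draw of ``k`` genes without replacement.  Signs are
    coherent within each walk with probability ``sign_coherent_prob``
    and uniform +/-1 elsewhere.  All network genes appear in the call
    table (non-significant ones unsigned), so jackknife removal can hit
    significant and non-significant entries alike.
    """
    nodes = sorted(net.nodes)
    if k > len(nodes):
        raise ValueError(f"k={k} exceeds the {len(nodes)} network genes")
    if not 0 <= p <= 1:
        raise ValueError("planting fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    n_planted = math.ceil(p * k)
    selected: list[str] = []
    selected_set: set[str] = set()
    signs: dict[str, int] = {}

    out_nbrs = {n: sorted(net.graph.successors(n)) for n in nodes}
    in_nbrs = {n: sorted(net.graph.predecessors(n)) for n in nodes}

    while len(selected) < n_planted:
        start = nodes[int(rng.integers(len(nodes)))]
        if start in selected_set:
            continue
        walk_sign = 1 if rng.random() < 0.5 else -1
        current = start
        while current is not None and len(selected) < n_planted:
            if current not in selected_set:
                selected.append(current)
                selected_set.add(current)
                coherent = rng.random() < sign_coherent_prob
                signs[current] = walk_sign if coherent else -walk_sign
            steps = [
                m
                for m in out_nbrs[current] + in_nbrs[current]
                if m not in selected_set
            ]
            current = steps[int(rng.integers(len(steps)))] if steps else None

    remaining = [n for n in nodes if n not in selected_set]
    n_uniform = k - len(selected)
    if n_uniform:
        picks = rng.choice(len(remaining), size=n_uniform, replace=False)
        for i in picks:
            g = remaining[int(i)]
            selected.append(g)
            selected_set.add(g)
            signs[g] = 1 if rng.random() < 0.5 else -1

    calls = {
        n: ((n in selected_set), signs.get(n)) for n in nodes
    }
    return ExpressionCalls(calls=calls, background=background)


def generate_background_calls(
    net: GeneNetwork,
    spec: SyntheticSpec,
    preset: dict[str, float] | None = None,
) -> dict[str, ExpressionCalls]:
    """One call set per genetic background with preset planting fractions."""
    preset = dict(BACKGROUND_PRESET if preset is None else preset)
    out = {}
    for i, (background, p) in enumerate(sorted(preset.items())):
        bg_seed = int(
            np.random.SeedSequence((spec.seed, 0x6267, i)).generate_state(1)[0] % 2**31
        )
        out[background] = plant_coherent_expression(
            net,
            k=spec.n_significant,
            p=p,
            seed=bg_seed,
            sign_coherent_prob=spec.sign_coherent_prob,
            background=background,
        )
    return out


def generate_toy_trn(
    metabolic_genes: set[str] | list[str], spec: SyntheticSpec
) -> TRN:
    """Random TF set regulating disjoint metabolic-gene targets.

    Each target has exactly one regulator, so a fully consistent sign
    assignment always exists.  Effects are activation with the spec's
    mix, otherwise repression; a ``dual_fraction`` of links may carry
    the ambiguous dual effect.
    """
    genes = sorted(metabolic_genes)
    if not genes:
        raise ValueError("need at least one metabolic gene")
    rng = np.random.default_rng(
        np.random.SeedSequence((spec.seed, 0x74726E))
    )
    n_targets = min(spec.n_trn_targets, len(genes))
    targets = [genes[int(i)] for i in rng.choice(len(genes), n_targets, replace=False)]
    edges = []
    for t_idx, target in enumerate(targets):
        tf = f"tf{int(rng.integers(spec.n_tfs)):02d}"
        u = rng.random()
        if u < spec.dual_fraction:
            effect = DUAL
        elif u < spec.dual_fraction + spec.activation_fraction:
            effect = ACTIVATION
        else:
            effect = REPRESSION
        edges.append(TRNEdge(regulator=tf, target=target, effect=effect))
    return TRN(edges=edges)


def consistent_trn_calls(trn: TRN, seed: int = 0, background: str = "") -> ExpressionCalls:
    """Signs making every non-dual effective link consistent.

    Each TF gets a random sign; targets inherit the sign implied by the
    link logic.  All TRN nodes are significant.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x636F6E)))
    signs: dict[str, int] = {}
    for tf in sorted(trn.regulators):
        signs[tf] = 1 if rng.random() < 0.5 else -1
    for e in trn.edges:
        reg_sign = signs[e.regulator]
        if e.effect == ACTIVATION:
            signs[e.target] = reg_sign
        elif e.effect == REPRESSION:
            signs[e.target] = -reg_sign
        else:  # dual links constrain nothing
            signs.setdefault(e.target, 1 if rng.random() < 0.5 else -1)
    calls = {g: (True, s) for g, s in signs.items()}
    return ExpressionCalls(calls=calls, background=background)


def shuffled_trn_calls(trn: TRN, seed: int = 0, background: str = "") -> ExpressionCalls:
    """Consistent calls with the sign multiset randomly permuted."""
    base = consistent_trn_calls(trn, seed=seed, background=background)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x736866)))
    genes = sorted(base.calls)
    signs = [base.calls[g][1] for g in genes]
    perm = rng.permutation(len(signs))
    calls = {g: (True, signs[int(i)]) for g, i in zip(genes, perm)}
    return ExpressionCalls(calls=calls, background=background)


def augment_calls_with_tf(
    calls: ExpressionCalls,
    trn: TRN,
    tf_significant_prob: float = 0.6,
    seed: int = 0,
) -> ExpressionCalls:
    """Add expression calls for the TRN's transcription factors.

    TFs are genes on the array too; without calls of their own they can
    never anchor an effective regulatory link.  Each TF is significant
    with the given probability, with a uniform random sign.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x7466)))
    merged = dict(calls.calls)
    for tf in sorted(trn.regulators):
        if tf in merged:
            continue
        if rng.random() < tf_significant_prob:
            merged[tf] = (True, 1 if rng.random() < 0.5 else -1)
        else:
            merged[tf] = (False, None)
    return ExpressionCalls(calls=merged, background=calls.background,
                           contrast=calls.contrast)


def generate_toy_fba_model(
    n_nutrients: int = 3,
    n_internal: int = 3,
    seed: int = 0,
    uptake: float = 10.0,
) -> tuple[FluxModel, MediumDefinition, dict]:
    """Small stoichiometric model with a hand-computable optimum.

    Layout: ``n_sub = max(1, ceil(n_nutrients/2))`` substitutable
    nutrients each convert to a common precursor ``P``; the remaining
    nutrients are essential, each feeding a private biomass precursor.
    ``P`` runs through a chain of ``n_internal`` conversions into
    ``PP``; biomass consumes one unit of ``PP`` and one of each private
    precursor.  With every uptake bounded by ``uptake`` the biomass
    optimum is ``min(n_sub*uptake, uptake over each essential)`` —
    recorded in the returned ground-truth dict together with the
    essential/substitutable split.  The seed only shuffles reaction
    gene labels; the topology is fixed by the counts.
    """
    if n_nutrients < 1 or n_internal < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    n_sub = max(1, math.ceil(n_nutrients / 2))
    nutrients = [f"N{i+1}" for i in range(n_nutrients)]
    substitutable = nutrients[:n_sub]
    essential = nutrients[n_sub:]

    stoich: dict[str, dict[str, float]] = {}
    lb: dict[str, float] = {}
    ub: dict[str, float] = {}
    genes: dict[str, frozenset[str]] = {}

    gene_labels = [f"gf{int(i):03d}" for i in rng.permutation(200)[: n_nutrients + n_internal + 1]]
    g_iter = iter(gene_labels)

    medium_bounds = {}
    for nut in nutrients:
        ex = f"EX_{nut}"
        stoich[ex] = {nut: -1.0}  # export orientation; uptake = negative flux
        lb[ex], ub[ex] = 0.0, 1000.0
        medium_bounds[ex] = uptake

    for nut in substitutable:
        rid = f"T_{nut}"
        stoich[rid] = {nut: -1.0, "P": 1.0}
        lb[rid], ub[rid] = 0.0, 1000.0
        genes[rid] = frozenset({next(g_iter)})
    for nut in essential:
        rid = f"T_{nut}"
        stoich[rid] = {nut: -1.0, f"Q_{nut}": 1.0}
        lb[rid], ub[rid] = 0.0, 1000.0
        genes[rid] = frozenset({next(g_iter)})

    chain = ["P"] + [f"I{i+1}" for i in range(n_internal - 1)] + ["PP"]
    for i in range(len(chain) - 1):
        rid = f"C{i+1}"
        stoich[rid] = {chain[i]: -1.0, chain[i + 1]: 1.0}
        lb[rid], ub[rid] = 0.0, 1000.0
        genes[rid] = frozenset({next(g_iter)})

    biomass_in: dict[str, float] = {"PP": -1.0}
    for nut in essential:
        biomass_in[f"Q_{nut}"] = -1.0
    stoich["BIOMASS"] = biomass_in
    lb["BIOMASS"], ub["BIOMASS"] = 0.0, 1000.0
    genes["BIOMASS"] = frozenset()

    model = FluxModel(
        stoichiometry=stoich,
        lower_bounds=lb,
        upper_bounds=ub,
        objective="BIOMASS",
        genes=genes,
    )
    rich = MediumDefinition(medium_bounds)
    optimum = min(
        [n_sub * uptake] + [uptake] * len(essential)
    )
    truth = {
        "optimum": optimum,
        "essential_nutrients": [f"EX_{n}" for n in essential],
        "substitutable_nutrients": [f"EX_{n}" for n in substitutable],
        "uptake": uptake,
    }
    return model, rich, truth


def write_input_bundle(
    outdir,
    spec: SyntheticSpec | None = None,
    n_nutrients: int = 3,
    n_internal: int = 3,
) -> dict:
    """Write a complete synthetic input bundle to a directory.

    Produces a reaction table, currency list, per-background expression
    tables (planting fractions from :data:`BACKGROUND_PRESET`), a TRN
    table, an SBML toy flux model with its rich medium, a ready-to-run
    pipeline config, and a ground-truth JSON (planted genes per
    background, planting fractions, essential nutrients, analytic
    biomass optimum).  Returns the ground-truth dict.
    """
    import json
    from pathlib import Path

    from . import io as mio
    from .network import project_to_genes

    spec = spec or SyntheticSpec()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    net, hubs = generate_toy_metabolism(spec)
    mio.write_reaction_table(net.reactions.values(), outdir / "reactions.tsv")
    mio.write_currency_list(hubs, outdir / "currency.txt")

    # plant on the currency-removed network: that is the analysis network
    clean = build_reaction_adjacency(net.reactions.values(), hubs)
    gene_net = project_to_genes(clean, provenance="synthetic")
    trn = generate_toy_trn(gene_net.nodes, spec)
    mio.write_trn_table(trn, outdir / "trn.tsv")

    model, rich, fba_truth = generate_toy_fba_model(
        n_nutrients=n_nutrients, n_internal=n_internal, seed=spec.seed
    )

    calls_by_background = generate_background_calls(gene_net, spec)
    planted = {}
    expression_tables = {}
    model_genes = sorted({g for gs in model.genes.values() for g in gs})
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0x666D)))
    for background, calls in calls_by_background.items():
        calls = augment_calls_with_tf(calls, trn, seed=spec.seed)
        # the flux model carries its own small gene set; give each a call
        # so the activity-filtered coherence stage has effective nodes
        merged = dict(calls.calls)
        for g in model_genes:
            if rng.random() < 0.5:
                merged[g] = (True, 1 if rng.random() < 0.5 else -1)
            else:
                merged[g] = (False, None)
        calls = ExpressionCalls(calls=merged, background=background)
        path = outdir / f"calls_{background}.tsv"
        mio.write_expression_calls(calls, path)
        expression_tables[background] = str(path)
        planted[background] = sorted(calls.significant)

    mio.write_sbml_model(model, outdir / "model.xml")
    mio.write_medium(rich, outdir / "medium.tsv")

    truth = {
        "seed": spec.seed,
        "planting_fractions": dict(BACKGROUND_PRESET),
        "significant_genes": planted,
        "currency_hubs": sorted(hubs),
        "fba": fba_truth,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)

    config = {
        "reaction_table": str(outdir / "reactions.tsv"),
        "expression_tables": expression_tables,
        "currency_mode": "list",
        "currency_list": str(outdir / "currency.txt"),
        "trn_table": str(outdir / "trn.tsv"),
        "trn_enabled": True,
        "fba_model": str(outdir / "model.xml"),
        "medium": str(outdir / "medium.tsv"),
        "fba_enabled": True,
        "seed": spec.seed,
        "outdir": str(outdir / "results"),
    }
    import yaml

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return truth
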