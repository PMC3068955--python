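"""Digital control and sign-consistency on the regulatory network.

Transcription-factor ("digital") control is quantified with the same
connected-node z-score machinery as metabolic coherence, run on the
transcription-factor -> metabolic-gene network (the digital CTC).  A
second, signed statistic asks whether the activation/repression logic
on each effective regulatory link agrees with the expression signs of
its endpoints; the consistent-link ratio is turned into a z-score
against a null that shuffles the observed signs across the effective
nodes (preserving the sign composition exactly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .coherence import (
    DEFAULT_N_REALIZATIONS,
    CoherenceResult,
    ExpressionCalls,
    mc_zscore,
    realization_rng,
)
from .network import GeneNetwork, MappingVariant

__all__ = [
    "ACTIVATION",
    "REPRESSION",
    "DUAL",
    "TRNEdge",
    "TRN",
    "EffectiveTRN",
    "ConsistencyResult",
    "filter_trn_to_metabolic",
    "trn_to_gene_network",
    "digital_ctc",
    "extract_effective_trn",
    "link_consistency",
    "trn_consistency_zscore",
]

ACTIVATION = "+"
REPRESSION = "-"
DUAL = "+-"
_EFFECTS = {ACTIVATION, REPRESSION, DUAL}


@dataclass(frozen=True)
class TRNEdge:
    regulator: str
    target: str
    effect: str

    def __post_init__(self) -> None:
        if self.effect not in _EFFECTS:
            raise ValueError(
                f"effect must be one of {sorted(_EFFECTS)}, got {self.effect!r}"
            )


@dataclass
class TRN:
    """Signed transcription-factor -> target edge list."""

    edges: list[TRNEdge]

    def __post_init__(self) -> None:
        seen = set()
        for e in self.edges:
            key = (e.regulator, e.target, e.effect)
            if key in seen:
                raise ValueError(f"duplicate TRN edge: {key}")
            seen.add(key)

    @property
    def regulators(self) -> set[str]:
        return {e.regulator for e in self.edges}

    @property
    def targets(self) -> set[str]:
        return {e.target for e in self.edges}

    @property
    def nodes(self) -> set[str]:
        return self.regulators | self.targets


@dataclass
class EffectiveTRN:
    """TRN restricted to significantly changed, signed genes.

    Effective links require a significant call at both endpoints; a TF
    without a significant call of its own contributes no effective
    links.  Dual-effect links and self-loops are kept out of the
    consistency computation (neither consistent nor inconsistent is
    defined for them).
    """

    node_signs: dict[str, int]
    links: list[TRNEdge]  # both endpoints significant, not dual, no self-loop
    consistent_flags: list[bool]


@dataclass
class ConsistencyResult:
    consistency: float
    zscore: float
    null_ratios: np.ndarray
    n_effective_links: int
    n_consistent: int
    n_realizations: int
    seed: int
    degenerate: bool = False
    background: str = ""

    def to_record(self) -> dict:
        return {
            "background": self.background,
            "consistency": self.consistency,
            "z": self.zscore,
            "n_effective_links": self.n_effective_links,
            "n_consistent": self.n_consistent,
            "n_realizations": self.n_realizations,
            "seed": self.seed,
            "degenerate": self.degenerate,
            "dual_links_excluded": True,
        }


def filter_trn_to_metabolic(trn: TRN, metabolic_genes: set[str]) -> TRN:
    """Keep only links whose target is a metabolic gene.

    Regulators are kept regardless of their own metabolic status: the
    statistic concerns regulatory input into metabolism.
    """
    return TRN(edges=[e for e in trn.edges if e.target in metabolic_genes])


def trn_to_gene_network(trn: TRN, provenance: str = "TRN") -> GeneNetwork:
    """Unsigned directed regulator->target graph for CTC computation.

    Parallel edges with different effects collapse to one edge;
    self-loops are dropped, mirroring the metabolic projection.
    """
    graph = nx.DiGraph()
    graph.add_nodes_from(sorted(trn.nodes))
    for e in trn.edges:
        if e.regulator != e.target:
            graph.add_edge(e.regulator, e.target)
    return GeneNetwork(
        graph=graph,
        variant=MappingVariant.ALL_MULTIPLICITIES,
        provenance=provenance,
        source=None,
    )


def digital_ctc(
    trn: TRN,
    calls: ExpressionCalls,
    n_realizations: int = DEFAULT_N_REALIZATIONS,
    seed: int = 0,
) -> CoherenceResult:
    """Digital control strength: the connected-node z-score on the TRN.

    Identical machinery to the metabolic coherence — effective
    subnetwork on significant genes, connected/overall ratio, z-score
    against size-matched random gene sets drawn from the TRN's nodes —
    via a single shared implementation.
    """
    net = trn_to_gene_network(trn)
    return mc_zscore(net, calls, n_realizations=n_realizations, seed=seed,
                     network_label="TRN")


def _is_consistent(effect: str, reg_sign: int, tgt_sign: int) -> bool:
    if effect == ACTIVATION:
        return reg_sign == tgt_sign
    if effect == REPRESSION:
        return reg_sign == -tgt_sign
    raise ValueError(f"consistency undefined for effect {effect!r}")


def extract_effective_trn(trn: TRN, calls: ExpressionCalls) -> EffectiveTRN:
    """Restrict the TRN to significant, signed genes and flag each link."""
    signs = {
        g: s for g in trn.nodes
        if (s := calls.sign(g)) is not None
    }
    links: list[TRNEdge] = []
    flags: list[bool] = []
    for e in trn.edges:
        if e.effect == DUAL or e.regulator == e.target:
            continue
        if e.regulator in signs and e.target in signs:
            links.append(e)
            flags.append(_is_consistent(e.effect, signs[e.regulator], signs[e.target]))
    return EffectiveTRN(node_signs=signs, links=links, consistent_flags=flags)


def link_consistency(effective: EffectiveTRN) -> float:
    """Fraction of effective links whose logic matches the endpoint signs.

    Activation is consistent when both endpoints change in the same
    direction; repression when they change in opposite directions.
    """
    if not effective.links:
        raise ValueError("no effective links: consistency is undefined")
    return sum(effective.consistent_flags) / len(effective.links)


def trn_consistency_zscore(
    trn: TRN,
    calls: ExpressionCalls,
    n_realizations: int = DEFAULT_N_REALIZATIONS,
    seed: int = 0,
) -> ConsistencyResult:
    """Sign-consistency z-score against a sign-shuffle null.

    Each null realization permutes the observed sign multiset across
    the effective nodes (network and node set fixed) and recomputes the
    consistent-link ratio.  Permuting — rather than resampling ±1 —
    preserves the sign composition in every realization.  A null with
    zero variance (e.g. all signs equal and all effects activation) is
    flagged degenerate with z = 0.
    """
    if n_realizations < 2:
        raise ValueError("need at least 2 null realizations")
    effective = extract_effective_trn(trn, calls)
    observed = link_consistency(effective)  # raises if no effective links

    nodes = sorted(effective.node_signs)
    signs = np.asarray([effective.node_signs[n] for n in nodes], dtype=np.int8)
    index = {n: i for i, n in enumerate(nodes)}
    link_idx = np.asarray(
        [(index[e.regulator], index[e.target]) for e in effective.links],
        dtype=np.int64,
    )
    activations = np.asarray(
        [e.effect == ACTIVATION for e in effective.links], dtype=bool
    )

    null_ratios = np.empty(n_realizations, dtype=float)
    for i in range(n_realizations):
        rng = realization_rng(seed, i)
        shuffled = signs[rng.permutation(signs.size)]
        reg_s = shuffled[link_idx[:, 0]]
        tgt_s = shuffled[link_idx[:, 1]]
        consistent = np.where(activations, reg_s == tgt_s, reg_s == -tgt_s)
        null_ratios[i] = consistent.mean()

    mean = float(null_ratios.mean())
    sd = float(null_ratios.std(ddof=1))
    degenerate = sd == 0.0 or math.isnan(sd)
    z = 0.0 if degenerate else (observed - mean) / sd

    return ConsistencyResult(
        consistency=observed,
        zscore=z,
        null_ratios=null_ratios,
        n_effective_links=len(effective.links),
        n_consistent=sum(effective.consistent_flags),
        n_realizations=n_realizations,
        seed=seed,
        degenerate=degenerate,
        background=calls.background,
    )
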