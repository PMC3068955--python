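"""Effective subnetworks and the metabolic coherence statistic.

The pattern of significantly differentially expressed genes is mapped
onto a static gene network, giving the *effective subnetwork*: the
node-induced subgraph on significant genes.  Its fraction of connected
nodes (at least one incident edge within the subnetwork, either
direction) is the metabolic coherence ratio (MCR).  To correct for the
size of the effective set, the MCR is turned into a z-score — the
metabolic coherence (MC) — against random gene sets of the same size
drawn uniformly without replacement from the static network's nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import GeneNetwork

__all__ = [
    "ExpressionCalls",
    "EffectiveSubnetwork",
    "CoherenceResult",
    "JackknifeResult",
    "extract_effective_subnetwork",
    "mcr",
    "mc_zscore",
    "jackknife_mc",
    "realization_rng",
]

DEFAULT_N_REALIZATIONS = 5000


def realization_rng(seed: int, index: int) -> np.random.Generator:
    """Deterministic per-realization RNG substream.

    Derived from ``(seed, index)`` so that results are independent of
    any parallelisation or evaluation order of the realizations.
    """
    return np.random.default_rng(np.random.SeedSequence((seed, index)))


@dataclass
class ExpressionCalls:
    """Differential-expression calls for one contrast in one background.

    ``calls`` maps each measured gene to ``(significant, sign)``; sign
    is +1/-1 for significant genes (direction of the expression change)
    and ``None`` otherwise.
    """

    calls: dict[str, tuple[bool, int | None]]
    background: str = ""
    contrast: str = ""

    def __post_init__(self) -> None:
        for gene, (sig, sign) in self.calls.items():
            if sig and sign not in (-1, 1):
                raise ValueError(
                    f"significant gene {gene!r} must carry sign -1 or +1"
                )

    @property
    def significant(self) -> set[str]:
        return {g for g, (sig, _) in self.calls.items() if sig}

    def sign(self, gene: str) -> int | None:
        entry = self.calls.get(gene)
        return entry[1] if entry and entry[0] else None

    def drop_genes(self, genes: set[str]) -> "ExpressionCalls":
        return ExpressionCalls(
            calls={g: v for g, v in self.calls.items() if g not in genes},
            background=self.background,
            contrast=self.contrast,
        )


@dataclass
class EffectiveSubnetwork:
    parent: GeneNetwork
    nodes: set[str]
    edges: set[tuple[str, str]]
    connected: set[str]
    n_missing: int  # significant genes absent from the parent network

    @property
    def isolated(self) -> set[str]:
        return self.nodes - self.connected


@dataclass
class CoherenceResult:
    """Observed coherence ratio, null sample and z-score."""

    mcr_observed: float
    null_ratios: np.ndarray
    mc_zscore: float
    n_effective_nodes: int
    n_connected: int
    n_realizations: int
    seed: int
    degenerate: bool = False
    n_missing: int = 0
    background: str = ""
    network_label: str = ""

    def to_record(self) -> dict:
        return {
            "background": self.background,
            "network_label": self.network_label,
            "mcr": self.mcr_observed,
            "mc": self.mc_zscore,
            "n_effective": self.n_effective_nodes,
            "n_connected": self.n_connected,
            "n_realizations": self.n_realizations,
            "seed": self.seed,
            "degenerate": self.degenerate,
            "genes_not_in_network": self.n_missing,
        }


@dataclass
class JackknifeResult:
    zscores: list[float]  # NaN marks repeats whose effective set emptied
    sd: float
    n_missing_repeats: int


def extract_effective_subnetwork(
    net: GeneNetwork, calls: ExpressionCalls
) -> EffectiveSubnetwork:
    """Node-induced subgraph on the significant genes.

    Significant genes absent from the network are ignored but counted
    in ``n_missing`` for reporting.
    """
    significant = calls.significant
    nodes = significant & net.nodes
    sub = net.graph.subgraph(nodes)
    edges = set(sub.edges)
    connected = {n for n in nodes if sub.degree(n) > 0}
    return EffectiveSubnetwork(
        parent=net,
        nodes=nodes,
        edges=edges,
        connected=connected,
        n_missing=len(significant - net.nodes),
    )


def mcr(sub: EffectiveSubnetwork) -> float:
    """Metabolic coherence ratio: connected / all effective nodes."""
    if not sub.nodes:
        raise ValueError("no effective nodes: MCR is undefined")
    return len(sub.connected) / len(sub.nodes)


def _connected_count(member_row: np.ndarray, adjacency: list[np.ndarray]) -> int:
    """Count members with >= 1 neighbour among the members.

    ``member_row`` is a boolean indicator over node indices;
    ``adjacency[i]`` lists the undirected neighbour indices of node i.
    """
    count = 0
    for i in np.flatnonzero(member_row):
        nbrs = adjacency[i]
        if nbrs.size and member_row[nbrs].any():
            count += 1
    return count


def _index_adjacency(net: GeneNetwork) -> tuple[list[str], list[np.ndarray]]:
    nodes = sorted(net.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    nbr_sets = net.neighbor_sets()
    adjacency = [
        np.fromiter((index[m] for m in nbr_sets[n]), dtype=np.int64)
        for n in nodes
    ]
    return nodes, adjacency


def mc_zscore(
    net: GeneNetwork,
    calls: ExpressionCalls,
    n_realizations: int = DEFAULT_N_REALIZATIONS,
    seed: int = 0,
    network_label: str = "",
) -> CoherenceResult:
    """Metabolic coherence: z-score of the MCR against size-matched nulls.

    Each null realization draws ``k`` genes (k = size of the effective
    set) uniformly without replacement from the static network's node
    set and recomputes the connected-node ratio on the induced
    subgraph.  ``z = (MCR - mean(MCR')) / sd(MCR')``.  A null with zero
    variance (pathological topology, e.g. a clique) yields ``z = 0``
    with the ``degenerate`` flag set rather than an error, so batch
    runs never crash.
    """
    if n_realizations < 2:
        raise ValueError("need at least 2 null realizations")
    sub = extract_effective_subnetwork(net, calls)
    observed = mcr(sub)  # raises on empty effective set
    k = len(sub.nodes)

    nodes, adjacency = _index_adjacency(net)
    n = len(nodes)

    null_ratios = np.empty(n_realizations, dtype=float)
    for i in range(n_realizations):
        rng = realization_rng(seed, i)
        picks = rng.choice(n, size=k, replace=False)
        member = np.zeros(n, dtype=bool)
        member[picks] = True
        null_ratios[i] = _connected_count(member, adjacency) / k

    mean = float(null_ratios.mean())
    sd = float(null_ratios.std(ddof=1))
    degenerate = sd == 0.0 or math.isnan(sd)
    z = 0.0 if degenerate else (observed - mean) / sd

    return CoherenceResult(
        mcr_observed=observed,
        null_ratios=null_ratios,
        mc_zscore=z,
        n_effective_nodes=k,
        n_connected=len(sub.connected),
        n_realizations=n_realizations,
        seed=seed,
        degenerate=degenerate,
        n_missing=sub.n_missing,
        background=calls.background,
        network_label=network_label or net.provenance,
    )


def jackknife_mc(
    net: GeneNetwork,
    calls: ExpressionCalls,
    n_repeats: int = 100,
    drop_fraction: float = 0.10,
    seed: int = 0,
    n_realizations: int = DEFAULT_N_REALIZATIONS,
) -> JackknifeResult:
    """Stability of MC under random removal of expression data.

    Each repeat removes ``floor(drop_fraction * n_calls)`` genes
    uniformly at random from the call table (significant and
    non-significant alike) and recomputes the MC.  The null-model seed
    is held fixed across repeats, so only the data removal varies; in
    the limit of zero dropped genes every repeat reproduces the
    full-data MC exactly.  Repeats whose effective set empties are
    recorded as NaN and counted.
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError(f"drop_fraction must be in [0, 1), got {drop_fraction}")
    genes = sorted(calls.calls)
    n_drop = math.floor(drop_fraction * len(genes))

    zscores: list[float] = []
    n_missing_repeats = 0
    for rep in range(n_repeats):
        # distinct stream family from the null realizations: extra key
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0x6A6B, rep)))
        dropped = set(
            np.asarray(genes, dtype=object)[
                rng.choice(len(genes), size=n_drop, replace=False)
            ]
        ) if n_drop else set()
        reduced = calls.drop_genes(dropped)
        try:
            res = mc_zscore(net, reduced, n_realizations=n_realizations, seed=seed)
        except ValueError:
            zscores.append(float("nan"))
            n_missing_repeats += 1
            continue
        zscores.append(res.mc_zscore)

    valid = np.asarray([z for z in zscores if not math.isnan(z)])
    sd = float(valid.std(ddof=1)) if valid.size > 1 else 0.0
    return JackknifeResult(zscores=zscores, sd=sd, n_missing_repeats=n_missing_repeats)
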