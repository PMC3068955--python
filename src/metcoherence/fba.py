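"""Flux balance analysis and flux-activity filtering of gene networks.

FBA predicts a steady-state flux distribution ``v`` maximizing a
biomass objective subject to ``S v = 0`` and per-reaction bounds.  The
optimum is found with :func:`scipy.optimize.linprog` (HiGHS).  Because
the optimal vertex is generally not unique, the default behaviour is
*parsimonious*: after fixing the biomass optimum a second LP minimizes
the total absolute flux, giving a canonical, reproducible solution from
which the active-reaction set is read off.

The active set drives two downstream analyses: restricting the
gene-centric network to active reactions, and scanning the metabolic
coherence while a rich medium is randomly reduced, component by
component, down to a minimal medium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .coherence import DEFAULT_N_REALIZATIONS, ExpressionCalls, mc_zscore
from .network import (
    GeneNetwork,
    Reaction,
    ReactionNetwork,
    build_reaction_adjacency,
    project_to_genes,
)

__all__ = [
    "FluxModel",
    "MediumDefinition",
    "FluxDistribution",
    "DEFAULT_FLUX_TOL",
    "solve_fba",
    "active_reaction_set",
    "filter_gene_network_by_activity",
    "medium_reduction_trajectory",
    "mc_vs_medium_curve",
    "reaction_network_from_flux_model",
]

DEFAULT_FLUX_TOL = 1e-6
_BIG = 1e6  # default cap replacing infinite bounds for the LP


@dataclass
class FluxModel:
    """Stoichiometric model with bounds, objective and gene associations.

    ``stoichiometry`` maps reaction id -> {metabolite id: signed
    coefficient} (negative = consumed).  Exchange reactions are the
    reactions touching exactly one metabolite; by convention they are
    written in export orientation (coefficient -1), so uptake is a
    negative flux bounded below by minus the medium's uptake bound.
    """

    stoichiometry: dict[str, dict[str, float]]
    lower_bounds: dict[str, float]
    upper_bounds: dict[str, float]
    objective: str
    genes: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.objective not in self.stoichiometry:
            raise ValueError(f"biomass reaction {self.objective!r} not in model")
        for rid in self.stoichiometry:
            lb = self.lower_bounds.get(rid, 0.0)
            ub = self.upper_bounds.get(rid, _BIG)
            if lb > ub:
                raise ValueError(f"reaction {rid!r}: lower bound {lb} > upper {ub}")

    @property
    def reaction_ids(self) -> list[str]:
        return sorted(self.stoichiometry)

    @property
    def metabolite_ids(self) -> list[str]:
        mets: set[str] = set()
        for coeffs in self.stoichiometry.values():
            mets |= set(coeffs)
        return sorted(mets)

    @property
    def exchanges(self) -> set[str]:
        """Single-metabolite reactions; a single-metabolite biomass drain
        (minimal toy models) is never treated as environment-facing."""
        return {
            rid
            for rid, coeffs in self.stoichiometry.items()
            if len(coeffs) == 1 and rid != self.objective
        }


@dataclass
class MediumDefinition:
    """Uptake bounds (non-negative inflow magnitudes) per exchange reaction."""

    bounds: dict[str, float]

    def __post_init__(self) -> None:
        for ex, b in self.bounds.items():
            if b < 0:
                raise ValueError(f"uptake bound for {ex!r} must be >= 0, got {b}")

    def without(self, exchange_id: str) -> "MediumDefinition":
        return MediumDefinition(
            {ex: b for ex, b in self.bounds.items() if ex != exchange_id}
        )

    @property
    def components(self) -> list[str]:
        return sorted(ex for ex, b in self.bounds.items() if b > 0)


@dataclass
class FluxDistribution:
    fluxes: dict[str, float]
    objective_value: float
    status: str  # "optimal" | "infeasible" | "unbounded"

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _matrices(model: FluxModel) -> tuple[list[str], list[str], np.ndarray]:
    rids = model.reaction_ids
    mids = model.metabolite_ids
    midx = {m: i for i, m in enumerate(mids)}
    S = np.zeros((len(mids), len(rids)))
    for j, rid in enumerate(rids):
        for m, c in model.stoichiometry[rid].items():
            S[midx[m], j] = c
    return rids, mids, S


def _bounds_with_medium(
    model: FluxModel, medium: MediumDefinition
) -> dict[str, tuple[float, float]]:
    exchanges = model.exchanges
    unknown = set(medium.bounds) - exchanges
    if unknown:
        raise ValueError(
            "medium references non-exchange reactions: " + ", ".join(sorted(unknown))
        )
    bounds: dict[str, tuple[float, float]] = {}
    for rid in model.stoichiometry:
        lb = model.lower_bounds.get(rid, 0.0)
        ub = model.upper_bounds.get(rid, _BIG)
        if rid in exchanges:
            coef = next(iter(model.stoichiometry[rid].values()))
            uptake = medium.bounds.get(rid, 0.0)
            if coef < 0:  # export orientation: uptake is negative flux
                lb = -uptake
            else:  # import orientation: uptake is positive flux
                ub = uptake
        lb = max(lb, -_BIG) if math.isfinite(lb) else -_BIG
        ub = min(ub, _BIG) if math.isfinite(ub) else _BIG
        bounds[rid] = (lb, ub)
    return bounds


def solve_fba(
    model: FluxModel,
    medium: MediumDefinition,
    parsimonious: bool = True,
    tol: float = DEFAULT_FLUX_TOL,
) -> FluxDistribution:
    """Maximize biomass flux subject to steady state and bounds.

    The medium's uptake bounds are applied to the exchange reactions
    before solving; exchanges absent from the medium are closed for
    uptake (secretion stays open).  With ``parsimonious=True`` the
    biomass optimum is fixed and total \\|flux\\| minimized in a second
    LP, so the returned flux vector — and hence the active set — is a
    canonical choice among the alternate optima.  Only the objective
    value is guaranteed across solvers.
    """
    rids, _, S = _matrices(model)
    bound_map = _bounds_with_medium(model, medium)
    bounds = [bound_map[r] for r in rids]
    c = np.zeros(len(rids))
    c[rids.index(model.objective)] = -1.0  # linprog minimizes

    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    if res.status == 2:
        return FluxDistribution(fluxes={}, objective_value=float("nan"), status="infeasible")
    if res.status == 3:
        return FluxDistribution(fluxes={}, objective_value=float("inf"), status="unbounded")
    if res.status != 0:
        return FluxDistribution(fluxes={}, objective_value=float("nan"), status="infeasible")

    objective_value = -float(res.fun)
    v = res.x

    if parsimonious:
        n = len(rids)
        # variables [v, t], minimize sum t with t >= |v|, biomass fixed
        c2 = np.concatenate([np.zeros(n), np.ones(n)])
        A_eq = np.hstack([S, np.zeros_like(S)])
        obj_row = np.zeros(2 * n)
        obj_row[rids.index(model.objective)] = 1.0
        A_eq = np.vstack([A_eq, obj_row])
        b_eq = np.concatenate([np.zeros(S.shape[0]), [objective_value]])
        ident = np.eye(n)
        A_ub = np.vstack(
            [np.hstack([ident, -ident]), np.hstack([-ident, -ident])]
        )
        b_ub = np.zeros(2 * n)
        bounds2 = bounds + [(0.0, None)] * n
        res2 = linprog(
            c2, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds2,
            method="highs",
        )
        if res2.status == 0:
            v = res2.x[:n]

    fluxes = {rid: float(val) for rid, val in zip(rids, v)}
    return FluxDistribution(fluxes=fluxes, objective_value=objective_value, status="optimal")


def active_reaction_set(flux: FluxDistribution, tol: float = DEFAULT_FLUX_TOL) -> set[str]:
    """Reactions carrying flux above the activity threshold."""
    if not flux.optimal:
        raise ValueError(f"flux distribution is not optimal (status={flux.status!r})")
    return {rid for rid, v in flux.fluxes.items() if abs(v) > tol}


def filter_gene_network_by_activity(
    net: GeneNetwork,
    model: FluxModel,
    active: set[str],
) -> GeneNetwork:
    """Rebuild the gene network using only active reactions.

    The projection is re-run on the reaction subset, so genes attached
    only to inactive reactions disappear and gene edges that were
    mediated by an inactive reaction pair are removed.  An empty active
    set yields a valid empty network.
    """
    if net.source is None:
        raise ValueError("gene network carries no source reaction network")
    unknown = active - set(model.stoichiometry)
    if unknown:
        raise ValueError(
            "active ids not in the flux model: " + ", ".join(sorted(unknown))
        )
    kept = [r for rid, r in net.source.reactions.items() if rid in active]
    sub = build_reaction_adjacency(kept, net.source.currency_ids)
    filtered = project_to_genes(sub, net.variant, provenance=net.provenance + "|active")
    return filtered


def medium_reduction_trajectory(
    model: FluxModel,
    rich: MediumDefinition,
    seed: int = 0,
    tol: float = DEFAULT_FLUX_TOL,
) -> list[MediumDefinition]:
    """Random rich-to-minimal medium reduction.

    Starting from the rich medium, one randomly chosen removable
    component (a component whose removal keeps biomass > tol) is
    removed per step until none remains removable.  The returned
    sequence starts at the rich medium and ends at a minimal medium;
    which minimal medium is reached depends on the seed, as many
    trajectories through media space exist.
    """
    first = solve_fba(model, rich, parsimonious=False)
    if not first.optimal or first.objective_value <= tol:
        raise ValueError("rich medium does not support biomass production")

    rng = np.random.default_rng(seed)
    trajectory = [rich]
    current = rich
    while True:
        removable = []
        for comp in current.components:
            trial = current.without(comp)
            sol = solve_fba(model, trial, parsimonious=False)
            if sol.optimal and sol.objective_value > tol:
                removable.append(comp)
        if not removable:
            break
        pick = removable[rng.integers(len(removable))]
        current = current.without(pick)
        trajectory.append(current)
    return trajectory


def mc_vs_medium_curve(
    model: FluxModel,
    net: GeneNetwork,
    calls_by_background: dict[str, ExpressionCalls],
    rich: MediumDefinition,
    n_trajectories: int = 20,
    seed: int = 0,
    n_realizations: int = DEFAULT_N_REALIZATIONS,
    tol: float = DEFAULT_FLUX_TOL,
) -> pd.DataFrame:
    """Mean +/- sd of MC per medium-reduction step and background.

    For each trajectory and step the medium is solved (parsimonious
    FBA), the active set extracted, the gene network filtered to active
    reactions, and the MC recomputed per background.  Steps are indexed
    from the rich end; trajectories of unequal length contribute only
    to the steps they possess, with the per-step n reported.
    Backgrounds whose effective set empties at some step are recorded
    as NaN for that step.
    """
    rows = []
    for j in range(n_trajectories):
        traj_seed = int(
            np.random.SeedSequence((seed, 0x7261, j)).generate_state(1)[0] % 2**31
        )
        trajectory = medium_reduction_trajectory(model, rich, seed=traj_seed, tol=tol)
        for step, medium in enumerate(trajectory):
            sol = solve_fba(model, medium, parsimonious=True, tol=tol)
            active = active_reaction_set(sol, tol=tol)
            filtered = filter_gene_network_by_activity(net, model, active)
            for background, calls in calls_by_background.items():
                mc_seed = int(
                    np.random.SeedSequence((seed, 0x6D63, j, step)).generate_state(1)[0]
                    % 2**31
                )
                try:
                    res = mc_zscore(
                        filtered, calls, n_realizations=n_realizations, seed=mc_seed
                    )
                    mc = res.mc_zscore
                except ValueError:
                    mc = float("nan")
                rows.append(
                    {"trajectory": j, "step": step, "background": background, "mc": mc}
                )

    raw = pd.DataFrame(rows)
    curve = (
        raw.groupby(["step", "background"])["mc"]
        .agg(mean_mc="mean", sd_mc="std", n="count")
        .reset_index()
    )
    curve["sd_mc"] = curve["sd_mc"].fillna(0.0)
    return curve


def reaction_network_from_flux_model(
    model: FluxModel,
    currency_ids: set[str] | None = None,
) -> ReactionNetwork:
    """Derive a reaction-centric network from a stoichiometric model.

    Substrates/products are read from the coefficient signs; a reaction
    is treated as reversible when its lower bound is negative.
    Exchange reactions participate like any other reaction (they rarely
    carry genes, so they drop out of the gene projection anyway).
    """
    reactions = []
    for rid in model.reaction_ids:
        coeffs = model.stoichiometry[rid]
        subs = frozenset(m for m, c in coeffs.items() if c < 0)
        prods = frozenset(m for m, c in coeffs.items() if c > 0)
        reactions.append(
            Reaction(
                id=rid,
                substrates=subs,
                products=prods,
                reversible=model.lower_bounds.get(rid, 0.0) < 0,
                genes=model.genes.get(rid, frozenset()),
            )
        )
    return build_reaction_adjacency(reactions, currency_ids or set())
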