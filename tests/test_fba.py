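import itertools
import math

import numpy as np
import pytest

from metcoherence.fba import (
    FluxModel,
    MediumDefinition,
    active_reaction_set,
    filter_gene_network_by_activity,
    mc_vs_medium_curve,
    medium_reduction_trajectory,
    reaction_network_from_flux_model,
    solve_fba,
)
from metcoherence.network import project_to_genes
from metcoherence.synthetic import generate_toy_fba_model, plant_coherent_expression

from conftest import calls_for


def toy_linear_model(uptake_ub=10.0):
    """EX_A (uptake <= 10) -> A -> B -> biomass."""
    return FluxModel(
        stoichiometry={
            "EX_A": {"A": -1.0},
            "AB": {"A": -1.0, "B": 1.0},
            "BIOMASS": {"B": -1.0},
        },
        lower_bounds={"EX_A": 0.0, "AB": 0.0, "BIOMASS": 0.0},
        upper_bounds={"EX_A": 1000.0, "AB": 1000.0, "BIOMASS": 1000.0},
        objective="BIOMASS",
        genes={"AB": frozenset({"gAB"})},
    )


def brute_force_lp_max(model, medium):
    """Vertex-enumeration oracle for max biomass on tiny models.

    Enumerates every choice of variables pinned to a bound, solves the
    remaining square/overdetermined steady-state system, keeps feasible
    vertices and returns the best objective.
    """
    from metcoherence.fba import _bounds_with_medium, _matrices

    rids, _, S = _matrices(model)
    bound_map = _bounds_with_medium(model, medium)
    n = len(rids)
    obj_idx = rids.index(model.objective)
    best = None
    for pinned in itertools.product([None, "lb", "ub"], repeat=n):
        free = [j for j in range(n) if pinned[j] is None]
        v = np.zeros(n)
        for j, kind in enumerate(pinned):
            if kind is not None:
                v[j] = bound_map[rids[j]][0 if kind == "lb" else 1]
        if free:
            A = S[:, free]
            b = -S[:, [j for j in range(n) if pinned[j] is not None]] @ v[
                [j for j in range(n) if pinned[j] is not None]
            ]
            sol, residuals, rank, _ = np.linalg.lstsq(A, b, rcond=None)
            if rank < len(free):
                continue  # not a vertex: underdetermined free block
            v[free] = sol
        if np.max(np.abs(S @ v)) > 1e-8:
            continue
        ok = all(
            bound_map[rids[j]][0] - 1e-9 <= v[j] <= bound_map[rids[j]][1] + 1e-9
            for j in range(n)
        )
        if ok and (best is None or v[obj_idx] > best):
            best = v[obj_idx]
    return best


class TestSolveFBA:
    def test_linear_chain_hand_optimum(self):
        model = toy_linear_model()
        sol = solve_fba(model, MediumDefinition({"EX_A": 10.0}))
        assert sol.optimal
        assert sol.objective_value == pytest.approx(10.0)
        assert sol.fluxes["EX_A"] == pytest.approx(-10.0)
        assert sol.fluxes["AB"] == pytest.approx(10.0)

    def test_steady_state_and_bounds_respected(self):
        model, rich, _ = generate_toy_fba_model()
        sol = solve_fba(model, rich)
        from metcoherence.fba import _bounds_with_medium, _matrices
        rids, _, S = _matrices(model)
        v = np.asarray([sol.fluxes[r] for r in rids])
        assert np.max(np.abs(S @ v)) < 1e-7
        bound_map = _bounds_with_medium(model, rich)
        for r in rids:
            lo, hi = bound_map[r]
            assert lo - 1e-7 <= sol.fluxes[r] <= hi + 1e-7

    def test_closed_medium_gives_zero_biomass(self):
        model = toy_linear_model()
        sol = solve_fba(model, MediumDefinition({}))
        assert sol.optimal
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_reported(self):
        model = toy_linear_model()
        model.lower_bounds["BIOMASS"] = 20.0  # demands more than uptake allows
        model.upper_bounds["BIOMASS"] = 30.0
        sol = solve_fba(model, MediumDefinition({"EX_A": 10.0}))
        assert sol.status == "infeasible"
        assert sol.fluxes == {}

    def test_parallel_routes_objective_contracted(self):
        model = FluxModel(
            stoichiometry={
                "EX_A": {"A": -1.0},
                "R1": {"A": -1.0, "B": 1.0},
                "R2": {"A": -1.0, "B": 1.0},
                "BIOMASS": {"B": -1.0},
            },
            lower_bounds={r: 0.0 for r in ["EX_A", "R1", "R2", "BIOMASS"]},
            upper_bounds={"EX_A": 1000.0, "R1": 6.0, "R2": 6.0, "BIOMASS": 1000.0},
            objective="BIOMASS",
        )
        sol = solve_fba(model, MediumDefinition({"EX_A": 10.0}))
        assert sol.objective_value == pytest.approx(10.0)  # 6 + 4 split, any way

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_vertex_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # tiny random chain with branch: <= 6 reactions
        ub_ex = float(rng.uniform(2, 10))
        cap = float(rng.uniform(1, 8))
        model = FluxModel(
            stoichiometry={
                "EX_A": {"A": -1.0},
                "R1": {"A": -1.0, "B": 1.0},
                "R2": {"A": -1.0, "C": 1.0},
                "R3": {"C": -1.0, "B": 1.0},
                "BIOMASS": {"B": -1.0},
            },
            lower_bounds={r: 0.0 for r in ["EX_A", "R1", "R2", "R3", "BIOMASS"]},
            upper_bounds={"EX_A": 1000.0, "R1": cap, "R2": 1000.0, "R3": 1000.0,
                          "BIOMASS": 1000.0},
            objective="BIOMASS",
        )
        medium = MediumDefinition({"EX_A": ub_ex})
        sol = solve_fba(model, medium)
        oracle = brute_force_lp_max(model, medium)
        assert sol.objective_value == pytest.approx(oracle, abs=1e-6)

    def test_agrees_with_cobra_on_toy_model(self):
        cobra = pytest.importorskip("cobra")
        model, rich, truth = generate_toy_fba_model()
        cm = cobra.Model("toy")
        mets = {m: cobra.Metabolite(m) for m in model.metabolite_ids}
        from metcoherence.fba import _bounds_with_medium
        bound_map = _bounds_with_medium(model, rich)
        for rid in model.reaction_ids:
            rxn = cobra.Reaction(rid)
            cm.add_reactions([rxn])
            rxn.add_metabolites({mets[m]: c for m, c in model.stoichiometry[rid].items()})
            rxn.lower_bound, rxn.upper_bound = bound_map[rid]
        cm.objective = "BIOMASS"
        expected = cm.optimize().objective_value
        sol = solve_fba(model, rich)
        assert sol.objective_value == pytest.approx(expected, abs=1e-6)
        assert sol.objective_value == pytest.approx(truth["optimum"], abs=1e-6)


class TestActiveSet:
    def test_hand_toy_active_reactions(self):
        model = toy_linear_model()
        sol = solve_fba(model, MediumDefinition({"EX_A": 10.0}))
        assert active_reaction_set(sol) == {"EX_A", "AB", "BIOMASS"}

    def test_large_tolerance_empties_set(self):
        model = toy_linear_model()
        sol = solve_fba(model, MediumDefinition({"EX_A": 10.0}))
        assert active_reaction_set(sol, tol=1e6) == set()

    def test_zero_flux_reaction_excluded(self):
        model = toy_linear_model()
        model.stoichiometry["DEAD"] = {"A": -1.0, "D": 1.0}
        model.stoichiometry["EX_D"] = {"D": -1.0}
        model.lower_bounds.update({"DEAD": 0.0, "EX_D": 0.0})
        model.upper_bounds.update({"DEAD": 1000.0, "EX_D": 0.0})
        sol = solve_fba(model, MediumDefinition({"EX_A": 10.0}))
        assert "DEAD" not in active_reaction_set(sol)

    def test_non_optimal_rejected(self):
        model = toy_linear_model()
        model.lower_bounds["BIOMASS"] = 20.0
        model.upper_bounds["BIOMASS"] = 30.0
        sol = solve_fba(model, MediumDefinition({"EX_A": 10.0}))
        with pytest.raises(ValueError, match="not optimal"):
            active_reaction_set(sol)


class TestActivityFilter:
    def test_all_active_is_identity(self):
        model, rich, _ = generate_toy_fba_model()
        net = project_to_genes(reaction_network_from_flux_model(model))
        filtered = filter_gene_network_by_activity(
            net, model, set(model.stoichiometry))
        assert filtered.nodes == net.nodes
        assert filtered.edges == net.edges

    def test_inactive_middle_reaction_breaks_gene_edge(self):
        model, rich, _ = generate_toy_fba_model(n_nutrients=2, n_internal=3)
        net = project_to_genes(reaction_network_from_flux_model(model))
        active = set(model.stoichiometry) - {"C2"}  # cut the chain's middle
        filtered = filter_gene_network_by_activity(net, model, active)
        g1 = next(iter(model.genes["C1"]))
        g2 = next(iter(model.genes["C2"]))
        g3 = next(iter(model.genes["C3"]))
        assert (g1, g2) in net.edges and (g2, g3) in net.edges
        assert (g1, g2) not in filtered.edges
        assert g2 not in filtered.nodes
        assert (g1, g3) not in filtered.edges  # no shortcut across the gap

    def test_fba_active_filter_matches_manual_projection(self):
        model, rich, _ = generate_toy_fba_model()
        net = project_to_genes(reaction_network_from_flux_model(model))
        sol = solve_fba(model, rich)
        active = active_reaction_set(sol)
        filtered = filter_gene_network_by_activity(net, model, active)
        manual_net = reaction_network_from_flux_model(model)
        kept = [r for rid, r in manual_net.reactions.items() if rid in active]
        from metcoherence.network import build_reaction_adjacency
        expected = project_to_genes(build_reaction_adjacency(kept), net.variant)
        assert filtered.edges == expected.edges
        assert filtered.nodes == expected.nodes

    def test_empty_active_set_gives_empty_network(self):
        model, _, _ = generate_toy_fba_model()
        net = project_to_genes(reaction_network_from_flux_model(model))
        filtered = filter_gene_network_by_activity(net, model, set())
        assert filtered.nodes == set() and filtered.edges == set()

    def test_unknown_active_id_rejected(self):
        model, _, _ = generate_toy_fba_model()
        net = project_to_genes(reaction_network_from_flux_model(model))
        with pytest.raises(ValueError, match="not in the flux model"):
            filter_gene_network_by_activity(net, model, {"NOPE"})


class TestMediumReduction:
    def test_essential_nutrient_never_removed(self):
        model, rich, truth = generate_toy_fba_model()
        for seed in range(5):
            traj = medium_reduction_trajectory(model, rich, seed=seed)
            final = traj[-1]
            for ess in truth["essential_nutrients"]:
                assert ess in final.components

    def test_exactly_one_substitutable_survives_and_seed_dependent(self):
        model, rich, truth = generate_toy_fba_model()
        survivors = set()
        for seed in range(12):
            final = medium_reduction_trajectory(model, rich, seed=seed)[-1]
            kept = set(final.components) & set(truth["substitutable_nutrients"])
            assert len(kept) == 1
            survivors |= kept
        assert len(survivors) == 2  # both outcomes occur over seeds

    def test_minimality_verified_post_hoc(self):
        model, rich, _ = generate_toy_fba_model()
        traj = medium_reduction_trajectory(model, rich, seed=3)
        for medium in traj:
            sol = solve_fba(model, medium, parsimonious=False)
            assert sol.optimal and sol.objective_value > 1e-6
        final = traj[-1]
        for comp in final.components:
            sol = solve_fba(model, final.without(comp), parsimonious=False)
            assert not (sol.optimal and sol.objective_value > 1e-6)

    def test_no_removable_components_trajectory_length_one(self):
        model, rich, truth = generate_toy_fba_model()
        minimal = medium_reduction_trajectory(model, rich, seed=0)[-1]
        again = medium_reduction_trajectory(model, minimal, seed=1)
        assert len(again) == 1
        assert again[0].bounds == minimal.bounds

    def test_infeasible_rich_medium_rejected(self):
        model, _, _ = generate_toy_fba_model()
        with pytest.raises(ValueError, match="rich medium"):
            medium_reduction_trajectory(model, MediumDefinition({}), seed=0)

    def test_active_gene_count_grows_as_medium_shrinks(self):
        """Fewer nutrients force longer internal routes into activity."""
        model, rich, _ = generate_toy_fba_model(n_nutrients=6, n_internal=4)
        net = project_to_genes(reaction_network_from_flux_model(model))
        traj = medium_reduction_trajectory(model, rich, seed=2)
        counts = []
        for medium in traj:
            sol = solve_fba(model, medium)
            filtered = filter_gene_network_by_activity(
                net, model, active_reaction_set(sol))
            counts.append(len(filtered.nodes))
        assert counts[-1] >= counts[0]


class TestMediumCurve:
    def test_single_trajectory_of_length_one_matches_rich_mc(self):
        model, rich, _ = generate_toy_fba_model()
        minimal = medium_reduction_trajectory(model, rich, seed=0)[-1]
        net = project_to_genes(reaction_network_from_flux_model(model))
        genes = sorted(net.nodes)
        calls = calls_for(set(genes[:4]), universe=net.nodes)
        curve = mc_vs_medium_curve(
            model, net, {"wt": calls}, minimal,
            n_trajectories=1, seed=5, n_realizations=200,
        )
        assert len(curve) == 1
        row = curve.iloc[0]
        assert row["step"] == 0 and row["n"] == 1 and row["sd_mc"] == 0.0

    def test_fixed_seed_bit_identical(self):
        model, rich, _ = generate_toy_fba_model()
        net = project_to_genes(reaction_network_from_flux_model(model))
        genes = sorted(net.nodes)
        calls = {"wt": calls_for(set(genes[:4]), universe=net.nodes)}
        a = mc_vs_medium_curve(model, net, calls, rich,
                               n_trajectories=3, seed=9, n_realizations=100)
        b = mc_vs_medium_curve(model, net, calls, rich,
                               n_trajectories=3, seed=9, n_realizations=100)
        assert a.equals(b)

    def test_planted_wildtype_above_random_mutant_at_rich_end(self):
        model, rich, _ = generate_toy_fba_model(n_nutrients=6, n_internal=10)
        net = project_to_genes(reaction_network_from_flux_model(model))
        k = 8
        wt = plant_coherent_expression(net, k=k, p=1.0, seed=1, background="wt")
        mut = plant_coherent_expression(net, k=k, p=0.0, seed=1, background="mut")
        curve = mc_vs_medium_curve(
            model, net, {"wt": wt, "mut": mut}, rich,
            n_trajectories=5, seed=2, n_realizations=300,
        )
        rich_end = curve[curve["step"] == 0].set_index("background")["mean_mc"]
        assert rich_end["wt"] > rich_end["mut"]
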