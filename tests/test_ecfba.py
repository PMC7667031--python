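"""Enzyme-constrained FBA: model assembly, constraints, NGAM solves."""

import numpy as np
import pandas as pd
import pytest

import omniflux as om
from omniflux.ecfba import EnzymeInfo, MetabolicNetwork, Reaction
from omniflux.errors import ArgumentError, DataError, ModelConstructionError
from omniflux.simulate import enzyme_abundance_matrix
from omniflux.verify import enumerate_objective, max_violation


def inert_growth(met="x"):
    """NGAM/biomass pair pinned to zero, to satisfy the network invariants."""
    return [Reaction("NGAM", {met: -1.0}, 0, 0, role="ngam"),
            Reaction("BIOMASS", {met: -1.0}, 0, 0, role="biomass")]


def single_enzyme_net(kcat=10.0, mw=50.0, ub=1000.0):
    """One enzymatic conversion between external pools; no internal balance."""
    return MetabolicNetwork(
        {"x": True},
        [Reaction("R", {}, 0, ub), *inert_growth()],
        {"R": EnzymeInfo("E_R", kcat, mw)},
    )


class TestBuildEcModel:
    def test_one_enzyme_pool_algebra(self):
        """Max flux = kcat * pool / MW when only the pool limits."""
        kcat, mw = 10.0, 50.0
        net = single_enzyme_net(kcat, mw)
        model = om.build_ec_model(net, p_total=0.5, f=0.5, sigma=0.5)
        sol = om.fba(model, "R", "max")
        assert sol.objective_value == pytest.approx(kcat * model.pool_cap / mw, rel=1e-9)

    def test_zero_f_silences_enzymatic_flux(self):
        model = om.build_ec_model(single_enzyme_net(), p_total=0.5, f=0.0, sigma=0.5)
        sol = om.fba(model, "R", "max")
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_constraint_matrix_matches_hand_assembly(self):
        """Entrywise comparison with an independently written dense oracle."""
        net = MetabolicNetwork(
            {"a": True, "b": True},
            [Reaction("EX_a", {"a": 1.0}, 0, 5),
             Reaction("R1", {"a": -1.0, "b": 2.0}, 0, 8),
             Reaction("EX_b", {"b": -1.0}, 0, 9),
             *inert_growth(met="a")],
            {"R1": EnzymeInfo("E1", kcat=4.0, mw=25.0)},
        )
        model = om.build_ec_model(net, p_total=1.0, f=0.5, sigma=0.5)
        A_eq, b_eq, A_ub, b_ub, bounds = model.to_lp()
        # vars: EX_a, R1, EX_b, NGAM, BIOMASS, E1
        expected_eq = np.array([
            [1.0, -1.0, 0.0, -1.0, -1.0, 0.0],   # a
            [0.0, 2.0, -1.0, 0.0, 0.0, 0.0],     # b
        ])
        expected_ub = np.array([
            [0.0, 1.0, 0.0, 0.0, 0.0, -4.0],     # coupling v_R1 <= 4 e
            [0.0, 0.0, 0.0, 0.0, 0.0, 25.0],     # pool
        ])
        assert np.array_equal(A_eq, expected_eq) and np.array_equal(b_eq, [0, 0])
        assert np.array_equal(A_ub, expected_ub)
        assert np.allclose(b_ub, [0.0, 0.25])
        assert bounds[0] == (0, 5) and bounds[1] == (0, 8)
        assert bounds[5] == (0.0, 0.25 / 25.0)

    def test_missing_kcat_invariants_enforced(self):
        with pytest.raises(ModelConstructionError):
            EnzymeInfo("E", kcat=0.0, mw=10.0)
        with pytest.raises(ModelConstructionError):
            MetabolicNetwork({"a": True}, [Reaction("R", {"a": 1.0})], {})

    def test_reversible_enzymatic_reaction_split(self):
        net = MetabolicNetwork(
            {"a": True, "b": True},
            [Reaction("EX_a", {"a": 1.0}, 0, 5),
             Reaction("R1", {"a": -1.0, "b": 1.0}, -3, 8, reversible=True),
             Reaction("EX_b", {"b": -1.0}, 0, 9),
             *inert_growth(met="a")],
            {"R1": EnzymeInfo("E1", kcat=4.0, mw=25.0)},
        )
        model = om.build_ec_model(net, p_total=1.0, f=0.5, sigma=0.5)
        directions = [v.direction for v in model.vars
                      if v.kind == "flux" and v.rxn_id == "R1"]
        assert sorted(directions) == [-1, 1]
        # both halves coupled to the same enzyme
        assert all(v.enzyme_id == "E1" for v in model.vars
                   if v.kind == "flux" and v.rxn_id == "R1")


class TestApplyProteomics:
    def test_tightening_never_increases_objective(self, toy):
        model = om.build_ec_model(toy.network, p_total=toy.config.p_total)
        base = om.fba(model, "NGAM", "max").objective_value
        usage = om.fba(model, "NGAM", "max").enzyme_usage
        eid = "E_GLY"
        cap = pd.DataFrame({"s": [usage[eid] * 0.5]}, index=[eid])
        capped = om.apply_proteomics(
            model, om.AbundanceMatrix(cap, "protein", "mmol_per_gDCW"), "s")
        tightened = om.fba(capped, "NGAM", "max").objective_value
        assert tightened <= base + 1e-9

    def test_zero_abundance_on_sole_path_starves_growth(self, toy):
        model = om.build_ec_model(toy.network, p_total=toy.config.p_total)
        cap = pd.DataFrame({"s": [0.0]}, index=["E_GLY"])
        capped = om.apply_proteomics(
            model, om.AbundanceMatrix(cap, "protein", "mmol_per_gDCW"), "s")
        sol = om.solve_ngam(capped, 0.1)
        assert sol.status == "infeasible" or sol.objective_value <= 1e-9

    def test_truth_fluxes_stay_feasible_under_truth_bounds(self, toy):
        """Direct substitution of the generator's reference state."""
        model = om.build_ec_model(toy.network, p_total=toy.config.p_total)
        proteome = enzyme_abundance_matrix(toy)
        for (strain, d), cond in toy.conditions.items():
            m = om.apply_proteomics(model, proteome, f"{strain}_{d:g}")
            sol = om.FluxSolution("optimal", cond.ngam, cond.fluxes,
                                  cond.enzyme_abundance)
            assert max_violation(m, sol) < 1e-8

    def test_molecules_per_cell_units_convert(self, toy):
        model = om.build_ec_model(toy.network, p_total=toy.config.p_total)
        # 6.022e6 molecules/cell * 5e10 cells/gDCW / N_A * 1e3 = 5e-4 mmol/gDCW
        cap = pd.DataFrame({"s": [6.02214076e6]}, index=["E_GLY"])
        capped = om.apply_proteomics(
            model, om.AbundanceMatrix(cap, "protein", "molecules_per_cell"), "s")
        j = capped._enzyme_var_index("E_GLY")
        assert capped.vars[j].ub == pytest.approx(5e-4, rel=1e-9)


class TestExchangeConstraints:
    def test_flex_window_arithmetic(self, toy):
        model = om.build_ec_model(toy.network, p_total=toy.config.p_total)
        rates = pd.DataFrame([{"reaction_id": "EX_etoh", "rate": 2.0,
                               "direction": "secretion"}])
        out = om.apply_exchange_constraints(model, rates, flex=1.03)
        j = out._flux_var_indices("EX_etoh")[0]
        assert out.vars[j].lb == pytest.approx(2.0 / 1.03)
        assert out.vars[j].ub == pytest.approx(2.06)

    def test_rigid_flex_pins_exactly(self, toy):
        model = om.build_ec_model(toy.network, p_total=toy.config.p_total)
        rates = pd.DataFrame([{"reaction_id": "EX_glc", "rate": 1.5,
                               "direction": "uptake"}])
        out = om.apply_exchange_constraints(model, rates, flex=1.0)
        j = out._flux_var_indices("EX_glc")[0]
        assert out.vars[j].lb == out.vars[j].ub == pytest.approx(1.5)

    def test_unknown_reaction_rejected(self, toy):
        model = om.build_ec_model(toy.network, p_total=toy.config.p_total)
        rates = pd.DataFrame([{"reaction_id": "EX_ghost", "rate": 1.0,
                               "direction": "uptake"}])
        with pytest.raises(DataError):
            om.apply_exchange_constraints(model, rates)

    def test_solution_exchanges_stay_in_flex_window(self, toy):
        model = om.build_ec_model(toy.network, p_total=toy.config.p_total)
        proteome = enzyme_abundance_matrix(toy)
        (strain, d), cond = next(iter(toy.conditions.items()))
        m = om.apply_proteomics(model, proteome, f"{strain}_{d:g}")
        m = om.apply_exchange_constraints(m, cond.measured_rates, flex=1.03)
        sol = om.solve_ngam(m, d)
        assert sol.status == "optimal"
        for _, row in cond.measured_rates.iterrows():
            v = sol.fluxes[row["reaction_id"]]
            assert row["rate"] / 1.03 - 1e-9 <= v <= row["rate"] * 1.03 + 1e-9


class TestSolveNgam:
    def chain_model(self, q=2.0, y=3.0, flex=1.0):
        net = MetabolicNetwork(
            {"s": True, "atp": True},
            [Reaction("UPT", {"s": 1.0}, 0, 10, role="exchange"),
             Reaction("SYN", {"s": -1.0, "atp": y}),
             Reaction("NGAM", {"atp": -1.0}, 0, 100, role="ngam"),
             Reaction("BIOMASS", {}, 0, 10, role="biomass")],
        )
        model = om.build_ec_model(net, p_total=0.5)
        rates = pd.DataFrame([{"reaction_id": "UPT", "rate": q, "direction": "uptake"}])
        return om.apply_exchange_constraints(model, rates, flex=flex)

    def test_single_path_closed_form(self):
        """All ATP from the uptake window's upper edge ends in maintenance."""
        sol = om.solve_ngam(self.chain_model(q=2.0, y=3.0, flex=1.03), 0.1)
        assert sol.objective_value == pytest.approx(2.0 * 1.03 * 3.0, rel=1e-9)

    def test_starvation_infeasible_or_zero(self, toy):
        model = om.build_ec_model(toy.network, p_total=toy.config.p_total)
        model.set_flux_bounds("EX_glc", 0.0, 0.0)
        sol = om.solve_ngam(model, 0.1)
        assert sol.status == "infeasible" or sol.objective_value <= 1e-9
        if sol.status == "infeasible":
            assert "growth" in sol.message

    def test_truth_implied_constraints_recover_ngam_exactly(self, toy):
        """flex=1 plus truth proteomics pins NGAM to the generated truth."""
        model = om.build_ec_model(toy.network, p_total=toy.config.p_total)
        proteome = enzyme_abundance_matrix(toy)
        for (strain, d), cond in toy.conditions.items():
            m = om.apply_proteomics(model, proteome, f"{strain}_{d:g}")
            m = om.apply_exchange_constraints(m, cond.measured_rates, flex=1.0)
            sol = om.solve_ngam(m, d)
            assert sol.status == "optimal"
            assert sol.objective_value == pytest.approx(cond.ngam, abs=1e-6)

    def test_relaxation_monotonicity(self, toy):
        model = om.build_ec_model(toy.network, p_total=toy.config.p_total)
        proteome = enzyme_abundance_matrix(toy)
        (strain, d), cond = next(iter(toy.conditions.items()))
        m = om.apply_proteomics(model, proteome, f"{strain}_{d:g}")
        m1 = om.apply_exchange_constraints(m, cond.measured_rates, flex=1.0)
        m2 = om.apply_exchange_constraints(m, cond.measured_rates, flex=1.1)
        v1 = om.solve_ngam(m1, d).objective_value
        v2 = om.solve_ngam(m2, d).objective_value
        assert v2 >= v1 - 1e-9

    def test_efficient_strain_has_lower_ngam(self, toy):
        """Directional analogue of the figure: the low-waste evolved strain
        spends the least maintenance energy at both dilution rates."""
        model = om.build_ec_model(toy.network, p_total=toy.config.p_total)
        proteome = enzyme_abundance_matrix(toy)
        ngam = {}
        for (strain, d), cond in toy.conditions.items():
            m = om.apply_proteomics(model, proteome, f"{strain}_{d:g}")
            m = om.apply_exchange_constraints(m, cond.measured_rates, flex=1.03)
            ngam[(strain, d)] = om.solve_ngam(m, d).objective_value
        for d in (0.1, 0.2):
            assert ngam[("B184", d)] < ngam[("MH34", d)]
            assert ngam[("B184", d)] < ngam[("AAC", d)]


class TestFba:
    def test_bound_attained_optimum(self):
        net = MetabolicNetwork(
            {"x": True},
            [Reaction("FREE", {}, 0, 5), *inert_growth()],
        )
        model = om.build_ec_model(net, p_total=0.5)
        assert om.fba(model, "FREE", "max").objective_value == pytest.approx(5.0)
        assert om.fba(model, "FREE", "min").objective_value == pytest.approx(0.0)

    def test_matches_vertex_enumeration_on_random_networks(self):
        for seed in range(8):
            net, pool = om.random_small_network(seed)
            model = om.EcModel(net, pool_cap=pool)
            sol = om.fba(model, "NGAM", "max")
            oracle = enumerate_objective(model, "NGAM", "max")
            assert oracle is not None and sol.status == "optimal"
            assert sol.objective_value == pytest.approx(oracle, abs=1e-7)
            assert max_violation(model, sol) < 1e-8

    def test_optimal_solutions_satisfy_steady_state(self, toy):
        model = om.build_ec_model(toy.network, p_total=toy.config.p_total)
        from omniflux.simulate import stoichiometric_matrix
        s, rxn_ids = stoichiometric_matrix(toy.network)
        for objective in ("NGAM", "EX_amy", "BIOMASS"):
            sol = om.fba(model, objective, "max")
            v = sol.fluxes.loc[rxn_ids].to_numpy()
            assert np.abs(s @ v).max() < 1e-8

    def test_invalid_sense_rejected(self, toy):
        model = om.build_ec_model(toy.network, p_total=0.5)
        with pytest.raises(ArgumentError):
            om.fba(model, "NGAM", "biggest")


def test_agrees_with_cobra_on_toy_model(toy):
    """Independent cross-check: the same ec-LP assembled in cobrapy."""
    cobra = pytest.importorskip("cobra")
    model = om.build_ec_model(toy.network, p_total=toy.config.p_total)
    proteome = enzyme_abundance_matrix(toy)
    (strain, d), cond = next(iter(toy.conditions.items()))
    m = om.apply_proteomics(model, proteome, f"{strain}_{d:g}")
    m = om.apply_exchange_constraints(m, cond.measured_rates, flex=1.03)
    ours = om.solve_ngam(m, d).objective_value

    cm = cobra.Model("ec_toy")
    mets = {mid: cobra.Metabolite(mid) for mid in toy.network.internal_metabolites}
    pool = cobra.Metabolite("enzyme_pool")
    src = cobra.Reaction("pool_source")
    src.add_metabolites({pool: 1.0})
    src.bounds = (0, m.pool_cap)
    cm.add_reactions([src])
    enzyme_mets = {}
    for rid, info in toy.network.enzymes.items():
        em = cobra.Metabolite(f"enz_{info.enzyme_id}")
        enzyme_mets[rid] = em
        draw = cobra.Reaction(f"draw_{info.enzyme_id}")
        draw.add_metabolites({pool: -info.mw, em: 1.0})
        draw.bounds = (0, m.vars[m._enzyme_var_index(info.enzyme_id)].ub)
        cm.add_reactions([draw])
    for rxn in toy.network.reactions:
        cr = cobra.Reaction(rxn.id)
        cr.add_metabolites({mets[k]: v for k, v in rxn.stoichiometry.items()})
        j = m._flux_var_indices(rxn.id)[0]
        cr.bounds = (m.vars[j].lb, m.vars[j].ub)
        if rxn.id == "BIOMASS":
            cr.bounds = (d, d)
        if rxn.id in toy.network.enzymes:
            cr.add_metabolites({enzyme_mets[rxn.id]: -1.0 / toy.network.enzymes[rxn.id].kcat})
        cm.add_reactions([cr])
    cm.objective = "NGAM"
    theirs = cm.optimize().objective_value
    assert ours == pytest.approx(theirs, rel=1e-6)
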