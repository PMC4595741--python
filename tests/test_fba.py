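import numpy as np
import pytest

from chlorofba.fba import (INFEASIBLE, OPTIMAL, RatioConstraint, SUPPORT_TOL,
                           UnknownReactionError, add_ratio_constraint,
                           build_total_flux_lp, minimize_total_flux, solve_lp)
from chlorofba.fixture import generate_synthetic_network
from chlorofba.model import (MetabolicModel, Metabolite, Reaction,
                             build_stoichiometric_matrix)
from oracles import brute_force_min_total_flux


def _toy(reactions, reversible=()):
    m = MetabolicModel("toy", compartments=("cytosol", "external"))
    mets = {met for _, r in reactions for met in r}
    for met in sorted(mets):
        m.add_metabolite(Metabolite(
            met, "external" if met.startswith("x_") else "cytosol"))
    for rid, stoich in reactions:
        m.add_reaction(Reaction(rid, stoich,
                                lb=-1000.0 if rid in reversible else 0.0))
    return m


@pytest.fixture
def chain():
    return _toy([("imp", {"x_A": -1, "A": 1}),
                 ("conv", {"A": -1, "B": 1}),
                 ("exp", {"B": -1, "x_B": 1})])


@pytest.fixture
def diamond():
    return _toy([("imp", {"x_A": -1, "A": 1}),
                 ("b1", {"A": -1, "B": 1}),
                 ("b2", {"A": -1, "B": 1}),
                 ("exp", {"B": -1, "x_B": 1})])


class TestMinimizeTotalFlux:
    def test_single_path_unit_demand(self, chain):
        sol = minimize_total_flux(chain, fixed={"exp": 1.0})
        assert sol.status == OPTIMAL
        assert sol.objective == pytest.approx(3.0, abs=1e-9)
        assert all(v == pytest.approx(1.0, abs=1e-9) for v in sol.fluxes.values())

    def test_blocked_chain_is_infeasible(self, chain):
        sol = minimize_total_flux(chain, fixed={"exp": 1.0}, blocked={"conv"})
        assert sol.status == INFEASIBLE
        assert not sol.fluxes

    def test_unknown_ids_raise(self, chain):
        with pytest.raises(UnknownReactionError):
            minimize_total_flux(chain, fixed={"nope": 1.0})
        with pytest.raises(UnknownReactionError):
            minimize_total_flux(chain, blocked={"nope"})

    def test_fixed_value_outside_bounds_rejected(self, chain):
        with pytest.raises(ValueError, match="outside bounds"):
            minimize_total_flux(chain, fixed={"exp": -5.0})

    def test_mass_balance_residual(self, leaf_model, case1_solution):
        S = build_stoichiometric_matrix(leaf_model)
        v = np.array([case1_solution.fluxes[r] for r in leaf_model.reactions])
        assert np.max(np.abs(S @ v)) <= 1e-6

    def test_objective_equals_total_absolute_flux(self, case1_solution):
        total = sum(abs(v) for v in case1_solution.fluxes.values())
        assert case1_solution.objective == pytest.approx(total, abs=1e-6)

    def test_oxygenase_idle_without_coupling(self, leaf_model):
        """Left uncoupled, the flux-minimal solution never runs the
        oxygenase: photorespiration only wastes carbon and flux."""
        sol = minimize_total_flux(leaf_model, fixed={"chlorophyll_tx": 1.0})
        assert sol.status == OPTIMAL
        assert abs(sol.fluxes["chl_RuBisCO_oxy"]) <= SUPPORT_TOL

    def test_objective_monotone_under_extra_constraints(self, leaf_model):
        base = minimize_total_flux(leaf_model, fixed={"chlorophyll_tx": 1.0})
        harder = [
            minimize_total_flux(leaf_model, fixed={"chlorophyll_tx": 1.0},
                                blocked={"chl_RuBisCO_oxy"}),
            minimize_total_flux(leaf_model,
                                fixed={"chlorophyll_tx": 1.0, "NH_3__tx": 4.0}),
            minimize_total_flux(leaf_model, fixed={"chlorophyll_tx": 1.0},
                                ratios=(RatioConstraint(
                                    "chl_RuBisCO_carb", "chl_RuBisCO_oxy", 3.0),)),
        ]
        for sol in harder:
            assert sol.status == OPTIMAL
            assert sol.objective >= base.objective - 1e-9

    @pytest.mark.parametrize("seed", range(12))
    def test_orthant_oracle_agreement(self, seed):
        """On small random networks the split-variable LP matches an
        orthant-enumeration minimizer built independently of it."""
        net = generate_synthetic_network(n_metabolites=4, n_reactions=7,
                                         n_parallel_paths=2, seed=seed)
        sol = minimize_total_flux(net.model, fixed={net.demand: 1.0})
        status, z, _ = brute_force_min_total_flux(net.model,
                                                  fixed={net.demand: 1.0})
        assert sol.status == OPTIMAL and status == "optimal"
        assert sol.objective == pytest.approx(z, abs=1e-6)


class TestSolveLP:
    def test_simple_bound(self):
        m = _toy([("imp", {"x_A": -1, "A": 1}), ("exp", {"A": -1, "x_B": 1})])
        m.reactions["imp"].lb = 2.0
        lp = build_total_flux_lp(m)
        res = solve_lp(lp)
        assert res.status == 0
        assert res.fun == pytest.approx(4.0)  # both reactions at 2

    def test_degenerate_alternate_optima_share_objective(self, diamond):
        # the two branches are interchangeable; the objective is unique
        z = [minimize_total_flux(diamond, fixed={"exp": 1.0}).objective
             for _ in range(3)]
        assert max(z) - min(z) <= 1e-9
        assert z[0] == pytest.approx(3.0, abs=1e-9)

    def test_against_second_backend(self, leaf_model):
        """The scipy/HiGHS optimum matches an independently constructed
        cobrapy/GLPK parsimonious solve of the same network."""
        cobra = pytest.importorskip("cobra")
        from cobra.flux_analysis import pfba

        cm = cobra.Model("leaf")
        for met in leaf_model.metabolites.values():
            if not met.is_external:
                cm.add_metabolites(cobra.Metabolite(
                    met.id, compartment=met.compartment))
        rxns = []
        for rxn in leaf_model.reactions.values():
            cr = cobra.Reaction(rxn.id)
            cr.lower_bound, cr.upper_bound = rxn.lb, rxn.ub
            rxns.append((cr, rxn))
        cm.add_reactions([cr for cr, _ in rxns])
        for cr, rxn in rxns:
            cr.add_metabolites({
                cm.metabolites.get_by_id(m): c for m, c in rxn.stoich.items()
                if not leaf_model.metabolites[m].is_external})
        cm.reactions.chlorophyll_tx.bounds = (1.0, 1.0)
        cm.reactions.chl_RuBisCO_oxy.bounds = (0.0, 0.0)
        cm.objective = "chlorophyll_tx"
        cobra_sol = pfba(cm)
        ours = minimize_total_flux(leaf_model, fixed={"chlorophyll_tx": 1.0},
                                   blocked={"chl_RuBisCO_oxy"})
        assert ours.objective == pytest.approx(cobra_sol.objective_value,
                                               abs=1e-5)
        for rid in ("chl_GluALA", "mit_GDC", "chl_GS2", "chl_GOGAT",
                    "Mal_2OG_chl_tx"):
            assert ours.fluxes[rid] == pytest.approx(
                cobra_sol.fluxes[rid], abs=1e-5)


class TestRatioConstraints:
    def test_forced_split(self):
        m = _toy([("vc", {"x_A": -1, "X": 1}),
                  ("vo", {"x_A": -1, "X": 1}),
                  ("demand", {"X": -1, "x_X": 1})])
        sol = minimize_total_flux(m, fixed={"demand": 1.0},
                                  ratios=(RatioConstraint("vc", "vo", 3.0),))
        assert sol.fluxes["vc"] == pytest.approx(0.75, abs=1e-9)
        assert sol.fluxes["vo"] == pytest.approx(0.25, abs=1e-9)

    def test_coupling_activates_both_rubisco_forms(self, leaf_model):
        sol = minimize_total_flux(
            leaf_model, fixed={"chlorophyll_tx": 1.0},
            ratios=(RatioConstraint("chl_RuBisCO_carb", "chl_RuBisCO_oxy", 3.0),))
        assert sol.status == OPTIMAL
        assert sol.fluxes["chl_RuBisCO_oxy"] > SUPPORT_TOL
        assert sol.fluxes["chl_RuBisCO_carb"] == pytest.approx(
            3 * sol.fluxes["chl_RuBisCO_oxy"], abs=1e-6)
        # C2 cycle active
        assert sol.fluxes["per_GOX"] > SUPPORT_TOL

    def test_ratio_with_blocked_partner_infeasible(self):
        m = _toy([("vc", {"x_A": -1, "X": 1}),
                  ("vo", {"x_A": -1, "X": 1}),
                  ("demand", {"X": -1, "x_X": 1})])
        sol = minimize_total_flux(m, fixed={"demand": 1.0}, blocked={"vo"},
                                  ratios=(RatioConstraint("vc", "vo", 3.0),))
        assert sol.status == INFEASIBLE

    def test_add_ratio_constraint_row(self, leaf_model):
        lp = build_total_flux_lp(leaf_model, fixed={"chlorophyll_tx": 1.0})
        lp2 = add_ratio_constraint(
            lp, RatioConstraint("chl_RuBisCO_carb", "chl_RuBisCO_oxy", 3.0))
        assert lp2.A_eq.shape[0] == lp.A_eq.shape[0] + 1
        res = solve_lp(lp2)
        assert res.status == 0
        fluxes = lp2.net_fluxes(res.x)
        assert fluxes["chl_RuBisCO_carb"] == pytest.approx(
            3 * fluxes["chl_RuBisCO_oxy"], abs=1e-6)

    def test_unknown_reaction_rejected(self, leaf_model):
        lp = build_total_flux_lp(leaf_model)
        with pytest.raises(UnknownReactionError):
            add_ratio_constraint(lp, RatioConstraint("nope", "also_nope", 2.0))
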