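import hashlib

import pytest

from chlorofba.essentiality import (ESSENTIAL, NO_DATA, NON_ESSENTIAL,
                                    extract_active_pathway,
                                    gene_deletion_scan, reaction_deletion_scan)
from chlorofba.fba import FluxSolution, minimize_total_flux
from chlorofba.fixture import generate_synthetic_network
from chlorofba.io import write_model
from chlorofba.model import MetabolicModel, Metabolite, Reaction
from chlorofba.scenarios import Scenario, case1
from oracles import brute_force_essential_set


def _toy(reactions, gprs=None):
    m = MetabolicModel("toy", compartments=("cytosol", "external"))
    mets = {met for _, r in reactions for met in r}
    for met in sorted(mets):
        m.add_metabolite(Metabolite(
            met, "external" if met.startswith("x_") else "cytosol"))
    for rid, stoich in reactions:
        m.add_reaction(Reaction(rid, stoich, gpr=(gprs or {}).get(rid)))
    return m


def _demand(rid, val=1.0):
    return Scenario(name="demand", fixed_fluxes={rid: val})


class TestReactionDeletionScan:
    def test_single_chain_everything_essential(self):
        chain = _toy([("imp", {"x_A": -1, "A": 1}),
                      ("conv", {"A": -1, "B": 1}),
                      ("exp", {"B": -1, "x_B": 1})])
        report = reaction_deletion_scan(chain, _demand("exp"),
                                        candidates=list(chain.reactions))
        assert report.essential == set(chain.reactions)

    def test_diamond_branches_redundant_stem_essential(self):
        diamond = _toy([("imp", {"x_A": -1, "A": 1}),
                        ("b1", {"A": -1, "B": 1}),
                        ("b2", {"A": -1, "B": 1}),
                        ("exp", {"B": -1, "x_B": 1})])
        report = reaction_deletion_scan(diamond, _demand("exp"),
                                        candidates=list(diamond.reactions))
        assert report.essential == {"imp", "exp"}
        assert report.non_essential == {"b1", "b2"}
        # agrees with exhaustive deletion through the independent LP
        assert report.essential == brute_force_essential_set(diamond, "exp")

    def test_unknown_candidate_listed_scan_continues(self, leaf_model):
        report = reaction_deletion_scan(leaf_model, case1(),
                                        candidates=["nope", "mit_GDC"])
        assert report.errors == ["nope"]
        assert report.verdicts["mit_GDC"] == ESSENTIAL

    def test_scan_is_side_effect_free(self, leaf_model):
        def digest(m):
            import io as _io
            buf = []
            for r in m.reactions.values():
                buf.append(f"{r.id}|{sorted(r.stoich.items())}|{r.lb}|{r.ub}")
            return hashlib.sha256("\n".join(buf).encode()).hexdigest()

        before = digest(leaf_model)
        reaction_deletion_scan(leaf_model, case1(),
                               candidates=["mit_GDC", "cyt_GS1", "chl_GS2"])
        assert digest(leaf_model) == before

    def test_gs2_essential_without_diffusion(self, leaf_model):
        report = reaction_deletion_scan(leaf_model, case1(),
                                        candidates=["chl_GS2"])
        assert report.verdicts["chl_GS2"] == ESSENTIAL

    def test_gs2_dispensable_with_diffusion(self, leaf_model):
        scenario = case1(diffusion=True)
        edited = scenario.apply_optional(leaf_model)
        report = reaction_deletion_scan(edited, scenario,
                                        candidates=["chl_GS2"])
        assert report.verdicts["chl_GS2"] == NON_ESSENTIAL

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_construction_and_brute_force(self, seed):
        net = generate_synthetic_network(n_metabolites=4, n_reactions=8,
                                         n_parallel_paths=3, seed=seed)
        report = reaction_deletion_scan(net.model, _demand(net.demand),
                                        candidates=list(net.model.reactions))
        assert report.essential == net.essential
        assert report.non_essential == net.non_essential
        assert report.essential == brute_force_essential_set(net.model,
                                                             net.demand)


class TestGeneDeletionScan:
    def test_or_semantics_keep_reaction_open(self):
        chain = _toy([("imp", {"x_A": -1, "A": 1}),
                      ("exp", {"A": -1, "x_B": 1})],
                     gprs={"imp": "g1 OR g2"})
        verdicts = gene_deletion_scan(chain, _demand("exp"))
        assert verdicts["g1"] == NON_ESSENTIAL
        assert verdicts["g2"] == NON_ESSENTIAL

    def test_and_semantics_close_reaction(self):
        chain = _toy([("imp", {"x_A": -1, "A": 1}),
                      ("exp", {"A": -1, "x_B": 1})],
                     gprs={"imp": "g1 AND g2"})
        verdicts = gene_deletion_scan(chain, _demand("exp"))
        assert verdicts["g1"] == ESSENTIAL
        assert verdicts["g2"] == ESSENTIAL

    def test_unknown_gene_reported_no_data(self):
        chain = _toy([("imp", {"x_A": -1, "A": 1}),
                      ("exp", {"A": -1, "x_B": 1})], gprs={"imp": "g1"})
        verdicts = gene_deletion_scan(chain, _demand("exp"), genes=["mystery"])
        assert verdicts["mystery"] == NO_DATA

    def test_fixture_gene_verdicts_follow_reaction_verdicts(self, leaf_model):
        """A gene is essential iff knocking it out closes a reaction set
        whose simultaneous deletion kills the demand; single-gene GPRs on
        essential reactions must therefore come out essential."""
        scan = reaction_deletion_scan(leaf_model, case1())
        genes = gene_deletion_scan(leaf_model, case1())
        assert genes["OsPBGD"] == ESSENTIAL       # sole gene of HMB synthase
        assert genes["OsGS2"] == ESSENTIAL        # GS2, diffusion closed
        assert genes["OsGLDC"] == ESSENTIAL       # AND-partner of GDC
        # isoenzyme pairs are individually dispensable
        assert genes["OsPORA"] == NON_ESSENTIAL
        assert genes["OsSAMS1"] == NON_ESSENTIAL
        # cross-check one mapping: every essential single-gene GPR reaction
        # in the scanned pathway implies gene essentiality
        for rid in scan.essential:
            gpr = leaf_model.reactions[rid].gpr
            if gpr and " " not in gpr:
                assert genes[gpr] == ESSENTIAL, rid


class TestActivePathway:
    def test_single_chain_lists_everything(self):
        chain = _toy([("imp", {"x_A": -1, "A": 1}),
                      ("exp", {"A": -1, "x_B": 1})])
        sol = minimize_total_flux(chain, fixed={"exp": 1.0})
        listing = extract_active_pathway(sol, chain)
        assert set(listing.reactions) == set(chain.reactions)

    def test_leaf_case1_pathway_content(self, leaf_model, case1_solution):
        """The flux-minimal route spans methyl cycle, GS/GOGAT, the organic
        acid shuttles and the SAM/AdoHcy transporters."""
        listing = extract_active_pathway(case1_solution, leaf_model)
        active = set(listing.reactions)
        assert {"cyt_MTHFR", "cyt_MS", "cyt_SAMS", "cyt_SAHH",
                "chl_GS2", "chl_GOGAT",
                "Mal_2OG_chl_tx", "Mal_Glu_chl_tx",
                "SAM_tx_T1", "AdoHcy_tx_T2"} <= active
        counts = listing.counts()
        assert counts["transporter"] > 0
        assert counts["chloroplast"] > counts["cytosol"]
        assert "peroxisome" not in counts  # no photorespiration in case 1

    def test_infeasible_solution_rejected(self, leaf_model):
        bad = FluxSolution(status="infeasible", objective=None)
        with pytest.raises(ValueError, match="infeasible"):
            extract_active_pathway(bad, leaf_model)
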