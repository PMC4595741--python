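"""Single-reaction and gene-level deletion scans against chlorophyll demand.

A reaction is essential when forcing its flux to zero (both directions for a
reversible reaction) makes the scenario's demand infeasible — strict
infeasibility, not a reduced optimum, since the demand is a fixed flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, TYPE_CHECKING

from .fba import INFEASIBLE, OPTIMAL, FluxSolution, minimize_total_flux
from .gpr import evaluate_gpr
from .model import MetabolicModel

if TYPE_CHECKING:  # pragma: no cover
    from .scenarios import Scenario

ESSENTIAL = "essential"
NON_ESSENTIAL = "non-essential"
NO_DATA = "no-data"


@dataclass
class EssentialityReport:
    verdicts: Dict[str, str] = field(default_factory=dict)
    statuses: Dict[str, str] = field(default_factory=dict)
    compartments: Dict[str, str] = field(default_factory=dict)
    errors: List[str] = field(default_factory=list)

    @property
    def essential(self) -> Set[str]:
        return {r for r, v in self.verdicts.items() if v == ESSENTIAL}

    @property
    def non_essential(self) -> Set[str]:
        return {r for r, v in self.verdicts.items() if v == NON_ESSENTIAL}

    def counts_by_compartment(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for rxn_id in self.essential:
            comp = self.compartments.get(rxn_id, "?")
            out[comp] = out.get(comp, 0) + 1
        return out


def _edits(scenario):
    if scenario is None:
        return {}, (), set()
    return dict(scenario.fixed_fluxes), tuple(scenario.ratios), set(scenario.blocked)


def reaction_deletion_scan(model: MetabolicModel,
                           scenario: Optional["Scenario"] = None,
                           candidates: Optional[Iterable[str]] = None
                           ) -> EssentialityReport:
    """Delete each candidate in turn and test feasibility of the demand.

    ``candidates`` defaults to the active pathway of the scenario's optimum
    (the deletion scope used for the leaf analysis); pass all reaction ids to
    scan the whole network.  The model is never mutated: deletions are
    expressed as extra blocked sets on fresh solves.
    """
    fixed, ratios, blocked = _edits(scenario)
    base = minimize_total_flux(model, fixed=fixed, ratios=ratios, blocked=blocked)
    if base.status != OPTIMAL:
        raise RuntimeError(f"baseline scenario is {base.status}; nothing to scan")
    if candidates is None:
        candidates = sorted(base.active_support)

    report = EssentialityReport()
    for rxn_id in candidates:
        if rxn_id not in model.reactions:
            report.errors.append(rxn_id)
            continue
        probe = minimize_total_flux(model, fixed=fixed, ratios=ratios,
                                    blocked=blocked | {rxn_id})
        report.statuses[rxn_id] = probe.status
        report.verdicts[rxn_id] = (
            ESSENTIAL if probe.status == INFEASIBLE else NON_ESSENTIAL)
        report.compartments[rxn_id] = (
            "transporter" if model.reactions[rxn_id].is_transporter
            else model.compartment_of(model.reactions[rxn_id]))
    return report


def gene_deletion_scan(model: MetabolicModel,
                       scenario: Optional["Scenario"] = None,
                       genes: Optional[Iterable[str]] = None) -> Dict[str, str]:
    """Knock out each gene; block every reaction whose GPR evaluates false.

    Genes never mentioned in a GPR are reported ``no-data``, never essential.
    """
    fixed, ratios, blocked = _edits(scenario)
    gpr_rxns = [(r.id, r.gpr) for r in model.reactions.values() if r.gpr]
    if not gpr_rxns:
        raise ValueError("no reaction carries a gene association")
    all_genes = model.genes
    if genes is None:
        genes = sorted(all_genes)

    verdicts: Dict[str, str] = {}
    for gene in genes:
        if gene not in all_genes:
            verdicts[gene] = NO_DATA
            continue
        closed = {rid for rid, gpr in gpr_rxns if not evaluate_gpr(gpr, {gene})}
        if not closed:
            verdicts[gene] = NON_ESSENTIAL
            continue
        probe = minimize_total_flux(model, fixed=fixed, ratios=ratios,
                                    blocked=blocked | closed)
        verdicts[gene] = ESSENTIAL if probe.status == INFEASIBLE else NON_ESSENTIAL
    return verdicts


@dataclass
class PathwayListing:
    reactions: List[str]
    by_compartment: Dict[str, List[str]]

    def counts(self) -> Dict[str, int]:
        return {c: len(rs) for c, rs in self.by_compartment.items()}


def extract_active_pathway(solution: FluxSolution,
                           model: MetabolicModel) -> PathwayListing:
    """Reactions carrying flux, grouped by compartment / transporter status."""
    if solution.status != OPTIMAL:
        raise ValueError(f"no pathway in a solution with status {solution.status!r}")
    active = [rid for rid in model.reactions if rid in solution.active_support]
    groups: Dict[str, List[str]] = {}
    for rid in active:
        rxn = model.reactions[rid]
        key = "transporter" if rxn.is_transporter else model.compartment_of(rxn)
        groups.setdefault(key, []).append(rid)
    return PathwayListing(reactions=active, by_compartment=groups)
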