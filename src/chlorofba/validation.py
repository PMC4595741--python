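"""Energy/redox conservation checks and solution auditing.

The leak test asks whether the network can generate ATP (or reducing power)
from nothing: all exchanges are closed and a transient hydrolysis/oxidation
sink for the probe couple is maximized.  Any positive maximum exposes an
erroneous energy-generating cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .fba import BALANCE_TOL, FluxSolution, build_total_flux_lp, solve_lp
from .model import (DEFAULT_UB, MetabolicModel, Reaction,
                    build_stoichiometric_matrix)

#: probe couples: sink converts the charged species into the discharged one
ENERGY_PROBES: Tuple[Tuple[str, str, str], ...] = (
    ("ATP", "ATP", "ADP"),
    ("NADPH", "NADPH", "NADP"),
    ("NADH", "NADH", "NAD"),
)

LEAK_TOL = 1e-6


@dataclass
class LeakReport:
    #: (probe, compartment) -> maximal producible flux with exchanges closed
    max_flux: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def verdict(self, probe: str, compartment: str) -> str:
        return ("leaking" if self.max_flux[(probe, compartment)] > LEAK_TOL
                else "conserved")

    @property
    def conserved(self) -> bool:
        return all(v <= LEAK_TOL for v in self.max_flux.values())

    @property
    def leaks(self) -> List[Tuple[str, str]]:
        return [k for k, v in self.max_flux.items() if v > LEAK_TOL]


def _exchange_ids(model: MetabolicModel) -> List[str]:
    return [r.id for r in model.reactions.values()
            if any(model.metabolites[m].is_external for m in r.stoich)]


def energy_redox_leak_test(model: MetabolicModel) -> LeakReport:
    """Probe every compartmented ATP/NADPH/NADH pool for free generation.

    Exchanges (reactions touching external species) are bounded to zero; a
    transient sink ``charged -> discharged (+ Pi for ATP)`` is added per
    probe and its flux maximized.  The model is copied, never mutated.
    """
    report = LeakReport()
    exchanges = set(_exchange_ids(model))
    for probe, charged, discharged in ENERGY_PROBES:
        for met in model.metabolites.values():
            if met.is_external or not met.id.endswith("_" + charged):
                continue
            prefix = met.id[: -len(charged) - 1]
            partner = f"{prefix}_{discharged}"
            if partner not in model.metabolites:
                continue
            probe_model = model.copy()
            for rid in exchanges:
                probe_model.reactions[rid].lb = 0.0
                probe_model.reactions[rid].ub = 0.0
            stoich = {met.id: -1.0, partner: 1.0}
            if probe == "ATP" and f"{prefix}_Pi" in model.metabolites:
                stoich[f"{prefix}_Pi"] = 1.0
            probe_model.add_reaction(
                Reaction("__leak_sink__", stoich, lb=0.0, ub=DEFAULT_UB))
            lp = build_total_flux_lp(probe_model)
            c = np.zeros(len(lp.columns))
            for j in lp.col_index["__leak_sink__"]:
                c[j] = -lp.columns[j][1]  # maximize sink flux
            res = solve_lp(lp, c=c)
            value = -float(res.fun) if res.status == 0 else 0.0
            comp = model.metabolites[met.id].compartment
            report.max_flux[(probe, comp)] = value
    return report


@dataclass
class SolutionAudit:
    residuals: Dict[str, float] = field(default_factory=dict)
    bound_violations: List[str] = field(default_factory=list)

    @property
    def max_residual(self) -> float:
        return max(self.residuals.values(), default=0.0)

    @property
    def clean(self) -> bool:
        return self.max_residual <= BALANCE_TOL and not self.bound_violations


def audit_solution(solution: FluxSolution, model: MetabolicModel,
                   tol: float = BALANCE_TOL) -> SolutionAudit:
    """Per-metabolite |S v| residuals and bound violations of a solution."""
    S = build_stoichiometric_matrix(model)
    v = np.array([solution.fluxes.get(rid, 0.0) for rid in model.reactions])
    resid = S @ v
    audit = SolutionAudit(
        residuals={m: abs(r) for m, r in zip(model.internal_metabolites(), resid)})
    for rid, rxn in model.reactions.items():
        flux = solution.fluxes.get(rid, 0.0)
        if flux < rxn.lb - tol or flux > rxn.ub + tol:
            audit.bound_violations.append(rid)
    return audit
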