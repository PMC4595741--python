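"""Flux variability analysis at the strict optimum or a relaxed multiple of it.

The total-flux optimum Z* is computed first; each reaction's net flux is then
minimized and maximized subject to the steady-state constraints, the scenario
edits, and the budget  sum_j |v_j| <= relaxation * Z*  expressed as a single
inequality row over the split variables.  At relaxation 1.0 the budget pins
the solution onto the optimal face.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, TYPE_CHECKING

import numpy as np

from .fba import (OPTIMAL, LinearProgram, SolverError, build_total_flux_lp,
                  minimize_total_flux, solve_lp)
from .model import MetabolicModel

if TYPE_CHECKING:  # pragma: no cover
    from .scenarios import Scenario

#: values within this tolerance are reported as tied for classification
TIE_TOL = 1e-6


class InfeasibleScenarioError(RuntimeError):
    pass


@dataclass
class FVAResult:
    relaxation: float
    objective_bound: float
    fba_val: Dict[str, float]
    fva_min: Dict[str, float] = field(default_factory=dict)
    fva_max: Dict[str, float] = field(default_factory=dict)

    def range_of(self, rxn_id: str) -> tuple:
        return self.fva_min[rxn_id], self.fva_max[rxn_id]


def run_fva(model: MetabolicModel, scenario: Optional["Scenario"] = None,
            relaxation: float = 1.0) -> FVAResult:
    """Per-reaction allowable flux ranges under a relaxed total-flux budget."""
    if relaxation < 1.0:
        raise ValueError("relaxation factor must be >= 1")
    fixed, ratios, blocked = _scenario_edits(scenario)
    ref = minimize_total_flux(model, fixed=fixed, ratios=ratios, blocked=blocked)
    if ref.status != OPTIMAL:
        raise InfeasibleScenarioError(
            f"scenario is {ref.status}; cannot run FVA")
    bound = relaxation * ref.objective

    lp = build_total_flux_lp(model, fixed=fixed, ratios=ratios, blocked=blocked)
    lp.A_ub = np.ones((1, len(lp.columns)))
    lp.b_ub = np.array([bound])

    result = FVAResult(relaxation=relaxation, objective_bound=bound,
                       fba_val=dict(ref.fluxes))
    for rxn_id in model.reactions:
        lo = _directional_opt(lp, rxn_id, sense=+1)
        hi = -_directional_opt(lp, rxn_id, sense=-1)
        result.fva_min[rxn_id] = lo
        result.fva_max[rxn_id] = hi
    return result


def _directional_opt(lp: LinearProgram, rxn_id: str, sense: int) -> float:
    res = solve_lp(lp, c=lp.objective_row(rxn_id, sense))
    if res.status != 0:
        raise SolverError(
            f"FVA sub-problem for {rxn_id!r} returned status {res.status}")
    return float(res.fun)


def _scenario_edits(scenario):
    if scenario is None:
        return {}, (), ()
    return scenario.fixed_fluxes, tuple(scenario.ratios), set(scenario.blocked)


@dataclass
class VariabilityClasses:
    """Partition of the reactions by their behaviour inside the relaxed polytope."""

    pinned: set = field(default_factory=set)           # fva_min = fva_max = fba_val
    essential_bounded: set = field(default_factory=set)  # flux cannot reach zero
    variable: set = field(default_factory=set)

    @property
    def variability_implied_essential(self) -> set:
        return self.pinned_nonzero | self.essential_bounded

    pinned_nonzero: set = field(default_factory=set)


def classify_by_variability(fva: FVAResult) -> VariabilityClasses:
    """Three-way partition; reactions whose flux cannot vanish within the
    budget are flagged variability-implied essential."""
    out = VariabilityClasses()
    for rxn_id, ref in fva.fba_val.items():
        lo, hi = fva.fva_min[rxn_id], fva.fva_max[rxn_id]
        pinned = abs(hi - lo) <= TIE_TOL
        zero_unreachable = lo > TIE_TOL or hi < -TIE_TOL
        if pinned:
            out.pinned.add(rxn_id)
            if abs(ref) > TIE_TOL:
                out.pinned_nonzero.add(rxn_id)
        elif zero_unreachable:
            out.essential_bounded.add(rxn_id)
        else:
            out.variable.add(rxn_id)
    return out
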