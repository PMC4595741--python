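"""Named experimental conditions and the ammonia-transporter scans.

Every bundled scenario fixes chlorophyll export at 1.0 flux unit.  Case 1
("carboxylase-only") blocks the Rubisco oxygenase; case 2 ("photorespiring")
couples carboxylase to oxygenase at Vc/Vo = 3 (normal air).  The optional
chloroplast-to-cytosol ammonia diffusion step is opened by widening its
upper bound rather than editing the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from . import fixture as fx
from .essentiality import reaction_deletion_scan
from .fba import (INFEASIBLE, OPTIMAL, FluxSolution, RatioConstraint,
                  minimize_total_flux)
from .model import DEFAULT_UB, MetabolicModel

CHLOROPHYLL_DEMAND = 1.0
VC_VO_RATIO = 3.0

#: fluxes reported on every scan grid point
SCAN_COLUMNS = (
    fx.CYT_NH3_TX, fx.CHL_NH3_TX, fx.GS1, fx.GS2, fx.GLU_GLN_TX,
    fx.MAL_2OG_TX, fx.GOGAT, fx.NH3_MIT_CHL_TX, fx.GDC, fx.SHMT_MIT,
)


@dataclass(frozen=True)
class Scenario:
    """A declarative set of constraint edits applied before solving."""

    name: str
    fixed_fluxes: Dict[str, float] = field(default_factory=dict)
    blocked: frozenset = frozenset()
    ratios: Tuple[RatioConstraint, ...] = ()
    #: reactions whose closed-by-default bound is opened, id -> new ub
    enabled_optional_reactions: Dict[str, float] = field(default_factory=dict)

    def with_fixed(self, **fluxes: float) -> "Scenario":
        merged = dict(self.fixed_fluxes)
        merged.update(fluxes)
        return replace(self, fixed_fluxes=merged)

    def apply_optional(self, model: MetabolicModel) -> MetabolicModel:
        """Return a copy of the model with optional reactions opened."""
        if not self.enabled_optional_reactions:
            return model
        clone = model.copy()
        for rxn_id, ub in self.enabled_optional_reactions.items():
            clone.reactions[rxn_id].ub = ub
        return clone

    def solve(self, model: MetabolicModel) -> FluxSolution:
        return minimize_total_flux(self.apply_optional(model),
                                   fixed=self.fixed_fluxes,
                                   ratios=self.ratios, blocked=self.blocked)


def case1(diffusion: bool = False) -> Scenario:
    """Carboxylase-only condition: oxygenase blocked, no ratio coupling."""
    return Scenario(
        name="case1" + ("_diffusion" if diffusion else ""),
        fixed_fluxes={fx.CHLOROPHYLL_TX: CHLOROPHYLL_DEMAND},
        blocked=frozenset({fx.RUBISCO_OXY}),
        enabled_optional_reactions=(
            {fx.NH3_DIFFUSION: DEFAULT_UB} if diffusion else {}),
    )


def case2(diffusion: bool = False) -> Scenario:
    """Photorespiring condition: Vc/Vo coupled at 3:1."""
    return Scenario(
        name="case2" + ("_diffusion" if diffusion else ""),
        fixed_fluxes={fx.CHLOROPHYLL_TX: CHLOROPHYLL_DEMAND},
        ratios=(RatioConstraint(fx.RUBISCO_CARB, fx.RUBISCO_OXY, VC_VO_RATIO),),
        enabled_optional_reactions=(
            {fx.NH3_DIFFUSION: DEFAULT_UB} if diffusion else {}),
    )


BUNDLED = {"case1": case1, "case2": case2}


def load_scenario_yaml(path) -> Scenario:
    """Read a scenario from a YAML mapping.

    Recognized keys: ``name``, ``fixed_fluxes`` (reaction -> value),
    ``blocked`` (list), ``ratios`` (list of ``{a, b, ratio}`` mappings) and
    ``enable`` (reaction -> new upper bound, for closed-by-default steps).
    """
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    ratios = tuple(RatioConstraint(r["a"], r["b"], float(r["ratio"]))
                   for r in raw.get("ratios", ()))
    return Scenario(
        name=str(raw.get("name", "custom")),
        fixed_fluxes={k: float(v)
                      for k, v in (raw.get("fixed_fluxes") or {}).items()},
        blocked=frozenset(raw.get("blocked", ())),
        ratios=ratios,
        enabled_optional_reactions={
            k: float(v) for k, v in (raw.get("enable") or {}).items()})


def get_scenario(name: str) -> Scenario:
    base, _, suffix = name.partition("_")
    if base not in BUNDLED or suffix not in ("", "diffusion"):
        raise KeyError(f"unknown scenario {name!r}")
    return BUNDLED[base](diffusion=suffix == "diffusion")


# ---------------------------------------------------------------------------
# scans and experiments
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    case: str
    grid: List[float]
    fluxes: Dict[float, Dict[str, float]] = field(default_factory=dict)
    objective: Dict[float, float] = field(default_factory=dict)
    infeasible_points: List[float] = field(default_factory=list)

    def column(self, rxn_id: str) -> List[float]:
        return [self.fluxes[a][rxn_id] for a in self.grid if a in self.fluxes]


def run_ammonia_scan(model: MetabolicModel, case: str = "case1",
                     grid: Sequence[float] = (0.0, 1.0, 2.0, 3.0, 4.0)
                     ) -> ScanResult:
    """Fix the chloroplastic ammonia importer along ``grid`` and re-solve.

    The cytosolic importer is left free; nitrogen closure forces it to carry
    the complement to 4.0.  Infeasible grid points are recorded and skipped.
    """
    scenario = get_scenario(case)
    result = ScanResult(case=case, grid=list(grid))
    for a in grid:
        sol = scenario.with_fixed(**{fx.CHL_NH3_TX: a}).solve(model)
        if sol.status != OPTIMAL:
            result.infeasible_points.append(a)
            continue
        result.fluxes[a] = {rid: sol.fluxes.get(rid, 0.0) for rid in SCAN_COLUMNS}
        result.objective[a] = sol.objective
    return result


@dataclass
class GS2Experiment:
    case: str
    diffusion_enabled: bool
    gs2_flux: float
    chloroplastic_ammonia_refixed: float   # HMB-synthase release + mito import
    mito_ammonia_to_chloroplast: float
    gs2_essential: bool
    solution: FluxSolution


def run_gs2_experiment(model: MetabolicModel, diffusion_enabled: bool,
                       case: str = "case1") -> GS2Experiment:
    """Probe the fate of chloroplast-born ammonia with/without the diffusion
    escape route: GS2 activity, the ammonia it refixes, and GS2 essentiality."""
    scenario = get_scenario(case + ("_diffusion" if diffusion_enabled else ""))
    edited = scenario.apply_optional(model)
    sol = minimize_total_flux(edited, fixed=scenario.fixed_fluxes,
                              ratios=scenario.ratios, blocked=scenario.blocked)
    if sol.status != OPTIMAL:
        raise RuntimeError(f"{scenario.name} infeasible on this model")
    deletion = minimize_total_flux(edited, fixed=scenario.fixed_fluxes,
                                   ratios=scenario.ratios,
                                   blocked=set(scenario.blocked) | {fx.GS2})
    hmbs_nh3 = sol.fluxes[fx.HMB_SYNTHASE] * \
        model.reactions[fx.HMB_SYNTHASE].stoich["chl_NH3"]
    mito_nh3 = sol.fluxes[fx.NH3_MIT_CHL_TX]
    return GS2Experiment(
        case=case, diffusion_enabled=diffusion_enabled,
        gs2_flux=sol.fluxes[fx.GS2],
        chloroplastic_ammonia_refixed=hmbs_nh3 + mito_nh3,
        mito_ammonia_to_chloroplast=mito_nh3,
        gs2_essential=deletion.status == INFEASIBLE,
        solution=sol)


@dataclass
class CaseComparison:
    photon_flux: Dict[str, float]
    total_flux: Dict[str, float]
    peroxisomal_support: Dict[str, int]
    mal_2og_flux: Dict[str, float]
    gdc_flux: Dict[str, float]
    shmt_mit_flux: Dict[str, float]
    preferred_importer: Dict[str, str]
    solutions: Dict[str, FluxSolution]


def compare_cases(model: MetabolicModel) -> CaseComparison:
    """Contrast the carboxylase-only and photorespiring optima."""
    out = CaseComparison({}, {}, {}, {}, {}, {}, {}, {})
    for name in ("case1", "case2"):
        sol = get_scenario(name).solve(model)
        if sol.status != OPTIMAL:
            raise RuntimeError(f"{name} infeasible")
        out.solutions[name] = sol
        out.photon_flux[name] = sol.fluxes[fx.PHOTON_TX]
        out.total_flux[name] = sol.objective
        out.peroxisomal_support[name] = sum(
            1 for rid in sol.active_support
            if model.compartment_of(model.reactions[rid]) == "peroxisome")
        out.mal_2og_flux[name] = sol.fluxes[fx.MAL_2OG_TX]
        out.gdc_flux[name] = sol.fluxes[fx.GDC]
        out.shmt_mit_flux[name] = sol.fluxes[fx.SHMT_MIT]
        out.preferred_importer[name] = _preferred_importer(sol)
    return out


def _preferred_importer(sol: FluxSolution, tol: float = 1e-6) -> str:
    cyt = sol.fluxes.get(fx.CYT_NH3_TX, 0.0)
    chl = sol.fluxes.get(fx.CHL_NH3_TX, 0.0)
    if cyt > tol and chl > tol:
        return "both"
    return "cytosolic" if cyt > tol else "chloroplastic"
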