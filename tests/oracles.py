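"""Independent brute-force oracles for small networks.

These deliberately avoid the package's split-variable LP construction: they
work on the unsplit system S v = 0 and enumerate sign orthants of the
reversible reactions, solving one plain scipy LP per orthant.  Intended for
networks of at most ~12 reactions.
"""

from __future__ import annotations

import itertools
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
from scipy.optimize import linprog

from chlorofba.model import MetabolicModel, build_stoichiometric_matrix


def _orthants(model: MetabolicModel, fixed: Mapping[str, float],
              blocked: Iterable[str]):
    """Yield (signs, bounds) for every sign pattern of reversible reactions."""
    rxns = list(model.reactions.values())
    blocked = set(blocked)
    rev_idx = [j for j, r in enumerate(rxns)
               if r.reversible and r.id not in fixed and r.id not in blocked]
    for pattern in itertools.product((+1, -1), repeat=len(rev_idx)):
        signs = np.ones(len(rxns))
        bounds = []
        ok = True
        for j, r in enumerate(rxns):
            lb, ub = r.lb, r.ub
            if r.id in fixed:
                lb = ub = fixed[r.id]
                if fixed[r.id] < 0:
                    signs[j] = -1
            if r.id in blocked:
                lb, ub = max(lb, 0.0), min(ub, 0.0)
                if lb > ub:
                    ok = False
                    break
            if j in rev_idx:
                s = pattern[rev_idx.index(j)]
                signs[j] = s
                lb, ub = (0.0, ub) if s > 0 else (lb, 0.0)
            bounds.append((lb, ub))
        if ok:
            yield signs, bounds


def brute_force_min_total_flux(model: MetabolicModel,
                               fixed: Optional[Mapping[str, float]] = None,
                               blocked: Iterable[str] = ()
                               ) -> Tuple[str, Optional[float], Dict[str, float]]:
    """Minimum of sum |v| by orthant enumeration; independent of the package LP."""
    fixed = fixed or {}
    S = build_stoichiometric_matrix(model)
    best = None
    best_fluxes: Dict[str, float] = {}
    feasible = False
    for signs, bounds in _orthants(model, fixed, blocked):
        res = linprog(signs, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                      method="highs")
        if res.status == 0:
            feasible = True
            if best is None or res.fun < best - 1e-12:
                best = res.fun
                best_fluxes = {r: x for r, x in zip(model.reactions, res.x)}
    if not feasible:
        return "infeasible", None, {}
    return "optimal", float(best), best_fluxes


def brute_force_is_feasible(model: MetabolicModel,
                            fixed: Optional[Mapping[str, float]] = None,
                            blocked: Iterable[str] = ()) -> bool:
    status, _, _ = brute_force_min_total_flux(model, fixed, blocked)
    return status == "optimal"


def brute_force_essential_set(model: MetabolicModel, demand: str,
                              value: float = 1.0) -> set:
    """Delete each reaction in turn; essential iff demand becomes infeasible."""
    essential = set()
    for rid in model.reactions:
        if not brute_force_is_feasible(model, fixed={demand: value},
                                       blocked={rid}):
            essential.add(rid)
    return essential


def brute_force_fva(model: MetabolicModel, demand: str, value: float = 1.0,
                    relaxation: float = 1.0) -> Dict[str, Tuple[float, float]]:
    """Per-reaction flux ranges under sum |v| <= relaxation * optimum."""
    status, z_star, _ = brute_force_min_total_flux(model, fixed={demand: value})
    assert status == "optimal"
    budget = relaxation * z_star
    S = build_stoichiometric_matrix(model)
    ranges: Dict[str, Tuple[float, float]] = {}
    ids = list(model.reactions)
    for target in ids:
        lo, hi = np.inf, -np.inf
        for signs, bounds in _orthants(model, {demand: value}, ()):
            # |v| is linear within the orthant: signs . v <= budget
            for sense in (+1, -1):
                c = np.zeros(len(ids))
                c[ids.index(target)] = sense
                res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                              A_ub=signs[None, :], b_ub=[budget],
                              bounds=bounds, method="highs")
                if res.status == 0:
                    val = sense * res.fun
                    lo, hi = min(lo, val), max(hi, val)
        ranges[target] = (lo, hi)
    return ranges
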