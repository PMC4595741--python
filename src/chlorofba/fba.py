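"""Steady-state linear programming: flux-minimization FBA.

The core problem is

    minimize  sum_j |v_j|
    s.t.      S v = 0          (internal metabolites balanced)
              lb <= v <= ub
              v_f = value      for every fixed reaction f
              v_a - r v_b = 0  for every ratio coupling
              v_b = 0          for every blocked reaction

|v| is linearized exactly by splitting each reversible reaction into two
non-negative half-variables (v = v+ - v-); the objective is the sum of all
half-variables plus the irreversible fluxes, with uniform weight 1 on every
reaction including transporters and exchanges.  At optimality the objective
itself forbids simultaneous v+ and v- activity.  Solved with scipy's HiGHS
backend, single-threaded and deterministic for a fixed model ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, build_stoichiometric_matrix

BALANCE_TOL = 1e-6
SUPPORT_TOL = 1e-9

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"


class SolverError(RuntimeError):
    """The LP backend failed for a reason other than infeasibility."""


class UnknownReactionError(KeyError):
    pass


@dataclass(frozen=True)
class RatioConstraint:
    """Couples two irreversible reactions so that v_a = ratio * v_b."""

    reaction_a: str
    reaction_b: str
    ratio: float

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError(f"ratio must be positive, got {self.ratio}")


@dataclass
class FluxSolution:
    status: str
    objective: Optional[float]
    fluxes: Dict[str, float] = field(default_factory=dict)

    @property
    def active_support(self) -> Set[str]:
        return {r for r, v in self.fluxes.items() if abs(v) > SUPPORT_TOL}

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass
class LinearProgram:
    """A split-variable LP over a model: all variables non-negative offsets.

    Column j of ``columns`` is ``(reaction_id, sign)``; the net flux of a
    reaction is the signed sum of its columns.  Equality rows are S plus any
    coupling/fixing rows; an optional inequality block carries the FVA
    total-flux budget.
    """

    columns: List[Tuple[str, int]]
    c: np.ndarray
    A_eq: np.ndarray
    b_eq: np.ndarray
    bounds: List[Tuple[float, float]]
    A_ub: Optional[np.ndarray] = None
    b_ub: Optional[np.ndarray] = None
    col_index: Dict[str, List[int]] = field(default_factory=dict)

    @property
    def trivially_infeasible(self) -> bool:
        return any(lo > hi for lo, hi in self.bounds)

    def net_fluxes(self, x: np.ndarray) -> Dict[str, float]:
        out: Dict[str, float] = {}
        for (rid, sign), xi in zip(self.columns, x):
            out[rid] = out.get(rid, 0.0) + sign * xi
        return out

    def objective_row(self, rxn_id: str, sense: int) -> np.ndarray:
        """Coefficient vector whose minimization gives sense*net_flux minimal."""
        row = np.zeros(len(self.columns))
        for j in self.col_index[rxn_id]:
            row[j] = sense * self.columns[j][1]
        return row


def build_total_flux_lp(
    model: MetabolicModel,
    fixed: Optional[Mapping[str, float]] = None,
    ratios: Sequence[RatioConstraint] = (),
    blocked: Iterable[str] = (),
) -> LinearProgram:
    fixed = dict(fixed or {})
    blocked = set(blocked)
    for rid in list(fixed) + [rc.reaction_a for rc in ratios] + \
            [rc.reaction_b for rc in ratios] + list(blocked):
        if rid not in model.reactions:
            raise UnknownReactionError(rid)

    S = build_stoichiometric_matrix(model)
    rxns = list(model.reactions.values())

    columns: List[Tuple[str, int]] = []
    col_of: List[np.ndarray] = []
    bounds: List[Tuple[float, float]] = []
    col_index: Dict[str, List[int]] = {}
    for j, rxn in enumerate(rxns):
        lb, ub = rxn.lb, rxn.ub
        if rxn.id in fixed:
            val = fixed[rxn.id]
            if val < rxn.lb - BALANCE_TOL or val > rxn.ub + BALANCE_TOL:
                raise ValueError(
                    f"fixed flux {val} outside bounds [{rxn.lb}, {rxn.ub}] "
                    f"of reaction {rxn.id!r}")
            lb = ub = val
        if rxn.id in blocked:
            # intersect with v = 0: deleting a reaction that is also fixed at
            # a nonzero demand leaves an empty feasible set (the essentiality
            # signal), expressed as inverted bounds
            lb, ub = max(lb, 0.0), min(ub, 0.0)
        if rxn.lb < 0:  # reversible: split into forward/backward halves
            f_lb, f_ub = max(lb, 0.0), max(ub, 0.0)
            b_lb, b_ub = max(-ub, 0.0), max(-lb, 0.0)
            col_index.setdefault(rxn.id, []).append(len(columns))
            columns.append((rxn.id, +1))
            col_of.append(S[:, j])
            bounds.append((f_lb, f_ub))
            col_index.setdefault(rxn.id, []).append(len(columns))
            columns.append((rxn.id, -1))
            col_of.append(-S[:, j])
            bounds.append((b_lb, b_ub))
        else:
            col_index.setdefault(rxn.id, []).append(len(columns))
            columns.append((rxn.id, +1))
            col_of.append(S[:, j])
            bounds.append((lb, ub))

    n = len(columns)
    A_core = np.column_stack(col_of) if n else np.zeros((S.shape[0], 0))
    extra_rows: List[np.ndarray] = []
    for rc in ratios:
        row = np.zeros(n)
        for j in col_index[rc.reaction_a]:
            row[j] += columns[j][1]
        for j in col_index[rc.reaction_b]:
            row[j] -= rc.ratio * columns[j][1]
        extra_rows.append(row)
    A_eq = np.vstack([A_core] + [r[None, :] for r in extra_rows]) if extra_rows else A_core
    b_eq = np.zeros(A_eq.shape[0])
    c = np.ones(n)
    return LinearProgram(columns=columns, c=c, A_eq=A_eq, b_eq=b_eq,
                         bounds=bounds, col_index=col_index)


_HIGHS_OPTS = {"presolve": True}


def solve_lp(lp: LinearProgram, c: Optional[np.ndarray] = None):
    """Solve the LP (minimize) with HiGHS; returns the raw scipy result."""
    res = linprog(
        c if c is not None else lp.c,
        A_eq=lp.A_eq if lp.A_eq.size else None,
        b_eq=lp.b_eq if lp.A_eq.size else None,
        A_ub=lp.A_ub, b_ub=lp.b_ub,
        bounds=lp.bounds, method="highs", options=_HIGHS_OPTS)
    if res.status not in (0, 2, 3):
        raise SolverError(f"LP solver failure (status {res.status}): {res.message}")
    return res


def _status_of(res) -> str:
    return {0: OPTIMAL, 2: INFEASIBLE, 3: UNBOUNDED}[res.status]


def minimize_total_flux(
    model: MetabolicModel,
    fixed: Optional[Mapping[str, float]] = None,
    ratios: Sequence[RatioConstraint] = (),
    blocked: Iterable[str] = (),
) -> FluxSolution:
    """Flux-minimal steady state under fixed fluxes, ratio couplings and blocks.

    Infeasibility is reported in the solution status (it is the essentiality
    signal), not raised.
    """
    lp = build_total_flux_lp(model, fixed=fixed, ratios=ratios, blocked=blocked)
    if lp.trivially_infeasible:
        return FluxSolution(status=INFEASIBLE, objective=None)
    res = solve_lp(lp)
    status = _status_of(res)
    if status != OPTIMAL:
        return FluxSolution(status=status, objective=None)
    fluxes = lp.net_fluxes(res.x)
    return FluxSolution(status=OPTIMAL, objective=float(res.fun), fluxes=fluxes)


def add_ratio_constraint(lp: LinearProgram, rc: RatioConstraint) -> LinearProgram:
    """Return a new LP with one extra equality row enforcing v_a = r * v_b."""
    if rc.reaction_a not in lp.col_index or rc.reaction_b not in lp.col_index:
        raise UnknownReactionError(
            f"{rc.reaction_a!r} or {rc.reaction_b!r} not in LP")
    n = len(lp.columns)
    row = np.zeros(n)
    for j in lp.col_index[rc.reaction_a]:
        row[j] += lp.columns[j][1]
    for j in lp.col_index[rc.reaction_b]:
        row[j] -= rc.ratio * lp.columns[j][1]
    A_eq = np.vstack([lp.A_eq, row[None, :]])
    b_eq = np.append(lp.b_eq, 0.0)
    return LinearProgram(columns=list(lp.columns), c=lp.c.copy(), A_eq=A_eq,
                         b_eq=b_eq, bounds=list(lp.bounds), A_ub=lp.A_ub,
                         b_ub=lp.b_ub, col_index=dict(lp.col_index))
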