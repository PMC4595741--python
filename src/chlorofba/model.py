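"""Domain types for compartmented stoichiometric networks.

A :class:`MetabolicModel` is an ordered collection of compartment-tagged
metabolites and mass-balanced reactions.  Metabolites living in the
``external`` pseudo-compartment are exempt from the steady-state balance;
everything else contributes one row to the stoichiometric matrix ``S``
(m internal metabolites x n reactions), whose columns follow reaction
insertion order so that ``S`` is reproducible bit-for-bit across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set

import numpy as np

EXTERNAL = "external"

#: compartments of the leaf cell model; models may declare their own set
DEFAULT_COMPARTMENTS = ("cytosol", "chloroplast", "mitochondrion", "peroxisome", EXTERNAL)

#: conventional "unbounded" flux magnitude (large relative to any flux of interest)
DEFAULT_UB = 1000.0


class ModelIntegrityError(ValueError):
    """A reaction references an undeclared metabolite, or an invariant is broken."""


@dataclass
class Metabolite:
    """A chemical species tagged with its compartment.

    ``is_external`` is derived: true iff the compartment is ``external``.
    External species act as unbalanced sources/sinks.
    """

    id: str
    compartment: str
    name: str = ""

    @property
    def is_external(self) -> bool:
        return self.compartment == EXTERNAL


@dataclass
class Reaction:
    """A stoichiometry map plus bounds; one column of S.

    ``stoich`` maps metabolite id to a signed coefficient (negative =
    consumed, positive = produced).  ``reversible`` must equal ``lb < 0``.
    ``gpr`` is an optional boolean gene-association expression such as
    ``"g1 AND (g2 OR g3)"``.
    """

    id: str
    stoich: Dict[str, float]
    lb: float = 0.0
    ub: float = DEFAULT_UB
    subsystem: str = ""
    gpr: Optional[str] = None
    is_transporter: bool = False

    def __post_init__(self) -> None:
        if not self.stoich:
            raise ModelIntegrityError(f"reaction {self.id!r}: empty stoichiometry")
        zero = [m for m, c in self.stoich.items() if c == 0]
        if zero:
            raise ModelIntegrityError(f"reaction {self.id!r}: zero coefficient for {zero}")
        if self.lb > self.ub:
            raise ModelIntegrityError(f"reaction {self.id!r}: lb {self.lb} > ub {self.ub}")

    @property
    def reversible(self) -> bool:
        return self.lb < 0

    def equation(self) -> str:
        """Render the reaction in the plain-text equation grammar."""

        def side(items: List[tuple]) -> str:
            parts = []
            for met, coef in items:
                parts.append(met if coef == 1 else f"{_fmt_coef(coef)} {met}")
            return " + ".join(parts)

        subs = [(m, -c) for m, c in self.stoich.items() if c < 0]
        prods = [(m, c) for m, c in self.stoich.items() if c > 0]
        arrow = "<>" if self.reversible else "->"
        return f"{side(subs)} {arrow} {side(prods)}".strip()


def _fmt_coef(c: float) -> str:
    return str(int(c)) if float(c).is_integer() else repr(float(c))


class MetabolicModel:
    """A compartmented reaction network with a deterministic ordering."""

    def __init__(self, model_id: str = "model",
                 compartments: Iterable[str] = DEFAULT_COMPARTMENTS) -> None:
        self.id = model_id
        self.compartments: Set[str] = set(compartments) | {EXTERNAL}
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        #: optional nitrogen atom counts, metabolite id -> int (fixture supplies them)
        self.nitrogen_atoms: Dict[str, int] = {}

    # -- construction -------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ModelIntegrityError(f"duplicate metabolite id {met.id!r}")
        if met.compartment not in self.compartments:
            raise ModelIntegrityError(
                f"metabolite {met.id!r}: undeclared compartment {met.compartment!r}")
        self.metabolites[met.id] = met
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ModelIntegrityError(f"duplicate reaction id {rxn.id!r}")
        missing = [m for m in rxn.stoich if m not in self.metabolites]
        if missing:
            raise ModelIntegrityError(
                f"reaction {rxn.id!r} references undeclared metabolite(s) {missing}")
        self.reactions[rxn.id] = rxn
        return rxn

    # -- views ---------------------------------------------------------
    @property
    def genes(self) -> Set[str]:
        from .gpr import gpr_genes

        out: Set[str] = set()
        for rxn in self.reactions.values():
            if rxn.gpr:
                out |= gpr_genes(rxn.gpr)
        return out

    def internal_metabolites(self) -> List[str]:
        return [m.id for m in self.metabolites.values() if not m.is_external]

    def compartment_of(self, rxn: Reaction) -> str:
        """Dominant compartment of a reaction: the unique internal compartment
        touched, or 'transport' when it spans several."""
        comps = {self.metabolites[m].compartment for m in rxn.stoich}
        comps.discard(EXTERNAL)
        if len(comps) == 1:
            return comps.pop()
        return "transport"

    def copy(self) -> "MetabolicModel":
        clone = MetabolicModel(self.id, self.compartments)
        for met in self.metabolites.values():
            clone.add_metabolite(Metabolite(met.id, met.compartment, met.name))
        for rxn in self.reactions.values():
            clone.add_reaction(Reaction(rxn.id, dict(rxn.stoich), rxn.lb, rxn.ub,
                                        rxn.subsystem, rxn.gpr, rxn.is_transporter))
        clone.nitrogen_atoms = dict(self.nitrogen_atoms)
        return clone

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
                f"{len(self.reactions)} reactions>")


def build_stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """Dense S over internal metabolites only.

    Row order follows metabolite insertion order (externals skipped); column
    order follows reaction insertion order.
    """
    internal = model.internal_metabolites()
    row = {m: i for i, m in enumerate(internal)}
    S = np.zeros((len(internal), len(model.reactions)))
    for j, rxn in enumerate(model.reactions.values()):
        for met, coef in rxn.stoich.items():
            if met not in model.metabolites:
                raise ModelIntegrityError(
                    f"reaction {rxn.id!r} references undeclared metabolite {met!r}")
            i = row.get(met)
            if i is not None:
                S[i, j] = coef
    return S


@dataclass
class ConsistencyReport:
    """Structural (topology-only) audit of the network."""

    orphan_metabolites: List[str] = field(default_factory=list)
    dead_ends: Dict[str, List[str]] = field(default_factory=dict)

    @property
    def clean(self) -> bool:
        return not self.orphan_metabolites and not self.dead_ends


def check_structural_consistency(model: MetabolicModel) -> ConsistencyReport:
    """Report internal metabolites that can never carry steady-state flux.

    A metabolite participating in a reversible reaction counts as both
    producible and consumable.  Orphans are declared but never referenced.
    """
    produced: Set[str] = set()
    consumed: Set[str] = set()
    touching: Dict[str, List[str]] = {}
    for rxn in model.reactions.values():
        for met, coef in rxn.stoich.items():
            touching.setdefault(met, []).append(rxn.id)
            if rxn.reversible or coef > 0:
                produced.add(met)
            if rxn.reversible or coef < 0:
                consumed.add(met)
    report = ConsistencyReport()
    for met_id in model.internal_metabolites():
        if met_id not in touching:
            report.orphan_metabolites.append(met_id)
        elif met_id not in produced or met_id not in consumed:
            report.dead_ends[met_id] = sorted(touching[met_id])
    return report
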