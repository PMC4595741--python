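"""Read and write models in the plain-text reaction (.rxn) format.

One reaction per line, tab-separated columns::

    id <TAB> equation <TAB> lb ub <TAB> subsystem <TAB> gpr

The equation grammar is ``coef met (+ coef met)* ARROW coef met (+ coef met)*``
with the coefficient omitted when 1; ``->`` marks an irreversible and ``<>``
a reversible reaction.  Metabolite ids match ``[A-Za-z0-9_\\-.]+``; their
compartment is taken from the id prefix (``cyt_``, ``chl_``, ``mit_``,
``per_``, ``x_`` for external).  Lines starting with ``#`` are comments.
Bounds default to [0, 1000] (irreversible) or [-1000, 1000] (reversible)
when the bounds column is empty.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

from .model import (DEFAULT_UB, MetabolicModel, Metabolite, Reaction)

_PREFIXES = {"cyt": "cytosol", "chl": "chloroplast", "mit": "mitochondrion",
             "per": "peroxisome", "x": "external"}
_MET_ID = re.compile(r"^[A-Za-z0-9_\-.]+$")
_NUMBER = re.compile(r"^[0-9]*\.?[0-9]+$")


class RxnParseError(ValueError):
    def __init__(self, message: str, line: int, column: Optional[int] = None):
        loc = f"line {line}" + (f", column {column}" if column is not None else "")
        super().__init__(f"{message} ({loc})")
        self.line = line
        self.column = column


def _compartment_for(met_id: str, line_no: int) -> str:
    prefix = met_id.split("_", 1)[0]
    comp = _PREFIXES.get(prefix)
    if comp is None:
        warnings.warn(
            f"unknown compartment prefix in {met_id!r} (line {line_no}); "
            "assigning to cytosol", stacklevel=2)
        return "cytosol"
    return comp


def parse_equation(text: str, line_no: int = 0) -> Tuple[Dict[str, float], bool]:
    """Parse one equation string into (stoich, reversible)."""
    if "<>" in text:
        arrow, reversible = "<>", True
    elif "->" in text:
        arrow, reversible = "->", False
    else:
        raise RxnParseError(f"missing or malformed arrow in {text!r}", line_no)
    left, _, right = text.partition(arrow)
    stoich: Dict[str, float] = {}

    def add_side(side: str, sign: int) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            tokens = term.split()
            if len(tokens) == 1:
                coef, met = 1.0, tokens[0]
            elif len(tokens) == 2:
                if not _NUMBER.match(tokens[0]):
                    raise RxnParseError(
                        f"unparseable coefficient {tokens[0]!r}", line_no)
                coef, met = float(tokens[0]), tokens[1]
            else:
                raise RxnParseError(f"malformed term {term.strip()!r}", line_no)
            if not _MET_ID.match(met):
                raise RxnParseError(f"invalid metabolite id {met!r}", line_no)
            stoich[met] = stoich.get(met, 0.0) + sign * coef
            if stoich[met] == 0:
                del stoich[met]

    add_side(left, -1)
    add_side(right, +1)
    if not stoich:
        raise RxnParseError(f"equation {text!r} has no net stoichiometry", line_no)
    return stoich, reversible


def read_model(path: Union[str, Path], model_id: Optional[str] = None
               ) -> MetabolicModel:
    path = Path(path)
    model = MetabolicModel(model_id or path.stem)
    seen_ids = set()
    for line_no, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = [c.strip() for c in raw.split("\t")]
        if len(cols) < 2:
            raise RxnParseError("expected at least id and equation columns", line_no)
        rxn_id, equation = cols[0], cols[1]
        if rxn_id in seen_ids:
            raise RxnParseError(f"duplicate reaction id {rxn_id!r}", line_no)
        seen_ids.add(rxn_id)
        stoich, reversible = parse_equation(equation, line_no)

        bounds_col = cols[2] if len(cols) > 2 and cols[2] else ""
        if bounds_col:
            parts = bounds_col.split()
            if len(parts) != 2:
                raise RxnParseError(
                    f"bounds column must hold two numbers, got {bounds_col!r}",
                    line_no)
            try:
                lb, ub = float(parts[0]), float(parts[1])
            except ValueError:
                raise RxnParseError(
                    f"unparseable bound in {bounds_col!r}", line_no) from None
        else:
            lb, ub = (-DEFAULT_UB, DEFAULT_UB) if reversible else (0.0, DEFAULT_UB)
        subsystem = cols[3] if len(cols) > 3 else ""
        gpr = cols[4] if len(cols) > 4 and cols[4] else None

        for met_id in stoich:
            if met_id not in model.metabolites:
                model.add_metabolite(
                    Metabolite(met_id, _compartment_for(met_id, line_no)))
        model.add_reaction(Reaction(rxn_id, stoich, lb=lb, ub=ub,
                                    subsystem=subsystem, gpr=gpr,
                                    is_transporter=_spans(model, stoich)))
    return model


def _spans(model: MetabolicModel, stoich: Dict[str, float]) -> bool:
    return len({model.metabolites[m].compartment for m in stoich}) > 1


def write_model(model: MetabolicModel, path: Union[str, Path]) -> None:
    """Serialize; ``read_model(write_model(m))`` reproduces S, bounds, gprs."""
    path = Path(path)
    lines = [f"# {model.id}: {len(model.metabolites)} metabolites, "
             f"{len(model.reactions)} reactions",
             "# id\tequation\tlb ub\tsubsystem\tgpr"]
    for rxn in model.reactions.values():
        lb = _fmt(rxn.lb)
        ub = _fmt(rxn.ub)
        lines.append("\t".join([rxn.id, rxn.equation(), f"{lb} {ub}",
                                rxn.subsystem, rxn.gpr or ""]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# SBML import (read-only)
# ---------------------------------------------------------------------------

class SBMLImportError(ValueError):
    pass


def import_sbml(path: Union[str, Path]) -> MetabolicModel:
    """Import an SBML Level 2/3 model.

    Species with ``boundaryCondition=true`` become external metabolites;
    bounds default to [0, 1000] / [-1000, 1000] by reversibility when the
    file carries no flux-bound annotations (fbc bounds are honoured when
    present).
    """
    try:
        import libsbml
    except ImportError as exc:  # pragma: no cover
        raise SBMLImportError(
            "python-libsbml is required for SBML import") from exc

    doc = libsbml.readSBMLFromString(Path(path).read_text(encoding="utf-8"))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise SBMLImportError(
            doc.getErrorLog().toString() or "invalid SBML document")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLImportError("file contains no SBML model")

    model = MetabolicModel(sbml_model.getId() or "sbml_model")
    compartments = {c.getId() for c in sbml_model.getListOfCompartments()}
    model.compartments |= compartments

    for sp in sbml_model.getListOfSpecies():
        comp = "external" if sp.getBoundaryCondition() else \
            (sp.getCompartment() or "cytosol")
        model.add_metabolite(Metabolite(sp.getId(), comp, sp.getName() or ""))

    params = {p.getId(): p.getValue()
              for p in sbml_model.getListOfParameters()}
    for rx in sbml_model.getListOfReactions():
        stoich: Dict[str, float] = {}
        for ref in rx.getListOfReactants():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) \
                - (ref.getStoichiometry() or 1.0)
        for ref in rx.getListOfProducts():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) \
                + (ref.getStoichiometry() or 1.0)
        stoich = {m: c for m, c in stoich.items() if c != 0}
        if not stoich:
            continue
        reversible = rx.getReversible()
        lb, ub = (-DEFAULT_UB, DEFAULT_UB) if reversible else (0.0, DEFAULT_UB)
        rfbc = rx.getPlugin("fbc")
        if rfbc is not None:
            if rfbc.isSetLowerFluxBound():
                lb = params.get(rfbc.getLowerFluxBound(), lb)
            if rfbc.isSetUpperFluxBound():
                ub = params.get(rfbc.getUpperFluxBound(), ub)
        model.add_reaction(Reaction(rx.getId(), stoich, lb=lb, ub=ub,
                                    is_transporter=_spans(model, stoich)))
    return model
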