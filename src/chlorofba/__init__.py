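"""chlorofba: constraint-based analysis of chlorophyll biosynthesis in a
compartmented leaf cell.

Flux-minimization FBA, flux variability analysis, reaction/gene deletion
essentiality, Rubisco carboxylase:oxygenase coupling and ammonia-transporter
scenario scans, exercised on a curated reduced leaf model and on synthetic
networks with known ground truth.
"""

from .model import (MetabolicModel, Metabolite, Reaction,
                    build_stoichiometric_matrix, check_structural_consistency)
from .io import read_model, write_model, import_sbml
from .fba import (FluxSolution, RatioConstraint, minimize_total_flux,
                  solve_lp, add_ratio_constraint, build_total_flux_lp)
from .fva import run_fva, classify_by_variability, FVAResult
from .essentiality import (reaction_deletion_scan, gene_deletion_scan,
                           extract_active_pathway, EssentialityReport)
from .scenarios import (Scenario, case1, case2, get_scenario,
                        run_ammonia_scan, run_gs2_experiment, compare_cases)
from .fixture import (build_leaf_fixture, generate_synthetic_network,
                      nitrogen_audit, nitrogen_import)
from .validation import energy_redox_leak_test, audit_solution

__version__ = "0.1.0"

__all__ = [
    "MetabolicModel", "Metabolite", "Reaction",
    "build_stoichiometric_matrix", "check_structural_consistency",
    "read_model", "write_model", "import_sbml",
    "FluxSolution", "RatioConstraint", "minimize_total_flux", "solve_lp",
    "add_ratio_constraint", "build_total_flux_lp",
    "run_fva", "classify_by_variability", "FVAResult",
    "reaction_deletion_scan", "gene_deletion_scan", "extract_active_pathway",
    "EssentialityReport",
    "Scenario", "case1", "case2", "get_scenario",
    "run_ammonia_scan", "run_gs2_experiment", "compare_cases",
    "build_leaf_fixture", "generate_synthetic_network",
    "nitrogen_audit", "nitrogen_import",
    "energy_redox_leak_test", "audit_solution",
]


def load_leaf_model():
    """Load the bundled reduced leaf model from its packaged .rxn file.

    Equivalent to :func:`build_leaf_fixture` (same S, bounds and gene
    associations); reading the file exercises the text format end to end.
    """
    from importlib.resources import as_file, files
    from . import io as _io

    with as_file(files("chlorofba") / "data" / "leaf.rxn") as p:
        model = _io.read_model(p, model_id="leaf_reduced")
    from .fixture import NITROGEN_ATOMS, _species_of
    for met_id in model.metabolites:
        n = NITROGEN_ATOMS.get(_species_of(met_id))
        model.nitrogen_atoms[met_id] = n if n is not None else 0
    return model
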