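"""The curated reduced leaf-cell network and synthetic test networks.

``build_leaf_fixture`` encodes a four-compartment (cytosol, chloroplast,
mitochondrion, peroxisome) stoichiometric model of chlorophyll-a synthesis
from inorganic nutrients and light:

* the tetrapyrrole branch in the chloroplast (8 Glu and 1 SAM per
  chlorophyll; the porphobilinogen -> hydroxymethylbilane step releases the
  4 excess ring nitrogens as ammonia),
* GS/GOGAT nitrogen assimilation in two compartments (cytosolic GS1,
  chloroplastic GS2, one NADPH-dependent chloroplastic GOGAT),
* the cytosolic methyl cycle regenerating SAM from AdoHcy, fed one-carbon
  units through cytosolic SHMT and closed by mitochondrial GDC/SHMT,
* the phosphoserine route for de-novo serine,
* the Calvin cycle with separable Rubisco carboxylase/oxygenase, the C2
  photorespiratory cycle through the peroxisome, two lumped light reactions,
* the organellar shuttles (Mal-OAA, Mal-Glu, Mal-2OG, Glu-Gln, SAM/AdoHcy)
  and the cytosolic and chloroplastic ammonia importers.

Chlorophyll export (4 N per molecule) is the only nitrogen sink, so every
feasible steady state imports exactly 4 units of ammonia per chlorophyll.
The chloroplast-to-cytosol ammonia diffusion step is present but bounded to
zero; scenarios may open it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import numpy as np

from .model import DEFAULT_UB, MetabolicModel, Metabolite, Reaction

# reaction ids that downstream modules refer to by name
CHLOROPHYLL_TX = "chlorophyll_tx"
CYT_NH3_TX = "NH_3__tx"            # external ammonia -> cytosol
CHL_NH3_TX = "ex_ammonia_tx"        # external ammonia -> chloroplast
NH3_DIFFUSION = "NH3_chl_cyt_diff"  # chloroplast -> cytosol, closed by default
RUBISCO_CARB = "chl_RuBisCO_carb"
RUBISCO_OXY = "chl_RuBisCO_oxy"
GLU_TO_ALA = "chl_GluALA"
HMB_SYNTHASE = "chl_HMBS"
GS1 = "cyt_GS1"
GS2 = "chl_GS2"
GOGAT = "chl_GOGAT"
GDC = "mit_GDC"
SHMT_MIT = "mit_SHMT"
MAL_2OG_TX = "Mal_2OG_chl_tx"
MAL_GLU_TX = "Mal_Glu_chl_tx"
MAL_OAA_TX = "Mal_OAA_chl_tx"
GLU_GLN_TX = "Glu_Gln_chl_tx"
NH3_MIT_CHL_TX = "NH3_mit_chl_tx"
PHOTON_TX = "Photon_tx"

_COMP_PREFIX = {"cytosol": "cyt", "chloroplast": "chl",
                "mitochondrion": "mit", "peroxisome": "per"}

#: nitrogen atom counts per species (compartment-independent); cofactor and
#: carrier moieties (adenine nucleotides, NAD(P), folates, adenosine) are
#: booked as nitrogen-free so that conserved pools stay out of the audit.
NITROGEN_ATOMS: Dict[str, int] = {
    "NH3": 1, "Glu": 1, "Gln": 2, "Gly": 1, "Ser": 1, "PSer": 1,
    "Met": 1, "Hcy": 1, "SAM": 1, "AdoHcy": 1,
    "ALA": 1, "PBG": 2, "HMB": 4, "UroIII": 4, "CoproIII": 4,
    "ProtogenIX": 4, "ProtoIX": 4, "MgPP": 4, "MgPPME": 4,
    "DVPchlide": 4, "Pchlide": 4, "Chlide": 4, "Chla": 4,
}


def _species_of(met_id: str) -> str:
    return met_id.split("_", 1)[1] if "_" in met_id else met_id


class _Builder:
    def __init__(self, model_id: str):
        self.model = MetabolicModel(model_id)

    def met(self, met_id: str) -> str:
        if met_id not in self.model.metabolites:
            if met_id.startswith("x_"):
                comp = "external"
            else:
                prefix = met_id.split("_", 1)[0]
                comp = {v: k for k, v in _COMP_PREFIX.items()}.get(prefix, "cytosol")
            self.model.add_metabolite(Metabolite(met_id, comp))
            n = NITROGEN_ATOMS.get(_species_of(met_id))
            if n is not None:
                self.model.nitrogen_atoms[met_id] = n
            elif comp != "external" or _species_of(met_id) in NITROGEN_ATOMS:
                self.model.nitrogen_atoms[met_id] = 0
        return met_id

    def rxn(self, rxn_id: str, stoich: Dict[str, float], rev: bool = False,
            subsystem: str = "", gpr: Optional[str] = None,
            lb: Optional[float] = None, ub: Optional[float] = None) -> None:
        for m in stoich:
            self.met(m)
        comps = {self.model.metabolites[m].compartment for m in stoich}
        is_tx = len(comps) > 1
        self.model.add_reaction(Reaction(
            rxn_id, stoich,
            lb=(-DEFAULT_UB if rev else 0.0) if lb is None else lb,
            ub=DEFAULT_UB if ub is None else ub,
            subsystem=subsystem, gpr=gpr, is_transporter=is_tx))


def build_leaf_fixture() -> MetabolicModel:
    """Construct the reduced leaf-cell model (see module docstring)."""
    b = _Builder("leaf_reduced")
    R = b.rxn

    # ---- light reactions (lumped) and photon supply --------------------
    # non-cyclic photophosphorylation: 8 photons -> 2 NADPH + 2 ATP + O2;
    # cyclic: 2 photons -> 1 ATP.  Ratios are a documented modelling choice.
    # photon flux runs an order of magnitude above metabolic fluxes, so the
    # light reactions carry explicit wide bounds instead of the 1000 default
    R(PHOTON_TX, {"x_Photon": -1, "chl_Photon": 1}, ub=10000.0, subsystem="light")
    R("chl_LightNonCyclic",
      {"chl_Photon": -8, "chl_NADP": -2, "chl_ADP": -2, "chl_Pi": -2,
       "chl_NADPH": 2, "chl_ATP": 2, "chl_O2": 1},
      ub=10000.0, subsystem="light")
    R("chl_LightCyclic",
      {"chl_Photon": -2, "chl_ADP": -1, "chl_Pi": -1,
       "chl_ATP": 1, "chl_H2O": 1},
      ub=10000.0, subsystem="light")

    # ---- Calvin cycle (chloroplast) ------------------------------------
    R(RUBISCO_CARB, {"chl_RuBP": -1, "chl_CO2": -1, "chl_H2O": -1, "chl_PGA": 2},
      subsystem="calvin", gpr="OsRBCS AND OsRBCL")
    R(RUBISCO_OXY, {"chl_RuBP": -1, "chl_O2": -1, "chl_PGA": 1, "chl_PGlyc": 1},
      subsystem="calvin", gpr="OsRBCS AND OsRBCL")
    R("chl_PGK", {"chl_PGA": -1, "chl_ATP": -1, "chl_BPG": 1, "chl_ADP": 1},
      subsystem="calvin")
    R("chl_GAPDH", {"chl_BPG": -1, "chl_NADPH": -1,
                    "chl_GAP": 1, "chl_NADP": 1, "chl_Pi": 1},
      subsystem="calvin")
    R("chl_TPI", {"chl_GAP": -1, "chl_DHAP": 1}, rev=True, subsystem="calvin")
    R("chl_FBA", {"chl_GAP": -1, "chl_DHAP": -1, "chl_FBP": 1}, subsystem="calvin")
    R("chl_FBPase", {"chl_FBP": -1, "chl_H2O": -1, "chl_F6P": 1, "chl_Pi": 1},
      subsystem="calvin")
    R("chl_TK1", {"chl_F6P": -1, "chl_GAP": -1, "chl_X5P": 1, "chl_E4P": 1},
      subsystem="calvin")
    R("chl_SBA", {"chl_E4P": -1, "chl_DHAP": -1, "chl_SBP": 1}, subsystem="calvin")
    R("chl_SBPase", {"chl_SBP": -1, "chl_H2O": -1, "chl_S7P": 1, "chl_Pi": 1},
      subsystem="calvin")
    R("chl_TK2", {"chl_S7P": -1, "chl_GAP": -1, "chl_X5P": 1, "chl_R5P": 1},
      subsystem="calvin")
    R("chl_RPE", {"chl_X5P": -1, "chl_Ru5P": 1}, rev=True, subsystem="calvin")
    R("chl_RPI", {"chl_R5P": -1, "chl_Ru5P": 1}, rev=True, subsystem="calvin")
    R("chl_PRK", {"chl_Ru5P": -1, "chl_ATP": -1, "chl_RuBP": 1, "chl_ADP": 1},
      subsystem="calvin")

    # lower chloroplast carbon metabolism feeding the rest of the cell
    R("chl_PGM_ENO", {"chl_PGA": -1, "chl_PEP": 1, "chl_H2O": 1}, rev=True,
      subsystem="glycolysis")
    R("chl_PK", {"chl_PEP": -1, "chl_ADP": -1, "chl_Pyr": 1, "chl_ATP": 1},
      subsystem="glycolysis")
    R("chl_PEPC", {"chl_PEP": -1, "chl_CO2": -1, "chl_H2O": -1,
                   "chl_OAA": 1, "chl_Pi": 1}, subsystem="anaplerosis")
    R("chl_MDH", {"chl_OAA": -1, "chl_NADPH": -1, "chl_Mal": 1, "chl_NADP": 1},
      subsystem="anaplerosis")
    R("chl_PPase", {"chl_PPi": -1, "chl_H2O": -1, "chl_Pi": 2},
      subsystem="housekeeping")

    # ---- chlorophyll branch (chloroplast) ------------------------------
    R(GLU_TO_ALA,
      {"chl_Glu": -1, "chl_ATP": -1, "chl_NADPH": -1,
       "chl_ALA": 1, "chl_ADP": 1, "chl_Pi": 1, "chl_NADP": 1},
      subsystem="tetrapyrrole", gpr="OsHEMA AND OsGSA")
    R("chl_ALAD", {"chl_ALA": -2, "chl_PBG": 1, "chl_H2O": 2},
      subsystem="tetrapyrrole", gpr="OsALAD")
    R(HMB_SYNTHASE, {"chl_PBG": -4, "chl_H2O": -1, "chl_HMB": 1, "chl_NH3": 4},
      subsystem="tetrapyrrole", gpr="OsPBGD")
    R("chl_UROS", {"chl_HMB": -1, "chl_UroIII": 1, "chl_H2O": 1},
      subsystem="tetrapyrrole")
    R("chl_UROD", {"chl_UroIII": -1, "chl_CoproIII": 1, "chl_CO2": 4},
      subsystem="tetrapyrrole")
    R("chl_CPO", {"chl_CoproIII": -1, "chl_O2": -1,
                  "chl_ProtogenIX": 1, "chl_CO2": 2, "chl_H2O": 2},
      subsystem="tetrapyrrole", gpr="OsCPO")
    R("chl_PPO", {"chl_ProtogenIX": -1, "chl_O2": -1.5,
                  "chl_ProtoIX": 1, "chl_H2O": 3},
      subsystem="tetrapyrrole", gpr="OsPPO")
    R("chl_MgCh", {"chl_ProtoIX": -1, "chl_ATP": -1, "chl_H2O": -1,
                   "chl_MgPP": 1, "chl_ADP": 1, "chl_Pi": 1},
      subsystem="tetrapyrrole", gpr="OsCHLH AND OsCHLI AND OsCHLD")
    R("chl_CHLM", {"chl_MgPP": -1, "chl_SAM": -1, "chl_MgPPME": 1, "chl_AdoHcy": 1},
      subsystem="tetrapyrrole", gpr="OsCHLM")
    R("chl_CYC", {"chl_MgPPME": -1, "chl_O2": -1, "chl_NADPH": -1,
                  "chl_DVPchlide": 1, "chl_NADP": 1, "chl_H2O": 2},
      subsystem="tetrapyrrole")
    R("chl_DVR", {"chl_DVPchlide": -1, "chl_NADPH": -1,
                  "chl_Pchlide": 1, "chl_NADP": 1},
      subsystem="tetrapyrrole")
    R("chl_POR", {"chl_Pchlide": -1, "chl_NADPH": -1, "chl_Chlide": 1, "chl_NADP": 1},
      subsystem="tetrapyrrole", gpr="OsPORA OR OsPORB")
    R("chl_CHLSYN", {"chl_Chlide": -1, "chl_PhyPP": -1, "chl_Chla": 1, "chl_PPi": 1},
      subsystem="tetrapyrrole", gpr="OsCHLG")
    # isoprenoid tail: lumped MEP pathway to GGPP, then geranylgeranyl reductase
    R("chl_MEP_GGPP",
      {"chl_Pyr": -4, "chl_GAP": -4, "chl_ATP": -4, "chl_NADPH": -4,
       "chl_GGPP": 1, "chl_CO2": 4, "chl_ADP": 4, "chl_Pi": 4,
       "chl_NADP": 4, "chl_PPi": 3},
      subsystem="isoprenoid")
    R("chl_GGR", {"chl_GGPP": -1, "chl_NADPH": -3, "chl_PhyPP": 1, "chl_NADP": 3},
      subsystem="isoprenoid", gpr="OsCHLP")
    R(CHLOROPHYLL_TX, {"chl_Chla": -1, "x_Chla": 1}, subsystem="demand")

    # ---- nitrogen assimilation -----------------------------------------
    R(GS2, {"chl_Glu": -1, "chl_NH3": -1, "chl_ATP": -1,
            "chl_Gln": 1, "chl_ADP": 1, "chl_Pi": 1},
      subsystem="nitrogen", gpr="OsGS2")
    R(GS1, {"cyt_Glu": -1, "cyt_NH3": -1, "cyt_ATP": -1,
            "cyt_Gln": 1, "cyt_ADP": 1, "cyt_Pi": 1},
      subsystem="nitrogen", gpr="OsGS1;1 OR OsGS1;2")
    # NADPH-dependent chloroplastic GOGAT, the network's sole Glu source;
    # leaves also carry a ferredoxin-dependent isoform (EC 1.4.7.1), not
    # modelled — one NADPH-linked GOGAT stands for the pooled activity
    R(GOGAT, {"chl_Gln": -1, "chl_2OG": -1, "chl_NADPH": -1,
              "chl_Glu": 2, "chl_NADP": 1},
      subsystem="nitrogen", gpr="OsNADH-GOGAT")

    # ---- cytosolic methyl cycle and serine/glycine metabolism ----------
    R("cyt_SHMT", {"cyt_Ser": -1, "cyt_THF": -1,
                   "cyt_Gly": 1, "cyt_MeTHF": 1, "cyt_H2O": 1},
      rev=True, subsystem="methyl_cycle", gpr="OsSHMT1")
    R("cyt_MTHFR", {"cyt_MeTHF": -1, "cyt_NADH": -1, "cyt_5MeTHF": 1, "cyt_NAD": 1},
      subsystem="methyl_cycle", gpr="OsMTHFR")
    R("cyt_MS", {"cyt_Hcy": -1, "cyt_5MeTHF": -1, "cyt_Met": 1, "cyt_THF": 1},
      subsystem="methyl_cycle", gpr="OsMS")
    R("cyt_SAMS", {"cyt_Met": -1, "cyt_ATP": -1, "cyt_H2O": -1,
                   "cyt_SAM": 1, "cyt_PPi": 1, "cyt_Pi": 1},
      subsystem="methyl_cycle", gpr="OsSAMS1 OR OsSAMS2")
    R("cyt_SAHH", {"cyt_AdoHcy": -1, "cyt_H2O": -1, "cyt_Hcy": 1, "cyt_Adenosine": 1},
      subsystem="methyl_cycle", gpr="OsSAHH")
    R("cyt_ADNSALV", {"cyt_Adenosine": -1, "cyt_ATP": -1, "cyt_ADP": 1, "cyt_AMP": 1},
      subsystem="methyl_cycle")
    R("cyt_ADK", {"cyt_AMP": -1, "cyt_ATP": -1, "cyt_ADP": 2},
      subsystem="housekeeping")
    R("cyt_PPase", {"cyt_PPi": -1, "cyt_H2O": -1, "cyt_Pi": 2},
      subsystem="housekeeping")
    # phosphoserine route for de-novo serine
    R("cyt_PGADH", {"cyt_PGA": -1, "cyt_NAD": -1, "cyt_PHP": 1, "cyt_NADH": 1},
      subsystem="serine")
    R("cyt_PSAT", {"cyt_PHP": -1, "cyt_Glu": -1, "cyt_PSer": 1, "cyt_2OG": 1},
      subsystem="serine")
    R("cyt_PSP", {"cyt_PSer": -1, "cyt_H2O": -1, "cyt_Ser": 1, "cyt_Pi": 1},
      subsystem="serine")
    # citrate synthesis and cytosolic redox
    R("cyt_PDH", {"cyt_Pyr": -1, "cyt_CoA": -1, "cyt_NAD": -1,
                  "cyt_AcCoA": 1, "cyt_CO2": 1, "cyt_NADH": 1},
      subsystem="carbon")
    R("cyt_CS", {"cyt_OAA": -1, "cyt_AcCoA": -1, "cyt_H2O": -1,
                 "cyt_CIT": 1, "cyt_CoA": 1},
      subsystem="carbon")
    R("cyt_MDH", {"cyt_OAA": -1, "cyt_NADH": -1, "cyt_Mal": 1, "cyt_NAD": 1},
      rev=True, subsystem="carbon")
    # mitochondrial outer-surface NADH oxidation (external dehydrogenase
    # feeding the alternative path; no ATP yield)
    R("cyt_NDex", {"cyt_NADH": -1, "cyt_O2": -0.5, "cyt_NAD": 1, "cyt_H2O": 1},
      subsystem="respiration")

    # ---- mitochondrion --------------------------------------------------
    R("mit_ACON", {"mit_CIT": -1, "mit_ICIT": 1}, rev=True,
      subsystem="tca", gpr="OsACO")
    R("mit_ICDH", {"mit_ICIT": -1, "mit_NAD": -1,
                   "mit_2OG": 1, "mit_CO2": 1, "mit_NADH": 1},
      subsystem="tca", gpr="OsICDH")
    R(GDC, {"mit_Gly": -1, "mit_THF": -1, "mit_NAD": -1,
            "mit_MeTHF": 1, "mit_NH3": 1, "mit_CO2": 1, "mit_NADH": 1},
      subsystem="photorespiration", gpr="OsGLDC AND OsGCSH")
    R(SHMT_MIT, {"mit_MeTHF": -1, "mit_Gly": -1, "mit_H2O": -1,
                 "mit_Ser": 1, "mit_THF": 1},
      subsystem="photorespiration", gpr="OsSHMT2")
    R("mit_ETC", {"mit_NADH": -1, "mit_O2": -0.5, "mit_ADP": -2.5, "mit_Pi": -2.5,
                  "mit_NAD": 1, "mit_ATP": 2.5, "mit_H2O": 3.5},
      subsystem="respiration")
    R("mit_AOX", {"mit_NADH": -1, "mit_O2": -0.5, "mit_NAD": 1, "mit_H2O": 1},
      subsystem="respiration")

    # ---- peroxisome (C2 cycle) ------------------------------------------
    R("per_GOX", {"per_Glycolate": -1, "per_O2": -1,
                  "per_Glyoxylate": 1, "per_H2O2": 1},
      subsystem="photorespiration", gpr="OsGLO")
    R("per_CAT", {"per_H2O2": -1, "per_H2O": 1, "per_O2": 0.5},
      subsystem="photorespiration", gpr="OsCATA")
    # combined serine:glyoxylate aminotransferase + hydroxypyruvate reductase
    R("per_SGAT_HPR", {"per_Ser": -1, "per_Glyoxylate": -1, "per_NADH": -1,
                       "per_Gly": 1, "per_Glycerate": 1, "per_NAD": 1},
      subsystem="photorespiration")
    R("per_GGAT", {"per_Glu": -1, "per_Glyoxylate": -1, "per_Gly": 1, "per_2OG": 1},
      subsystem="photorespiration")
    R("per_MDH", {"per_Mal": -1, "per_NAD": -1, "per_OAA": 1, "per_NADH": 1},
      subsystem="photorespiration")
    # chloroplast legs of the C2 cycle
    R("chl_PGP", {"chl_PGlyc": -1, "chl_H2O": -1, "chl_Glycolate": 1, "chl_Pi": 1},
      subsystem="photorespiration")
    R("chl_GLYK", {"chl_Glycerate": -1, "chl_ATP": -1, "chl_PGA": 1, "chl_ADP": 1},
      subsystem="photorespiration")

    # ---- transporters ----------------------------------------------------
    # chloroplast envelope shuttles
    R(MAL_2OG_TX, {"cyt_2OG": -1, "chl_Mal": -1, "chl_2OG": 1, "cyt_Mal": 1},
      subsystem="shuttle")
    R(MAL_GLU_TX, {"chl_Glu": -1, "cyt_Mal": -1, "cyt_Glu": 1, "chl_Mal": 1},
      subsystem="shuttle")
    R(MAL_OAA_TX, {"chl_OAA": -1, "cyt_Mal": -1, "cyt_OAA": 1, "chl_Mal": 1},
      rev=True, subsystem="shuttle")
    R(GLU_GLN_TX, {"cyt_Gln": -1, "chl_Glu": -1, "chl_Gln": 1, "cyt_Glu": 1},
      subsystem="shuttle")
    R("SAM_tx_T1", {"cyt_SAM": -1, "chl_SAM": 1}, subsystem="shuttle")
    R("AdoHcy_tx_T2", {"chl_AdoHcy": -1, "cyt_AdoHcy": 1}, subsystem="shuttle")
    R("PGA_chl_tx", {"chl_PGA": -1, "cyt_PGA": 1}, subsystem="shuttle")
    R("Pyr_chl_tx", {"chl_Pyr": -1, "cyt_Pyr": 1}, subsystem="shuttle")
    R("CO2_chl_tx", {"cyt_CO2": -1, "chl_CO2": 1}, rev=True, subsystem="gas")
    R("O2_chl_tx", {"chl_O2": -1, "cyt_O2": 1}, rev=True, subsystem="gas")
    R("H2O_chl_tx", {"cyt_H2O": -1, "chl_H2O": 1}, rev=True, subsystem="gas")
    R("Pi_chl_tx", {"cyt_Pi": -1, "chl_Pi": 1}, rev=True, subsystem="shuttle")
    R("Glycolate_chl_per_tx", {"chl_Glycolate": -1, "per_Glycolate": 1},
      subsystem="photorespiration")
    R("Glycerate_per_chl_tx", {"per_Glycerate": -1, "chl_Glycerate": 1},
      subsystem="photorespiration")
    # ammonia movements
    R(CYT_NH3_TX, {"x_NH3": -1, "cyt_NH3": 1}, subsystem="nitrogen")
    R(CHL_NH3_TX, {"x_NH3": -1, "chl_NH3": 1}, subsystem="nitrogen")
    R(NH3_DIFFUSION, {"chl_NH3": -1, "cyt_NH3": 1}, ub=0.0, subsystem="nitrogen")
    R(NH3_MIT_CHL_TX, {"mit_NH3": -1, "chl_NH3": 1}, subsystem="nitrogen")
    # mitochondrial membrane
    R("CIT_mit_tx", {"cyt_CIT": -1, "mit_CIT": 1}, subsystem="shuttle")
    R("OG_mit_tx", {"mit_2OG": -1, "cyt_2OG": 1}, subsystem="shuttle")
    R("Gly_mit_tx", {"cyt_Gly": -1, "mit_Gly": 1}, subsystem="shuttle")
    R("Ser_mit_tx", {"mit_Ser": -1, "cyt_Ser": 1}, subsystem="shuttle")
    R("CO2_mit_tx", {"mit_CO2": -1, "cyt_CO2": 1}, rev=True, subsystem="gas")
    R("O2_mit_tx", {"cyt_O2": -1, "mit_O2": 1}, rev=True, subsystem="gas")
    R("H2O_mit_tx", {"cyt_H2O": -1, "mit_H2O": 1}, rev=True, subsystem="gas")
    R("Pi_mit_tx", {"cyt_Pi": -1, "mit_Pi": 1}, rev=True, subsystem="shuttle")
    R("ANT_mit_tx", {"mit_ATP": -1, "cyt_ADP": -1, "cyt_ATP": 1, "mit_ADP": 1},
      subsystem="shuttle")
    # peroxisomal membrane
    R("Ser_per_tx", {"cyt_Ser": -1, "per_Ser": 1}, subsystem="photorespiration")
    R("Gly_per_tx", {"per_Gly": -1, "cyt_Gly": 1}, subsystem="photorespiration")
    R("Glu_per_tx", {"cyt_Glu": -1, "per_Glu": 1}, subsystem="photorespiration")
    R("OG_per_tx", {"per_2OG": -1, "cyt_2OG": 1}, subsystem="photorespiration")
    R("Mal_per_tx", {"cyt_Mal": -1, "per_Mal": 1}, subsystem="photorespiration")
    R("OAA_per_tx", {"per_OAA": -1, "cyt_OAA": 1}, subsystem="photorespiration")
    R("O2_per_tx", {"cyt_O2": -1, "per_O2": 1}, rev=True, subsystem="gas")
    R("H2O_per_tx", {"cyt_H2O": -1, "per_H2O": 1}, rev=True, subsystem="gas")
    # exchanges with the environment
    R("CO2_tx", {"x_CO2": -1, "cyt_CO2": 1}, rev=True, subsystem="exchange")
    R("O2_tx", {"cyt_O2": -1, "x_O2": 1}, rev=True, subsystem="exchange")
    R("H2O_tx", {"x_H2O": -1, "cyt_H2O": 1}, rev=True, subsystem="exchange")
    R("Pi_tx", {"x_Pi": -1, "cyt_Pi": 1}, rev=True, subsystem="exchange")

    # externals occurring in nitrogen bookkeeping
    b.model.nitrogen_atoms["x_NH3"] = 1
    b.model.nitrogen_atoms["x_Chla"] = 4
    return b.model


# ---------------------------------------------------------------------------
# nitrogen audit
# ---------------------------------------------------------------------------

@dataclass
class NitrogenAudit:
    imbalances: Dict[str, float] = field(default_factory=dict)
    missing_annotation: List[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.imbalances


def nitrogen_audit(model: MetabolicModel) -> NitrogenAudit:
    """Check each non-exchange reaction for zero net nitrogen.

    Reactions touching external species are the declared nitrogen entry and
    exit points and are exempt.  Metabolites missing an atom-count
    annotation are listed, not fatal.
    """
    audit = NitrogenAudit()
    for rxn in model.reactions.values():
        if any(model.metabolites[m].is_external for m in rxn.stoich):
            continue
        balance = 0.0
        ok = True
        for met, coef in rxn.stoich.items():
            n = model.nitrogen_atoms.get(met)
            if n is None:
                if met not in audit.missing_annotation:
                    audit.missing_annotation.append(met)
                ok = False
            else:
                balance += coef * n
        if ok and abs(balance) > 1e-9:
            audit.imbalances[rxn.id] = balance
    return audit


def nitrogen_import(solution, model: Optional[MetabolicModel] = None) -> float:
    """Total external ammonia entering the cell in a flux solution."""
    return solution.fluxes.get(CYT_NH3_TX, 0.0) + solution.fluxes.get(CHL_NH3_TX, 0.0)


# ---------------------------------------------------------------------------
# synthetic networks with a known-by-construction essential set
# ---------------------------------------------------------------------------

@dataclass
class SyntheticNetwork:
    model: MetabolicModel
    demand: str
    essential: Set[str]
    non_essential: Set[str]


def generate_synthetic_network(n_metabolites: int, n_reactions: int,
                               n_parallel_paths: int, seed: int
                               ) -> SyntheticNetwork:
    """Layered source->demand chain with parallel branches at random stages.

    The backbone is a linear chain of ``n_metabolites`` internal species fed
    by an import and drained by a demand export.  Stages are widened with up
    to ``n_parallel_paths`` parallel duplicate reactions until ``n_reactions``
    internal reactions exist; every reaction in a widened stage is
    non-essential by construction, every other reaction essential.  A random
    subset of single-copy stage reactions is made reversible.  Deterministic
    per seed.
    """
    if n_metabolites < 1 or n_parallel_paths < 1:
        raise ValueError("sizes must be >= 1")
    n_stages = n_metabolites + 1  # chain edges incl. entry from source species
    if n_reactions < n_stages:
        raise ValueError(
            f"need at least {n_stages} reactions for {n_metabolites} metabolites")
    # the demand edge is never widened so that fixing/deleting it stays unambiguous
    max_rxns = (n_stages - 1) * n_parallel_paths + 1
    if n_reactions > max_rxns:
        raise ValueError(
            f"at most {max_rxns} reactions possible with "
            f"{n_parallel_paths} parallel paths")
    rng = np.random.default_rng(seed)

    model = MetabolicModel(f"synthetic_{seed}",
                           compartments=("cytosol", "external"))
    species = [f"cyt_M{i}" for i in range(n_metabolites)]
    for s in species:
        model.add_metabolite(Metabolite(s, "cytosol"))
    model.add_metabolite(Metabolite("x_S", "external"))
    model.add_metabolite(Metabolite("x_P", "external"))

    chain = ["x_S"] + species + ["x_P"]
    copies = [1] * n_stages
    extra = n_reactions - n_stages
    while extra > 0:
        if n_stages == 1:
            raise ValueError("cannot widen a single-edge network")
        stage = int(rng.integers(0, n_stages - 1))
        if copies[stage] < n_parallel_paths:
            copies[stage] += 1
            extra -= 1

    essential: Set[str] = set()
    non_essential: Set[str] = set()
    demand_id = f"r{n_stages - 1}"
    for stage in range(n_stages):
        sub, prod = chain[stage], chain[stage + 1]
        for k in range(copies[stage]):
            rid = f"r{stage}" if copies[stage] == 1 else f"r{stage}_{k}"
            rev = copies[stage] == 1 and prod != "x_P" and rng.random() < 0.3
            model.add_reaction(Reaction(rid, {sub: -1, prod: 1},
                                        lb=-DEFAULT_UB if rev else 0.0))
            (essential if copies[stage] == 1 else non_essential).add(rid)
    return SyntheticNetwork(model=model, demand=demand_id,
                            essential=essential, non_essential=non_essential)
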