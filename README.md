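# chlorofba

Constraint-based analysis of chlorophyll-a biosynthesis in a compartmented
leaf cell (rice-style C3 metabolism), for plant systems biologists who want
to interrogate how inorganic nutrients and light are turned into chlorophyll
across the cytosol, chloroplast, mitochondrion and peroxisome — and in
particular how ammonia assimilation by the two glutamine synthetase
isoenzymes (cytosolic GS1, chloroplastic GS2) is coupled to tetrapyrrole
synthesis.

## The model and the analyses

A metabolic network is a stoichiometric matrix **S** (m internal metabolites
× n reactions).  At steady state every internal metabolite is balanced,

```
S v = 0,    LB ≤ v ≤ UB,
```

and the package solves the linear program

```
min Σ_j |v_j|   subject to   S v = 0,  bounds,  v_chl_tx = 1,
```

i.e. flux-minimization FBA ("economy of the enzymic machinery") with the
chlorophyll-a exporter pinned at 1 flux unit.  |v| is linearized exactly by
splitting reversible reactions into non-negative half-variables; the LP is
solved with scipy's HiGHS backend.  On top of that core the package provides

* **FVA** — per-reaction flux ranges under a relaxed budget
  Σ|v| ≤ k·Z\* (k = 1, 1.5, 2…), with a pinned/essential-bounded/variable
  classification;
* **essentiality scans** — single-reaction and GPR-aware gene deletions
  against the chlorophyll demand (essential ⇔ deletion makes the demand
  infeasible);
* **scenarios** — case 1 (Rubisco carboxylase only) and case 2
  (carboxylase:oxygenase coupled 3:1, i.e. photorespiring air), ammonia-
  importer scans, and the GS2/ammonia-diffusion experiment;
* **validation** — structural consistency, nitrogen-atom audits, and
  energy/redox leak tests (no ATP/NADPH/NADH from nothing when all
  exchanges are closed).

The curated reduced leaf model (108 reactions, 4 compartments, bundled as
`data/leaf.rxn` and constructible in code via `build_leaf_fixture()`)
encodes the tetrapyrrole branch (8 Glu and 1 SAM per chlorophyll; the PBG →
HMB step releases 4 NH3), GS/GOGAT, the cytosolic methyl cycle closed by
mitochondrial GDC/SHMT, the Calvin and C2 cycles, two lumped light
reactions, and the organellar shuttles (Mal-OAA, Mal-Glu, Mal-2OG, Glu-Gln,
SAM/AdoHcy).  Chlorophyll export (4 N/molecule) is the only nitrogen sink,
so every steady state imports exactly 4 NH3 per chlorophyll.

## Worked example

Scan the chloroplastic ammonia importer from 0 to 4 under case 1:

```
$ chlorofba scan src/chlorofba/data/leaf.rxn --case case1 --grid 0:4:1 --out out
$ cut -f1-8 out/scan.tsv
chl_importer  NH_3__tx  ex_ammonia_tx  cyt_GS1   chl_GS2   Glu_Gln_chl_tx  Mal_2OG_chl_tx  chl_GOGAT
0.000000      4.000000  0.000000       4.000000  4.500000  4.000000        8.500000        8.500000
1.000000      3.000000  1.000000       3.000000  5.500000  3.000000        8.500000        8.500000
2.000000      2.000000  2.000000       2.000000  6.500000  2.000000        8.500000        8.500000
3.000000      1.000000  3.000000       1.000000  7.500000  1.000000        8.500000        8.500000
4.000000      0.000000  4.000000       0.000000  8.500000  0.000000        8.500000        8.500000
```

Reading the table: the two importers always sum to 4 (the nitrogen content
of one chlorophyll); GS1 tracks the cytosolic importer and the Glu-Gln
shuttle tracks GS1; GS2 rises unit-for-unit with the chloroplastic importer
from its floor of 4.5 (4 NH3 released ring-side by HMB synthase + 0.5
shipped in from mitochondrial glycine decarboxylase); GOGAT and the Mal-2OG
shuttle are pinned at 8.5 at every grid point.

The GS2 experiment with chloroplast→cytosol ammonia diffusion closed:

```
$ chlorofba gs2 src/chlorofba/data/leaf.rxn --diffusion off --out out
$ head -7 out/gs2.json
{
  "case": "case1",
  "chloroplastic_ammonia_refixed": 4.5,
  "diffusion": "off",
  "gs2_essential": true,
  "gs2_flux": 8.5,
  "mito_ammonia_to_chloroplast": 0.5,
```

With `--diffusion on` GS2 becomes dispensable (`"gs2_essential": false`):
the chloroplastic ammonia can escape to the cytosol and be refixed by GS1 —
the modelling counterpart of GS2 mutants growing normally only when
photorespiratory ammonia production is low.

Other entry points: `chlorofba fba|fva|essential|compare-cases|validate|synth`,
or the library functions (`minimize_total_flux`, `run_fva`,
`reaction_deletion_scan`, `run_ammonia_scan`, …).

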