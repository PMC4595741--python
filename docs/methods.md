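# Methods

## The steady-state model

The analysis treats a leaf cell as a compartmented stoichiometric network at
steady state: for every internal metabolite, production equals consumption
(`S v = 0`), fluxes respect bounds, and the cell meets a fixed demand of one
flux unit of exported chlorophyll a.  Among all feasible steady states the
package selects the one minimizing total absolute flux, `Σ_j |v_j|`, a
parsimony objective that stands in for the cost of maintaining enzymatic
machinery.  All reactions — enzymatic steps, transporters, exchanges, the
photon importer — carry uniform weight 1; no weighting scheme is assumed.

The absolute value is linearized exactly: every reversible reaction is split
into two non-negative half-variables (`v = v⁺ − v⁻`) and the objective sums
all half-variables.  At an optimum the objective itself excludes
simultaneous `v⁺`/`v⁻` activity, so no integer constraints are needed.
Fixed fluxes tighten both bounds; blocked reactions intersect the bounds
with `v = 0` (so deleting a reaction that also carries a nonzero fixed
demand is correctly reported infeasible); ratio couplings such as
carboxylase:oxygenase = 3 enter as extra equality rows `v_a − r·v_b = 0`.
LPs are solved with scipy's HiGHS interface, single-threaded, with variable
order fixed by model insertion order, so runs are deterministic.

Numerical conventions: mass-balance tolerance 1e-6 (residual `|S v|` any
accepted solution must meet), support tolerance 1e-9 (a flux below it counts
as zero), FVA ties within 1e-6 are classified as equal.  Default bounds in
the text format are [0, 1000] / [−1000, 1000]; the fixture's photon importer
and the two lumped light reactions carry explicit bounds of 10000 because
photon flux runs an order of magnitude above metabolic fluxes and would
otherwise saturate the conventional "unbounded" value under photorespiration.

## Flux variability, essentiality

FVA first computes the optimal total flux Z\*, then minimizes and maximizes
each reaction's net flux subject to the same constraints plus the budget
`Σ|v| ≤ relaxation × Z*`.  The budget is an inequality; at relaxation 1.0 it
pins solutions onto the optimal face, which for the bundled leaf model is a
single vertex (every reaction's range collapses to its FBA value).
Reactions whose flux cannot reach zero within the relaxed budget are flagged
variability-implied essential; the suite checks that this set is contained
in the deletion-essential set.

A reaction is deletion-essential when forcing it to zero makes the
chlorophyll demand infeasible — strict infeasibility, not a reduced
optimum, because a fixed demand has no growth-rate scale on which a
partial-impairment threshold would be meaningful.  Reversible reactions are
deleted whole (both directions).  Gene deletions evaluate every
gene-association expression (AND/OR trees) with the knocked-out gene false
and block all closed reactions simultaneously; genes absent from every
expression are reported `no-data`, never essential.  The default deletion
scope is the active pathway of the scenario's optimum, with an option to
scan everything.

## The reduced leaf model

`build_leaf_fixture()` encodes, from the pathway literature, the smallest
network on which the coupled nitrogen/one-carbon bookkeeping of chlorophyll
synthesis is well posed.  Design choices that matter:

* **Tetrapyrrole branch.**  The three-step tRNA-dependent activation of
  glutamate is lumped into one Glu → ALA reaction (ATP- and
  NADPH-consuming); intermediates between ALA and chlorophyllide follow the
  canonical steps (ALA dehydratase 2:1, HMB synthase 4 PBG → HMB + 4 NH3,
  decarboxylations at UROD/CPO, SAM-dependent methylation at CHLM).  Eight
  glutamates and one SAM are consumed per chlorophyll; four of the eight
  nitrogen atoms return as chloroplastic ammonia at the HMB-synthase step.
  Nitrogen atom counts per species ship with the model (ALA 1, PBG 2,
  HMB → chlorophyll 4) and a per-reaction audit verifies closure; carrier
  moieties (adenine nucleotides, NAD(P), folates, adenosine) are booked
  nitrogen-free so conserved pools stay out of the audit.
* **Nitrogen assimilation.**  GS1 (cytosol) and GS2 (chloroplast), one
  NADPH-dependent chloroplastic GOGAT as the sole glutamate source, the
  Glu-Gln antiporter delivering cytosolic glutamine to GOGAT, and two
  ammonia importers (into cytosol and into chloroplast).  A
  chloroplast→cytosol ammonia diffusion step exists in the model but is
  bounded to zero; diffusion scenarios widen that bound instead of editing
  the network.
* **One-carbon supply.**  The methyl cycle (SHMT, MTHFR, methionine
  synthase, SAM synthetase, AdoHcy hydrolase, adenosine salvage plus
  adenylate kinase) turns once per chlorophyll.  Its glycine by-product can
  only be disposed of through mitochondrial GDC/SHMT, which forces the
  0.5-unit GDC/SHMT flux and the 0.5-unit mitochondrial ammonia export to
  the chloroplast; serine is topped up through the cytosolic phosphoserine
  route.
* **Carbon backbone.**  Calvin cycle with standard stoichiometries and
  separable Rubisco carboxylase/oxygenase; lower glycolysis, PEP carboxylase
  and NADP-malate dehydrogenase in the chloroplast; citrate synthesis in the
  cytosol with mitochondrial aconitase/ICDH regenerating 2-oxoglutarate for
  the Mal-2OG shuttle.  The Mal-OAA antiporter is reversible (its direction
  is an outcome, not an input; at the case-1 optimum it exports OAA to the
  cytosol).  Surplus cytosolic NADH is oxidized by the mitochondrial
  external dehydrogenase/alternative path (no ATP), and a mitochondrial
  alternative oxidase uncouples ICDH/GDC redox from ATP demand (P/O of the
  coupled chain: 2.5).
* **Photorespiration.**  Phosphoglycolate phosphatase and glycerate kinase
  in the chloroplast; glycolate oxidase, catalase, a combined
  serine:glyoxylate aminotransferase + hydroxypyruvate reductase, a
  glutamate:glyoxylate aminotransferase and malate dehydrogenase in the
  peroxisome.  The Glu:glyoxylate aminotransferase is required: with serine
  as the only amino donor the second glyoxylate of each C2 turn cannot be
  aminated and the photorespiring case is structurally infeasible.
* **Light.**  Two lumped reactions: non-cyclic photophosphorylation at
  8 photons : 2 NADPH : 2 ATP : 1 O2 and cyclic at 2 photons : 1 ATP.  The
  1:1 ATP:NADPH ratio of the non-cyclic reaction is deliberate — the
  chloroplast's ATP:NADPH demand exceeds 1 in both cases, so the cyclic
  reaction tops up ATP and both light reactions can be active without an
  artificial ATP drain.  Photon totals depend directly on these lumped
  ratios, so the suite asserts only the ordering (photorespiration costs
  strictly more light), never absolute photon numbers.

With these choices the printed flux values of the analysis are not tuned
constants but stoichiometric necessities: any feasible steady state imports
exactly 4 NH3 per chlorophyll (the only nitrogen sink), runs GOGAT and the
Mal-2OG shuttle at 8.5, GDC/SHMT at 0.5, and GS2 at 4.5 + a where a is the
chloroplastic importer flux.  The flux-minimal optimum of case 1 is unique
(FVA at relaxation 1.0 pins all 108 reactions), which makes the reported
values stable across solvers and orderings.

## Scenarios

Case 1 blocks the oxygenase; case 2 couples Vc/Vo = 3:1.  Both fix
chlorophyll export at 1.  The ammonia scan fixes the chloroplastic importer
at 0…4 and leaves the cytosolic importer free (nitrogen closure forces the
complement).  The GS2 experiment reports the GS2 flux, the chloroplastic
ammonia it refixes (ring release + mitochondrial import: 4.5 in case 1,
larger under photorespiration) and whether GS2 deletion leaves the demand
feasible.  On this reduced network the strict flux minimum keeps GS2 active
even when diffusion is open (diffusing and refixing through GS1 costs two
extra steps per NH3); the biological statement "GS2 can be inactive when
ammonia may diffuse" is therefore expressed as GS2 deletion feasibility
rather than as the flux value of one particular optimum.  Likewise the
free-choice optimum prefers the chloroplastic importer in both cases here
(2 steps per N versus 3 through GS1 and the antiport); in a genome-scale
network the photorespiring case can shift that preference, which a model of
this size cannot resolve — the suite asserts only that the all-cytosolic
route stays feasible.

## The synthetic generator and what passing tests show

`generate_synthetic_network` builds layered source→demand chains whose
essential set is known by construction: widened stages (parallel duplicate
reactions) are redundant, single-copy stages essential, and a seeded subset
of single-copy stages is reversible.  Deletion scans and FVA on these
networks are compared against orthant-enumeration brute-force oracles that
share no code with the production LP.  These networks (and the reduced leaf
model) exercise the solver logic exhaustively, but they are small, exactly
balanced and noise-free; passing them shows the algorithms are correct, not
that a genome-scale reconstruction of a real leaf would reproduce the same
flux values — the reduced model deliberately contains exactly one route for
most functions, whereas genome-scale networks are highly redundant.

## Known limitations

* Proton and charge balance are not enforced, matching the granularity of
  the source network; water is included where the pathway literature names
  it.
* Lumped light, MEP and Glu→ALA stoichiometries make absolute photon
  totals model choices; only orderings are meaningful.
* The chlorophyll-b cycle, chlorophyll degradation and reactive-oxygen
  effects are out of scope.
* Gene associations cover a representative subset of reactions (isoenzyme
  pairs, AND-complexes) sufficient for the GPR machinery, not a complete
  gene catalogue.
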