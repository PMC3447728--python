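# Methods

## Scope and layering

The package is organised as a pipeline of five layers: domain types and
structural checks (`model`), drafting from pathway data (`kegg`, with
`fixtures` as the offline data source), curation (`reconstruction`),
analysis (`fba`, `dfba`), and interchange (`sbml`, `svg`, `cli`). Every
analysis operates on the same in-memory `MetabolicModel`; SBML is the
exchange format, a plain JSON document the internal one.

## The constraint-based model

A reaction stores one signed stoichiometry map (negative = consumed,
positive = produced) together with flux bounds in mmol/g DCW/h.
Reversibility is encoded redundantly in the bounds: irreversible implies
`lower_bound >= 0`; a reversible reaction defaults to ±M with
M = 1000 mmol/g DCW/h, a conventional "effectively unbounded" cap
(configurable per reaction). External (boundary) species are explicit
`external=True` metabolites rather than implicit sinks, so SBML export
can mark `boundaryCondition`; their rows are omitted from **S**, which
is what makes inflow/outflow reactions net sources and sinks. Rows and
columns of **S** are ordered lexicographically, so matrix construction,
SBML export and SVG rendering are deterministic and diffable.

Structural checks:

- **Dead ends** — internal metabolites that are only produced or only
  consumed, with a reversible reaction counting as both producer and
  consumer of all its participants. These flag network gaps for manual
  curation; no automated gap-filling is attempted (deliberately out of
  scope).
- **Mass balance** — per-element deltas Σᵢ (coefficient × element
  count). Formulas outside the plain grammar (repeat units like
  `(C5H8O4)n`, residue markers like `R`) make the reaction "unchecked"
  rather than guessed at; element symbols are validated against the
  periodic table. Charge balance and compartments are out of scope.

## Drafting rules

Pathway maps (KGML) determine *which* reactions an organism carries and
their direction; the reaction table (LIGAND-style equations over
C-number compound ids) is the stoichiometry authority, because KGML
substrate/product lists omit coefficients and cofactors. Decisions that
the inputs leave open are resolved as follows, and each is surfaced in
the draft report rather than silent:

- a reaction listed in several maps is included once; a reversibility
  conflict across maps resolves to reversible (least restrictive — a
  curator can tighten it later);
- a KGML orientation that is flipped relative to the equation keeps the
  equation's orientation, with a logged warning;
- equations with non-numeric coefficients (`n`, `(n+1)`) or glycan
  terms are excluded and reported — a reported gap is recoverable, a
  silently wrong stoichiometry is not;
- duplicate table records keep the first occurrence.

## The synthetic organism generator

`generate_fixture_organism` stands in for a live pathway database so
every test runs offline. It emits syntactically valid KGML and a
LIGAND-style flat table for a network with fully known structure: an
irreversible backbone chain from a designated substrate to a designated
product (guaranteeing that flux analysis is feasible once exchanges are
added), closed cycles (every cycle compound has a producer and a
consumer), bridge reactions between covered compounds with coefficients
in {1, 2}, and `n_orphans` deliberately dead-ended metabolites. The
generator records the ground-truth model, the overlap set, the corrupted
records and the exact dead-end set, so parsing + assembly can be checked
for *equality*, not plausibility. Geometry defaults (4 pathways, 60
reaction placements, 8 of them duplicates, no corruption) give a 52-
reaction draft. What the generator does **not** emulate: realistic
element compositions, cofactor usage patterns, or KGML gene/ortholog
entries — drafting tests therefore establish parser/assembler
correctness, not biological realism.

## Reconstruction semantics

All operations are pure: they validate against the input model and
return an edited deep copy, which makes YAML edit scripts atomic for
free (the first invalid directive aborts with its position; the input
model is untouched). Specific choices:

- **Inflow** targets any internal metabolite directly (a lumped
  transport-plus-activation step); `fixed=v` pins lb = ub = v, the
  standard way to impose a measured rate.
- **Knockout** zeroes bounds but keeps the reaction, preserving
  reporting and reversibility of the edit.
- **Biomass** consumes building-block demands (mmol/g DCW) plus
  GAM ATP + GAM H₂O → GAM ADP + GAM Pi, and produces one unit of a
  synthetic biomass species drained by a paired sink; biomass flux is
  then the specific growth rate in 1/h. Demands are user-supplied.
- **Maintenance** (NGAM) is ATP + H₂O → ADP + Pi with lb = ub = NGAM.
- **Direction edits** store coefficients so they always read
  left-to-right forward: setting "backward" negates the stoichiometry
  and makes the reaction irreversible.

## Flux analysis numerics

The LP is solved with scipy's HiGHS (`linprog`); every problem the
package formulates is linear, so no NLP machinery is used. Reported
optima are checked against |**S**·v| ≤ 1e−6 per metabolite before being
returned. FBA optima are unique in objective value but not in the flux
vector; all higher-level analyses therefore compare objective values or
run a secondary optimization at a fixed primary optimum (fix biomass,
maximize the product), never raw witness vectors.

- `fit_gam` exploits that growth is monotone non-increasing in GAM
  (every extra mmol ATP/g DCW competes with growth for the same capped
  ATP supply): bisection on a default bracket [0, 1000] mmol ATP/g DCW,
  ≤ 60 iterations, to a default growth tolerance of 1e−4 h⁻¹, with the
  substrate uptake fixed beforehand. A sampled (GAM, growth) curve is
  returned for plotting.
- `production_envelope` computes the maximal growth μ\*, then maximizes
  the target flux on a uniform μ-grid over [0, μ\*]; the resulting
  curve is concave (LP feasible sets shrink affinely in μ), which the
  tests verify by a midpoint check.
- `constrain_and_resolve` applies temporary bounds to a copy, so
  scenario analysis leaves the model bit-identical.

The independent cross-check for all of this is COBRApy + GLPK (via
optlang) rebuilt from the same model — a different formulation and
solver path — used in the tests and the acceptance script only.

## Dynamic FBA (static optimization approach)

The time course is split into fixed steps dt; each interval solves an
ordinary FBA with bounds resolved at its left edge. Piecewise-constant
profiles are left-closed step functions (a value holds from its
breakpoint until the next). Monod profiles set ub = vmax·S/(Ks+S) from
the current tracked concentration, lb = 0. Between intervals, biomass
updates exponentially, X ← X·e^{μ dt} (exact for constant μ, hence the
closed-form test is exact at grid points), and each tracked substrate
updates by S ← max(0, S − v·X̄·dt) with X̄ the exact interval-average
biomass (X_{k+1} − X_k)/(μ dt) for μ > 0. Clamping at zero plus
per-interval bound recomputation prevents negative concentrations. An
infeasible interval terminates the run gracefully with a partial
trajectory — late-time infeasibility (maintenance can no longer be
covered) is a meaningful endpoint, not an error. The integrator is
first-order in dt against a continuous-kinetics reference; at dt = 0.01 h
the Monod test problem stays within 1% of an independent high-accuracy
ODE integration over 10 h.

Units are chosen so dS/dt = −v·X is dimensionally consistent: biomass
g DCW/L, substrates mmol/L, fluxes mmol/g DCW/h.

## SBML and SVG

Export is SBML Level 3 Version 1 with the FBC v2 package (non-strict):
bounds as shared constant parameters, the objective as an FBC objective,
reaction category and optional solved fluxes in XHTML notes. Ids that
are not valid SBML SIds are sanitized reversibly — the original id is
embedded in the entity notes, so read(write(m)) restores ids exactly.
The reader accepts both that dialect and the legacy Level 2 encoding of
2012-era constraint-based models, searching bounds in FBC attributes,
then kinetic-law parameters named `LOWER_BOUND`/`UPPER_BOUND` (with
`OBJECTIVE_COEFFICIENT` for the objective), then notes, and falling back
to reversibility-based defaults with a warning. Exported documents pass
libsbml consistency checking with zero errors.

SVG rendering is a bipartite drawing (metabolite circles, reaction
squares) laid out by a seed-deterministic force-directed embedding;
coordinates are rounded to two decimals so identical inputs give
byte-identical documents. Edge width scales with |flux|, zero-flux edges
are dashed. Models above 2000 nodes drop labels.

## The demonstration model

The TOY model (`fluxdraft.toy`) is a synthetic 10-metabolite central
metabolism: glycolysis, oxidative + non-oxidative pentose phosphate
pathway (3 P5P ↔ 2 F6P + GAP), a lumped TCA route, anaplerosis and a
lumped biomass sink with conventional bacterial precursor demands.
Decarboxylations are implicit (CO₂ is untracked), which is what lets
carbon in excess of acetate + biomass leave the system. Its purpose is a
transparent end-to-end surface: with glucose fixed at 11.0 and acetate
at 6.4 mmol/g DCW/h the maximum growth rate is ≈1.06 h⁻¹, and the same
LP optimum must be reproduced by the independent oracle to 1e−6
relative.

## The medium-scale surrogate

`fluxdraft.surrogate` packages an X514-like anaerobic ethanologen built
in code (no external files): 196 species, 229 reactions — 161
intracellular conversions + 1 maintenance, 19 inflow/outflow, 39
gap-filling exchanges, 9 biomass-related (7 building-block syntheses,
biomass production, biomass sink). Design choices:

- **Energetics.** Glycolysis nets 2 ATP + 2 NADH per glucose; pyruvate:
  ferredoxin oxidoreductase feeds electrons to ferredoxin; acetate
  kinase yields 1 ATP per acetate; ethanol costs 2 NADH; an
  NADH-dependent hydrogenase and a ferredoxin:NAD⁺ oxidoreductase give
  redox flexibility; a lumped membrane energy-converting hydrogenase
  couples ferredoxin reoxidation to H₂ with 0.233 ATP per ferredoxin (a
  chemiosmotic, hence non-integer, H⁺/ATP ratio). This coupling value
  was chosen once, at design time, so that the model's ATP yield
  reproduces the high maintenance-energy phenotype of this organism
  class under its reference chemostat condition (glucose 3.92 mmol/g
  DCW/h, NGAM 7.6 mmol ATP/g DCW/h, growth 0.042 h⁻¹ ⇒ fitted GAM
  ≈ 220 mmol ATP/g DCW).
- **Gap filling** follows the metabolite-exchange principle: 39
  metabolites shared with out-of-scope pathways (UTP, other nucleotides,
  cofactor pools) get reversible exchange reactions; at any optimum they
  carry zero flux but they keep the network free of dead ends.
- **Peripheral padding.** 21 linear chains duplicate energy-neutral
  core conversions, standing in for peripheral pathway content; they
  create alternate optima in flux space but cannot change any objective
  value. A mineral phosphate inflow balances the phosphate exported
  inside phosphorylated biomass precursors.
- **Gold file.** All reference numbers for this model (max growth,
  fitted GAM, envelope points, acetate-restriction gain) live in
  `src/fluxdraft/data/x514_surrogate_gold.json`, regenerated from the
  model by `scripts/regenerate_gold.py` — documented, reproducible
  outputs of the package itself, not hand-entered values.

At the ATP-limited optimum all acetyl-CoA goes to acetate, so ethanol
appears only when growth is given up — the envelope falls from
7.6 mmol/g DCW/h at zero growth to zero at μ\*; restricting acetate
secretion from 2.0 to 0.6 mmol/g DCW/h raises ethanol at the respective
optimal growth by ≈26%.

## Problem sizes in the test suite

The suite runs on one CPU in well under a minute: random drafting
networks use 30 reaction placements, monotonicity properties check 100
edits across 50 random networks, drafting and SBML round trips cover 20
and 8 seeds respectively, and the dynamic-FBA oracle comparison
integrates 1000 intervals at dt = 0.01 h. These sizes were chosen to
exercise every code path with margin, while the surrogate (229
reactions) covers the medium-scale regime.

## Known limitations

- No flux variability analysis, ¹³C-MFA, thermodynamic direction
  prediction, gene–protein–reaction associations, compartments, charge
  balance, or automated gap-finding — all deliberately out of scope.
- Mass-balance checking refuses polymeric formulas rather than
  approximating them.
- The drafting layer trusts the reaction table's orientation; organisms
  with systematically flipped annotations would need manual direction
  edits.
- Dynamic FBA is the fixed-step static optimization approach only; no
  stiffness control and no simultaneous (collocation) formulation.
- The surrogate is a designed artifact: it reproduces the *workflows*
  and the qualitative physiology of a real medium-scale draft, not any
  organism's measured flux map.
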