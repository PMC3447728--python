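# fluxdraft

Draft constraint-based metabolic models from KEGG-style pathway data and
analyse them with flux balance analysis (FBA) and dynamic FBA — entirely
offline, as a Python library plus a small CLI.

## Who this is for

Microbial physiologists and systems biologists who want to go from a
genome-annotation-level description of an organism (pathway maps plus a
reaction database) to a working stoichiometric model, impose measured
exchange rates, and predict growth and product formation — without a
commercial modelling stack. The package covers the whole loop:

1. **Drafting** — parse KGML pathway documents and LIGAND-style reaction
   tables (`ENTRY`/`NAME`/`EQUATION` flat files or a 3-column TSV),
   cross-reference them, and assemble an organism-specific seed model
   (`fluxdraft.kegg`). Reactions with polymeric or glycan equations are
   excluded and reported, never silently approximated.
2. **Reconstruction** — add inflow/outflow exchanges, a biomass reaction
   with growth-associated maintenance (GAM), a non-growth-associated
   maintenance (NGAM) reaction, heterologous or gap-fill reactions;
   knock reactions out; retune directions and participants; batch all of
   it in atomic YAML edit scripts (`fluxdraft.reconstruction`).
3. **Analysis** — steady-state FBA with arbitrary linear objectives,
   GAM fitting against a measured growth rate, growth-vs-product
   trade-off curves, scenario analysis under temporary bounds
   (`fluxdraft.fba`), and dynamic FBA by the static optimization
   approach with piecewise-constant or Monod-kinetic exchange bounds
   (`fluxdraft.dfba`).
4. **Interchange** — SBML Level 3 + FBC export, readers for both L3-FBC
   and legacy Level 2 kinetic-law-parameter encodings, and SVG network
   rendering with flux-weighted edges (`fluxdraft.sbml`,
   `fluxdraft.svg`).

## The model at the core

FBA treats metabolism at steady state: with stoichiometric matrix **S**
(rows = internal metabolites, columns = reactions) and flux vector *v*,

maximize  *c·v*  subject to  **S** *v* = 0,  *lb* ≤ *v* ≤ *ub*

which is a linear program (solved here with scipy's HiGHS backend).
Exchange reactions are unbalanced sources/sinks whose fluxes are uptake
and secretion rates (mmol/g DCW/h); the biomass pseudo-reaction consumes
building blocks in measured proportions (mmol/g DCW) plus GAM ATP, so
its flux is the specific growth rate μ (1/h); NGAM is a pinned ATP
hydrolysis flux. Dynamic FBA splits a fermentation time course into
intervals, solves one "mini-FBA" per interval with time-dependent
bounds, and integrates biomass (X ← X·e^{μΔt}) and tracked substrate
pools between intervals.

## Worked example

The packaged demonstration model (`fluxdraft.toy`) covers glycolysis,
the pentose phosphate pathway, a lumped TCA route and the anaplerotic
node: 10 metabolites, 16 reactions after reconstruction. Glucose uptake
is fixed at 11.0 and acetate secretion at 6.4 mmol/g DCW/h, and biomass
is maximized:

```python
from fluxdraft import solve_fba
from fluxdraft.toy import reconstruct_toy

model = reconstruct_toy()          # glucose 11.0, acetate 6.4 mmol/g DCW/h
solution = solve_fba(model)
print(f"growth rate: {solution.objective_value:.5f} 1/h")
print(f"glucose in : {solution.fluxes['glc_in']:.2f} mmol/g DCW/h")
print(f"acetate out: {solution.fluxes['ac_out']:.2f} mmol/g DCW/h")
```

prints

```
growth rate: 1.05988 1/h
glucose in : 11.00 mmol/g DCW/h
acetate out: 6.40 mmol/g DCW/h
```

i.e. under those fixed exchange rates the network can support a specific
growth rate of about 1.06 h⁻¹, with all remaining carbon leaving through
the lumped decarboxylation steps.

The packaged medium-scale surrogate (`fluxdraft.surrogate`, 196 species
/ 229 reactions, an anaerobic glucose-to-ethanol fermenter) shows the
maintenance-energy workflow. With glucose uptake 3.92 mmol/g DCW/h and
NGAM 7.6 mmol ATP/g DCW/h, fitting GAM to a measured growth rate of
0.042 h⁻¹:

```python
from fluxdraft import fit_gam
from fluxdraft.surrogate import build_x514_surrogate

fit = fit_gam(build_x514_surrogate(), target_growth=0.042)
print(f"fitted GAM: {fit.gam:.1f} mmol ATP/g DCW (growth {fit.growth:.4f} 1/h)")
```

prints

```
fitted GAM: 219.7 mmol ATP/g DCW (growth 0.0421 1/h)
```

The same model predicts a strict ethanol/growth trade-off
(`production_envelope`) and quantifies how restricting acetate secretion
from 2.0 to 0.6 mmol/g DCW/h raises ethanol production at optimal
growth by ~26% (`constrain_and_resolve`).

## CLI

```
fluxdraft fixture --seed 1 --out-dir org/          # synthetic organism
fluxdraft draft --kgml-dir org/ --reaction-table org/reactions.txt \
                --organism syn --out draft.xml
fluxdraft edit draft.xml --script edits.yaml --out model.xml
fluxdraft fba model.xml --out fluxes.tsv
fluxdraft envelope model.xml --target etoh_out --points 20
fluxdraft fitgam model.xml --target-growth 0.042 --uptake glc_in=3.92
fluxdraft dfba model.xml --monod glc_in:10:1 --track glc=20 --dt 0.01 --t-end 10
fluxdraft render model.xml --out network.svg
```

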