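# diazofba

Constraint-based modelling of **diazotrophic, heterocyst-forming
cyanobacteria** as a two-cell system, for metabolic modellers and strain
designers working with *Anabaena*-type filaments.

In a nitrogen-fixing filament the photosynthetic vegetative cells and the
micro-oxic, N₂-fixing heterocysts divide labour: the vegetative cell fixes
CO₂ and exports sucrose and glutamate; the heterocyst burns the sucrose,
runs nitrogenase (16 ATP + 8 e⁻ ≈ 4 NAD(P)H per N₂, a 4:1 ATP:NAD(P)H
demand), and returns glutamine and 2-oxoglutarate.  `diazofba` builds
genome-scale (or reduced) models of this system as a single flux space

&nbsp;&nbsp;&nbsp;&nbsp;S·v = 0, lb ≤ v ≤ ub

with two super-compartments (`__vc` / `__hc` id suffixes), and provides:

* **network_core / io** — typed metabolite/reaction/model structures,
  mass- and charge-balance checking, per-cell content summaries, and readers
  and writers for SBML L3+fbc (via cobrapy/libsbml), a tabular TSV dialect
  and a JSON dump;
* **two-cell builder** — duplicate a single-cell template into the
  two-compartment model (heterocyst loses PSII, RuBisCo and GOGAT; the
  vegetative cell loses nitrogenase), add the four inter-cell exchanges, and
  apply the diazotrophic culture constraints (inorganic carbon ≤ 8.5
  mmol/gDW/h, photons ≤ 100 per photosystem, N₂ ≤ 10, heterocyst O₂ ≤
  0.7 × 9 % = 0.063, heterocyst biomass floor 0.1 × 0.1824 h⁻¹, and the
  glutamate→glutamine flux coupling);
* **solver** — FBA, parsimonious FBA and FVA as linear programs on
  scipy/HiGHS, plus derived queries (minimum uptake for a growth target,
  metabolite turnover, loop reporting);
* **heterocyst energetics** — the energy-scheme scenarios (no light;
  OPPP + cyclic PSI; glycolysis + TCA + cyclic PSI with complete or
  incomplete oxidation) and their growth/sucrose/CO₂ metrics;
* **optforce** — OptForce strain design: wild-type vs overproduction flux
  spaces, single and pairwise MUST sets with the published filtering rules,
  and the bi-level FORCE-set search collapsed to a single MILP by LP duality,
  with integer-cut enumeration of alternative strategies;
* **toy fixtures** — a deterministic ~59-reaction synthetic two-cell network
  with the canonical filament topology, elementally balanced and with
  hand-derivable optima, plus synthetic MFA ranges and two lactam production
  pathways (valerolactam via 5-aminovalerate, caprolactam via adipyl-CoA).

## Worked example

```python
from diazofba import fba, fva, make_toy_two_cell

model, manifest = make_toy_two_cell()
print(fba(model).objective_value)          # 0.27486 1/h
ranges = fva(model, fixed={"biomass__vc": (0.1824, 0.1824)},
             targets=["nitrogenase__hc", "glu_vc_hc_exch"])
print(ranges.minimum("nitrogenase__hc"))   # 0.10032 mmol/gDW/h
print(ranges.minimum("glu_vc_hc_exch"))    # 0.18240 mmol/gDW/h
```

The maximum growth rate, 0.27486 h⁻¹, is exactly the carbon-limited value
8.5/29 − 0.01824 (biomass holds 29 mmol C/gDW; the heterocyst turnover floor
consumes the rest).  With growth pinned to the experimental 0.1824 h⁻¹, the
minimum nitrogenase flux is half the biomass nitrogen demand (2 NH₃ per N₂)
and the glutamate/glutamine shuttle must carry one glutamate per unit
growth.  `examples/` contains four narrative scripts (two-cell FBA, the
energy-scheme table, OptForce design, model I/O); running
`examples/02_heterocyst_energy_schemes.py` prints the scheme table whose
incomplete-oxidation variant needs 3× the sucrose and evolves ½ the CO₂ of
the pentose-phosphate scheme, and `examples/03_optforce_strain_design.py`
finds the single intervention (upregulated lysine biosynthesis) that
guarantees 1.187 mmol/gDW/h of secreted valerolactam — 90 % of the
theoretical yield — in the worst case.

A thin CLI mirrors the workflow: `diazofba make-toy | simulate | scenarios |
optforce | build-two-cell` (see `--help`).

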