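# Methods

## The two-cell flux model

A heterocystous filament is modelled as one steady-state flux space
`S·v = 0, lb ≤ v ≤ ub` spanning two super-compartments.  Every template
reaction is duplicated with `__vc` (vegetative) and `__hc` (heterocyst)
suffixes — the id dialect of ModelSEED-style reconstructions, in which cell
membership is a suffix on the template id — except for the cell-specific
deletions: the heterocyst copy lacks photosystem II, RuBisCo and GOGAT, the
vegetative copy lacks nitrogenase.  Four non-facilitated inter-cell
exchanges connect the compartments: sucrose and glutamate flow to the
heterocyst, glutamine and 2-oxoglutarate flow back.  Both compartments carry
the same biomass equation; only the vegetative biomass is the FBA objective
(only vegetative cells divide), while the heterocyst biomass keeps a lower
bound as a macromolecule-turnover proxy.

Uptakes follow the positive-flux convention: every uptake is a dedicated
forward reaction whose physiological limit is a plain upper bound, and every
secretion is a separate forward reaction.  This makes each culture bound a
single number on a single reaction.

### Diazotrophic constraint set

| constraint | value | note |
|---|---|---|
| inorganic carbon uptake ub | 8.5 mmol/gDW/h | minimum uptake supporting the measured growth rate; carbon-limited conditions |
| photon uptake ub | 100 mmol/gDW/h per photosystem | restricts futile light-driven cycles without limiting biomass yield |
| N₂ uptake ub | 10 mmol/gDW/h | non-limiting; caps the fixation/ammonia-secretion cycle |
| heterocyst O₂ uptake ub | 0.7 × 0.09 = 0.063 mmol/gDW/h | culture-level uptake apportioned by the heterocyst fraction of cells |
| heterocyst biomass lb | 0.1 × 0.1824 h⁻¹ | turnover floor |
| growth rate | 0.1824 h⁻¹ = ln 2 / 3.8 h | measured doubling time |
| glu/gln coupling | flux(glu vc→hc) = flux(gln hc→vc) | all transferred glutamate returns as glutamine, so the heterocyst cannot eat glutamate as carbon |

The heterocyst fraction defaults to 0.09 (observed range 8–9 %); the config
exposes it.  "CO₂" and "bicarbonate" uptake are one inorganic-carbon bound.
The glu/gln coupling is implemented as a **pseudo-metabolite balance row**
(produced by the glutamate exchange, consumed by the glutamine exchange), so
the model stays a pure `S·v = 0` LP with no solver-specific side
constraints.  Whether the coupling should be an equality or only directional
is an open modelling question; the equality is implemented and flagged here.

Biomass coefficients come from macromolecule mass fractions rescaled to 1
g/gDW (enforced to 1e-9): coefficient (mmol/gDW) = rescaled fraction /
precursor molar mass (g/mmol), plus a growth-associated ATP maintenance
term.

## Linear programming

All LPs run on scipy's HiGHS backend with dual-simplex determinism; repeated
runs are bit-identical.  Feasibility tolerance 1e-9; reported values are
meaningful to about 1e-6.  FVA first maximises the objective, then pins the
objective reaction to (1 − 1e-9) × optimum as an *equality* before scanning
per-reaction minima/maxima — the offset dodges degenerate-optimum chatter.
pFBA fixes the objective the same way and minimises Σ|v| by splitting each
flux into non-negative forward/reverse parts (the absolute-flux norm; the
irreversible-split norm coincides for this formulation).  Thermodynamically
infeasible loops are controlled the way the culture constraints do it —
finite photon bounds — not by loopless-FVA; `report_loops` flags internal
cycles (e.g. the cost-free sucrose synthesis/hydrolysis pair in the toy)
without altering any result.

FBA/FVA/pFBA are deliberately implemented on the raw `S`/`lb`/`ub` arrays
rather than delegated to a COBRA stack, because the OptForce dualisation
below needs exactly those arrays; cobrapy (GLPK) then serves as an
*independent* cross-check in the test suite, and as the SBML L3+fbc
reader/writer behind the io module.

## Heterocyst energetics

Nitrogenase demands 16 ATP and 8 electrons (4 NAD(P)H) per N₂ — a 4:1
ATP:NAD(P)H ratio.  Scenarios probe which heterocyst routes can meet it,
each expressed as role-aliased bound edits (role names resolve through a
per-model alias table, so published reaction ids and toy ids share the same
scenario code):

* `LETC_minus` — heterocyst photon uptake 0;
* `OPPP_LETC` — G6P isomerase, phosphoketolase and GAPDH blocked, so G6P is
  oxidised only through the pentose-phosphate pathway;
* `GLY_TCA_LETC` — G6P dehydrogenase and phosphoketolase blocked; variants
  additionally cap the 2-oxoglutarate export (variant 1) or the heterocyst
  CO₂ evolution (variant 2) at the base variant's FVA minimum, forcing
  complete vs incomplete oxidation.

For this module the heterocyst turnover floor is lifted (no macromolecule
turnover assumed), leaving nitrogenase and glutamine synthetase as the only
heterocyst energy sinks; the 10 % floor applies everywhere else.  Metrics:
FBA maximum growth, then FVA minima of heterocyst sucrose uptake and CO₂
evolution with growth fixed at that maximum.  CO₂ evolution is measured on
the heterocyst CO₂ release reaction, not a net balance.  The ATP:NAD(P)H
turnover ratio of a pFBA solution counts NADH and NADPH jointly (the split
is not observable at this lumping level) via per-compartment metabolite
turnover, Σ max(0, coefficient × flux).

## OptForce strain design

Wild-type flux space: measured ¹³C-MFA flux ranges are imposed as bounds on
the covered (vegetative central-carbon) reactions and FVA propagates them to
the rest of the network, heterocyst included.  Overproduction space: product
secretion ≥ 90 % of theoretical yield and biomass ≥ 10 % of its maximum,
again characterised by FVA; the theoretical yield is computed with the
biomass lower bound at zero, the 10 % floor being a separate constraint.
Reactions whose ranges separate strictly (ε = 1e-6) form MUST^U / MUST^L /
MUST^X; pairwise sets compare the ranges of flux sums and differences, over
the metabolite-sharing pair universe by default (a full quadratic scan is
available by passing pairs explicitly).  Filtering follows the published
rules in order: boundary/transport/spontaneous/lumped kinds out of all sets;
linear pathways collapsed onto their first reaction (structural coupling:
a metabolite with a unique producer and unique consumer chains them);
growth-coupled reactions out of MUST^L; essential and very-low-flux
(< 1e-3 mmol/gDW/h, configurable) reactions out of MUST^X.

The FORCE-set search is the bi-level program *max over ≤ k interventions of
the worst-case product flux*, where the inner space is the MFA-constrained
wild type with each chosen intervention's bounds **replaced**: up-regulation
imposes the overproduction-space minimum as a lower bound (upper bound back
to the model's), down-regulation imposes the overproduction-space maximum as
an upper bound, knockout pins zero.  Replacing rather than intersecting is
deliberate: an up-regulated pathway that is silent in the wild type would
otherwise be infeasible by construction.  The program is collapsed to one
MILP by dualising the inner LP (dual variables for the balance rows and both
bound sides) and linearising every binary-times-dual product with a big-M
envelope (M = 1e4).  Because a too-small M could silently inflate the
objective, the guaranteed flux of the selected binaries is always
re-verified by solving the inner LP directly; infeasible selections are
excluded by an integer cut and the search continues.  Alternative FORCE sets
are enumerated with integer cuts; enumeration stops when the best remaining
strategy guarantees no more than the wild-type worst case.  The objective is
*maximise guaranteed product at budget k* (the alternative — minimise the
FORCE set at a fixed target — is not implemented).  Fold changes follow the
published convention: imposed lower bound / wild-type maximum for
up-regulation, wild-type minimum / imposed upper bound for down-regulation,
Δ for knockouts, with zero denominators reported as ∞.

## The synthetic two-cell network

The packaged generator emits a deterministic (RNG-free, bit-identical)
~59-reaction model with the canonical filament topology: vegetative linear
electron transport (8 photons → 4 Fd_red + 2 ATP, water-splitting
stoichiometry), cyclic PSI (2 photons/ATP), FNR (2 Fd_red ↔ NAD(P)H), a
lumped Calvin cycle (6 CO₂ + 12 NADPH + 18 ATP → hexose), sucrose synthesis
and shuttle; heterocyst OPPP (12 NAD(P)H/hexose), glycolysis (2 ATP + 2
NAD(P)H + 2 pyruvate), a two-lump TCA with a 2-oxoglutarate exit,
respiration capped by the 0.063 O₂ bound, nitrogenase (16 ATP + 8 Fd_red +
N₂ → 2 NH₃ + H₂), GS/GDH, and ethanol/H₂ vents.  Electron bookkeeping uses
explicit reduced-ferredoxin and NAD(P)H species so the 8 e⁻ ↔ 4 NAD(P)H
equivalence is a stoichiometric fact.  Redox state is carried as H atoms
(NADPH = NADP + 2H), energy-carrier formulas satisfy ATP = ADP + Pi exactly
(so ATP coefficients are free parameters), and the hexose pool lumps away
phosphate bookkeeping; every non-boundary reaction passes the element/charge
balance check.  Electron-carrier stoichiometries (12 NAD(P)H per hexose, 8
Fd_red per N₂) are fixed by mass balance and the generator refuses to change
them.

Inorganic carbon uses a shared external pool with a single culture-level
exchange (ub 8.5) plus per-cell uptake/release transports, so
heterocyst-evolved CO₂ can be re-fixed by the vegetative cell — without
recycling, the complete-oxidation schemes could not reach the default
optimum.  O₂, N₂ and photons have per-cell exchanges only (the heterocyst
envelope blocks O₂ sharing; light is absorbed per cell).

The manifest's reference optima are analytic where a closed form exists —
growth is carbon-limited at 8.5/29 − 0.01824 = 0.274863 h⁻¹ (29 mmol C per
gDW of biomass), the heterocyst NAD(P)H budget gives the scheme minima
(e.g. OPPP sucrose minimum = 2μ/24, the incomplete-oxidation variant 3×
that and half its CO₂) — and otherwise frozen from the release solve and
reproduced by the independent GLPK oracle in the test suite.  The emulated
MFA fixture takes ±10 % bands around the network's pFBA fluxes for a
measured subset of vegetative central-carbon reactions; as with a real
labelling study of a non-diazotrophic donor, nothing touching the sucrose
shuttle or the heterocyst is covered.

### What the toy does and does not show

The toy reproduces the *structure* of diazotrophic metabolism — division of
labour, the 4:1 energy demand, the scheme trade-offs, carbon-limited growth
— with hand-checkable numbers, so green tests certify the algorithms (I/O,
LP/MILP correctness, scenario and MUST/FORCE logic), not any genome-scale
prediction.  Its absolute fluxes, the ~1.45× growth drop without heterocyst
light, and its particular FORCE sets are properties of the lumped network,
not of a real reconstruction; genome-scale results additionally depend on
the published model files, which are journal supplementary material and not
redistributed here (the corresponding acceptance test states this when they
are absent).

## Numerical choices and limitations

* LP feasibility 1e-9, value comparisons 1e-6, MUST separation ε 1e-6,
  MUST^X low-flux threshold 1e-3 mmol/gDW/h, big-M 1e4 with primal
  re-verification.
* Default bounds are finite (±1000 mmol/gDW/h), which the duality-based
  MILP requires.
* The vertex-enumeration oracle used in tests is exponential and applied
  only to ≤ 10-reaction networks; the full toy is cross-checked against
  GLPK instead.
* Chain collapse uses structural coupling (unique producer/consumer); it
  does not detect coupling through reversible or branched routes.
* The tabular dialect does not carry the objective; callers re-set it after
  loading.
* Scenario roles absent from a model's alias table are skipped when marked
  optional (e.g. phosphoketolase in the toy, whose lumped glycolysis already
  contains the published isomerase and GAPDH steps) and raise when required.
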