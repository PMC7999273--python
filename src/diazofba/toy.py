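"""Deterministic reduced two-cell network with hand-verifiable optima.

The generator emits a ~59-reaction diazotrophic model with the canonical
filament topology: a vegetative cell running the light-driven electron
transport chain (LETC), a lumped Calvin cycle and sucrose export, and a
heterocyst catabolising sucrose through the oxidative pentose-phosphate
pathway (OPPP), glycolysis and a two-step TCA lump with a 2-oxoglutarate
exit, powered by cyclic photosystem I and a respiratory chain capped by the
micro-oxic O2 bound, and running nitrogenase (16 ATP + 8 reduced ferredoxin
per N2, i.e. 4 NAD(P)H equivalents) plus glutamine synthetase.  Sucrose and
glutamate flow to the heterocyst; glutamine and 2-oxoglutarate flow back.

Electron bookkeeping uses explicit reduced-ferredoxin and NAD(P)H species
(2 Fd_red = 1 NAD(P)H), so the 8 e- / 4 NAD(P)H equivalence is a real
stoichiometric fact of the network.  Every non-boundary reaction is
elementally balanced; redox state is carried as H atoms (NADPH = NADP + 2 H,
Fd_red = Fd_ox + H) and the hexose pool lumps away phosphate bookkeeping.
Energy-carrier formulas satisfy ATP = ADP + Pi exactly, so the ATP
coefficients of the generator parameters can vary without breaking balance.

There is no randomness anywhere: generator output is bit-identical across
runs.  The shipped manifest declares the network counts and the reference
optima; every manifest value is reproduced by an independent solver in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import MetabolicModel, Metabolite, Reaction
from .optforce import PathwaySpec
from .solver import FluxRanges, pfba
from .twocell import TwoCellConfig, apply_diazotrophic_constraints, build_two_cell, default_config

__all__ = [
    "ToyParams",
    "ToyManifest",
    "make_toy_template",
    "make_toy_two_cell",
    "make_mfa_fixture",
    "make_pathway_fixtures",
    "MFA_FIXTURE_REACTIONS",
]


@dataclass
class ToyParams:
    """Tunable yields of the toy network.

    Mass balance fixes the electron-carrier stoichiometries (12 NADPH per
    fully oxidised hexose, 4 Fd_red per 8 photons at the linear LETC, 8 Fd_red
    per N2 at nitrogenase); the ATP terms and flux bounds are free.  Defaults
    give a nitrogenase demand ratio of 16 ATP : 4 NAD(P)H = 4:1.
    """

    photons_per_atp: float = 2.0  # cyclic PSI
    letc_atp_per_8_photons: float = 2.0  # linear chain, alongside 4 Fd_red
    p_o_ratio: float = 2.0  # ATP per NAD(P)H at the respiratory chain
    ppp_nadph_per_g6p: float = 12.0  # fixed by mass balance
    glycolysis_atp_per_g6p: float = 2.0
    n2ase_atp_per_n2: float = 16.0
    n2ase_fdred_per_n2: float = 8.0  # fixed by mass balance (2 NH3 + H2)
    biomass_g6p: float = 4.0  # mmol/gDW
    biomass_glu: float = 1.0  # mmol/gDW
    biomass_gam_atp: float = 10.0  # growth-associated maintenance, mmol/gDW
    config: TwoCellConfig = field(default_factory=lambda: _toy_config())

    def __post_init__(self) -> None:
        for name in ("photons_per_atp", "letc_atp_per_8_photons", "p_o_ratio",
                     "glycolysis_atp_per_g6p", "biomass_g6p", "biomass_glu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ppp_nadph_per_g6p != 12.0:
            raise ValueError("ppp_nadph_per_g6p is fixed at 12 by mass balance")
        if self.n2ase_fdred_per_n2 != 8.0:
            raise ValueError("n2ase_fdred_per_n2 is fixed at 8 by mass balance")


def _toy_config(**overrides) -> TwoCellConfig:
    return default_config(
        heterocyst_deletions=("psii_letc", "rubisco_calvin", "gogat"),
        vegetative_deletions=("nitrogenase",),
        **overrides,
    )


@dataclass
class ToyManifest:
    """Declared counts and reference optima of the shipped toy network.

    ``reference_optima`` values (mmol/gDW/h, growth in 1/h) are analytic where
    a closed form exists (carbon-limited growth, heterocyst NAD(P)H budgets)
    and otherwise frozen from the independent-solver run that released the
    generator; the test suite reproduces every entry.
    """

    template_reactions: int
    two_cell_reactions: int
    two_cell_metabolites: int
    vegetative_template_reactions: int
    heterocyst_template_reactions: int
    shared_template_reactions: int
    reference_optima: dict[str, float]
    lumping_notes: dict[str, str] = field(default_factory=dict)


# metabolite roster: id -> (name, formula map, super-compartment marker)
# formulas use H-atom redox bookkeeping and generic carrier elements
# (Fd ferredoxin, Nn nicotinamide, Ad adenosine, Cz coenzyme A)
_SPECIES: dict[str, tuple[str, dict[str, float]]] = {
    "photon": ("photon", {}),
    "h2o": ("water", {"H": 2, "O": 1}),
    "co2": ("carbon dioxide", {"C": 1, "O": 2}),
    "o2": ("oxygen", {"O": 2}),
    "n2": ("dinitrogen", {"N": 2}),
    "nh3": ("ammonia", {"N": 1, "H": 3}),
    "h2": ("dihydrogen", {"H": 2}),
    "etoh": ("ethanol", {"C": 2, "H": 6, "O": 1}),
    "fdox": ("oxidised ferredoxin", {"Fd": 1}),
    "fdred": ("reduced ferredoxin", {"Fd": 1, "H": 1}),
    "nadp": ("NAD(P)+", {"Nn": 1}),
    "nadph": ("NAD(P)H", {"Nn": 1, "H": 2}),
    "atp": ("ATP", {"Ad": 1, "P": 3}),
    "adp": ("ADP", {"Ad": 1, "P": 2}),
    "pi": ("phosphate", {"P": 1}),
    "g6p": ("hexose unit (glucose-6-phosphate pool)", {"C": 6, "H": 12, "O": 6}),
    "sucrose": ("sucrose (di-hexose unit)", {"C": 12, "H": 24, "O": 12}),
    "pyr": ("pyruvate", {"C": 3, "H": 4, "O": 3}),
    "akg": ("2-oxoglutarate", {"C": 5, "H": 6, "O": 5}),
    "suc": ("succinate", {"C": 4, "H": 6, "O": 4}),
    "coa": ("coenzyme A", {"Cz": 1}),
    "accoa": ("acetyl-CoA", {"C": 2, "H": 2, "O": 1, "Cz": 1}),
    "glu": ("glutamate", {"C": 5, "H": 9, "N": 1, "O": 4}),
    "gln": ("glutamine", {"C": 5, "H": 10, "N": 2, "O": 3}),
    "lys": ("lysine", {"C": 6, "H": 14, "N": 2, "O": 2}),
}

_TEMPLATE_ROLES = {
    "co2_uptake": "EX_ci",
    "photon_uptake": "photon_in",
    "n2_uptake": "n2_in",
    "o2_uptake": "o2_in",
    "co2_evolution": "ci_release",
    "psii": "psii_letc",
    "rubisco": "rubisco_calvin",
    "gogat": "gogat",
    "nitrogenase": "nitrogenase",
    # the lumped glycolysis reaction is both the G6P isomerase entry step and
    # the GAPDH segment of the published scenario ids
    "g6p_isomerase": "glycolysis",
    "gapdh": "glycolysis",
    "g6p_dehydrogenase": "oppp",
    "succinate_dehydrogenase": "sdh_tca3",
    "atp": "atp",
    "nadph": "nadph",
}

#: vegetative central-carbon reactions covered by the emulated MFA ranges.
#: A real labelling experiment covers a measured subset only; the donor
#: organism is a non-diazotroph, so nothing touching the sucrose shuttle or
#: the heterocyst is measured.
MFA_FIXTURE_REACTIONS = (
    "oppp__vc",
    "tca_2__vc",
    "sdh_tca3__vc",
    "sucrose_hydrolysis__vc",
    "ethanol_fermentation__vc",
    "lysine_synthesis__vc",
)


def make_toy_template(params: ToyParams | None = None) -> MetabolicModel:
    """Single-cell template of the toy network (30 reactions).

    ``build_two_cell`` with the default toy config turns this into the
    two-compartment model; cell-specific deletions are PSII+Calvin (lumped),
    RuBisCo-containing, and GOGAT in the heterocyst, nitrogenase in the
    vegetative cell.
    """
    p = params or ToyParams()
    model = MetabolicModel(id="toy_anabaena")
    for met_id, (name, formula) in _SPECIES.items():
        model.add_metabolite(
            Metabolite(id=met_id, name=name, formula=dict(formula), compartment="c")
        )
    model.add_metabolite(
        Metabolite(
            id="co2_ex",
            name="culture inorganic carbon pool",
            formula={"C": 1, "O": 2},
            compartment="e",
            super_compartment="shared-external",
        )
    )

    def rxn(rid, stoich, lb=0.0, ub=1000.0, kind="enzymatic", name="", subsystem=""):
        model.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                kind=kind,
                name=name,
                subsystem=subsystem,
            )
        )

    # boundary + transports -------------------------------------------------
    rxn("EX_ci", {"co2_ex": 1.0}, lb=-1000.0, kind="exchange",
        name="culture inorganic-carbon exchange (positive = uptake)")
    rxn("ci_uptake", {"co2_ex": -1.0, "co2": 1.0}, kind="transport",
        name="inorganic carbon uptake")
    rxn("ci_release", {"co2": -1.0, "co2_ex": 1.0}, kind="transport",
        name="CO2 evolution")
    rxn("photon_in", {"photon": 1.0}, kind="exchange", name="photon uptake")
    rxn("o2_in", {"o2": 1.0}, kind="exchange", name="O2 uptake")
    rxn("o2_out", {"o2": -1.0}, kind="exchange", name="O2 evolution")
    rxn("n2_in", {"n2": 1.0}, kind="exchange", name="N2 uptake")
    rxn("h2_out", {"h2": -1.0}, kind="exchange", name="H2 vent")
    rxn("etoh_out", {"etoh": -1.0}, kind="exchange", name="ethanol secretion")
    rxn("h2o_exch", {"h2o": 1.0}, lb=-1000.0, kind="exchange", name="water exchange")

    # photosynthetic / respiratory energetics -------------------------------
    a = p.letc_atp_per_8_photons
    rxn("psii_letc",
        {"photon": -8.0, "h2o": -2.0, "fdox": -4.0, "adp": -a, "pi": -a,
         "o2": 1.0, "fdred": 4.0, "atp": a},
        name="linear electron transport (PSII->PSI lump)",
        subsystem="photosynthesis")
    rxn("cef_psi",
        {"photon": -p.photons_per_atp, "adp": -1.0, "pi": -1.0, "atp": 1.0},
        name="cyclic electron flow around PSI", subsystem="photosynthesis")
    rxn("fnr", {"fdred": -2.0, "nadp": -1.0, "fdox": 2.0, "nadph": 1.0},
        lb=-1000.0, name="ferredoxin-NADP+ reductase", subsystem="photosynthesis")
    po = p.p_o_ratio
    rxn("retc",
        {"nadph": -2.0, "o2": -1.0, "adp": -2 * po, "pi": -2 * po,
         "nadp": 2.0, "h2o": 2.0, "atp": 2 * po},
        name="respiratory electron transport chain", subsystem="respiration")

    # carbon core -----------------------------------------------------------
    rxn("rubisco_calvin",
        {"co2": -6.0, "nadph": -12.0, "atp": -18.0,
         "g6p": 1.0, "h2o": 6.0, "nadp": 12.0, "adp": 18.0, "pi": 18.0},
        name="RuBisCo + Calvin cycle (lumped)", subsystem="carbon fixation")
    rxn("sucrose_synthesis", {"g6p": -2.0, "sucrose": 1.0},
        name="sucrose synthesis", subsystem="sucrose metabolism")
    rxn("sucrose_hydrolysis", {"sucrose": -1.0, "g6p": 2.0},
        name="sucrose hydrolysis", subsystem="sucrose metabolism")
    g = p.glycolysis_atp_per_g6p
    rxn("glycolysis",
        {"g6p": -1.0, "adp": -g, "pi": -g, "nadp": -2.0,
         "pyr": 2.0, "atp": g, "nadph": 2.0},
        name="glycolysis (G6P isomerase -> pyruvate lump)", subsystem="glycolysis")
    rxn("oppp",
        {"g6p": -1.0, "h2o": -6.0, "nadp": -12.0, "co2": 6.0, "nadph": 12.0},
        name="oxidative pentose phosphate pathway (full oxidation lump)",
        subsystem="pentose phosphate pathway")
    rxn("pdh", {"pyr": -1.0, "coa": -1.0, "nadp": -1.0,
                "accoa": 1.0, "co2": 1.0, "nadph": 1.0},
        name="pyruvate dehydrogenase", subsystem="TCA cycle")
    rxn("tca_1",
        {"pyr": -2.0, "h2o": -1.0, "nadp": -2.0, "akg": 1.0, "co2": 1.0, "nadph": 2.0},
        name="proximal TCA lump (pyruvate -> 2-oxoglutarate)", subsystem="TCA cycle")
    rxn("tca_2",
        {"akg": -1.0, "h2o": -1.0, "nadp": -1.0, "adp": -1.0, "pi": -1.0,
         "suc": 1.0, "co2": 1.0, "nadph": 1.0, "atp": 1.0},
        name="2-oxoglutarate -> succinate (substrate-level ATP)", subsystem="TCA cycle")
    rxn("sdh_tca3",
        {"suc": -1.0, "h2o": -4.0, "nadp": -7.0, "co2": 4.0, "nadph": 7.0},
        name="succinate dehydrogenase + distal TCA (full oxidation lump)",
        subsystem="TCA cycle")
    rxn("ethanol_fermentation",
        {"pyr": -1.0, "nadph": -1.0, "etoh": 1.0, "co2": 1.0, "nadp": 1.0},
        name="pyruvate decarboxylase + alcohol dehydrogenase",
        subsystem="fermentation")

    # nitrogen --------------------------------------------------------------
    na = p.n2ase_atp_per_n2
    rxn("nitrogenase",
        {"n2": -1.0, "fdred": -8.0, "atp": -na,
         "nh3": 2.0, "h2": 1.0, "fdox": 8.0, "adp": na, "pi": na},
        name="nitrogenase", subsystem="nitrogen fixation")
    rxn("gs", {"glu": -1.0, "nh3": -1.0, "atp": -1.0,
               "gln": 1.0, "h2o": 1.0, "adp": 1.0, "pi": 1.0},
        name="glutamine synthetase", subsystem="nitrogen assimilation")
    rxn("gogat", {"gln": -1.0, "akg": -1.0, "nadph": -1.0, "glu": 2.0, "nadp": 1.0},
        name="glutamine oxoglutarate aminotransferase", subsystem="nitrogen assimilation")
    rxn("gdh", {"akg": -1.0, "nh3": -1.0, "nadph": -1.0,
                "glu": 1.0, "h2o": 1.0, "nadp": 1.0},
        name="glutamate dehydrogenase", subsystem="nitrogen assimilation")

    # biosynthesis ----------------------------------------------------------
    rxn("lysine_synthesis",
        {"pyr": -2.0, "glu": -2.0, "nadph": -2.0, "atp": -2.0,
         "lys": 1.0, "akg": 2.0, "h2o": 2.0, "nadp": 2.0, "adp": 2.0, "pi": 2.0},
        name="lysine biosynthesis (aspartate-pathway lump)",
        subsystem="amino acid metabolism")
    gam = p.biomass_gam_atp
    rxn("biomass",
        {"g6p": -p.biomass_g6p, "glu": -p.biomass_glu, "atp": -gam,
         "adp": gam, "pi": gam},
        kind="biomass", name="biomass formation (1 gDW per unit flux)")

    model.annotations["roles"] = dict(_TEMPLATE_ROLES)
    model.objective = ("biomass", "max")
    model.validate()
    return model


def make_toy_two_cell(
    params: ToyParams | None = None,
) -> tuple[MetabolicModel, ToyManifest]:
    """Build the constrained two-cell toy model and its manifest.

    The returned model carries the full diazotrophic constraint set
    (inorganic carbon 8.5, photons 100 per cell, N2 10, heterocyst O2 0.063,
    heterocyst biomass floor 0.1 x 0.1824, glutamate/glutamine coupling) and
    maximises vegetative biomass.  Raises at generation time if the parameter
    combination cannot sustain growth.
    """
    p = params or ToyParams()
    template = make_toy_template(p)
    model = build_two_cell(template, p.config)
    apply_diazotrophic_constraints(model, p.config)
    manifest = _build_manifest(p)
    from .solver import fba

    check = fba(model)
    if not check.optimal or check.objective_value <= 0:
        raise ValueError(
            f"toy parameters yield no growth (status {check.status}, "
            f"mu={check.objective_value})"
        )
    return model, manifest


def _build_manifest(p: ToyParams) -> ToyManifest:
    cfg = p.config
    # carbon per unit biomass (mmol C/gDW): hexose + glutamate precursors
    carbon = 6 * p.biomass_g6p + 5 * p.biomass_glu
    hc_floor = cfg.heterocyst_biomass_lb_fraction * cfg.mu_exp
    # carbon-limited optima: all fixed carbon ends in biomass, heterocyst CO2
    # is re-fixed through the shared pool, nothing is vented at the optimum
    mu_default = cfg.co2_uptake_ub / carbon - hc_floor
    mu_zero_turnover = cfg.co2_uptake_ub / carbon
    # heterocyst NAD(P)H demand at zero turnover: FNR for nitrogenase only.
    # NH3 demand mu (glutamate->glutamine shuttle), N2ase = mu/2,
    # Fd_red = 8 * mu/2, NAD(P)H = Fd_red / 2 = 2 mu.
    d_nadph = 2.0 * mu_zero_turnover
    ref = {
        # two-cell model, full constraint set
        "default_growth": mu_default,
        # energetics module conditions (no heterocyst macromolecule turnover)
        "scheme_default_growth": mu_zero_turnover,
        "scheme_oppp_growth": mu_zero_turnover,
        "scheme_gly_tca_growth": mu_zero_turnover,
        # FVA minima at the scheme optimum; sucrose in di-hexose units
        "scheme_default_min_sucrose": d_nadph / 24.0,
        "scheme_default_min_co2": d_nadph / 4.0,
        "scheme_oppp_min_sucrose": d_nadph / 24.0,
        "scheme_oppp_min_co2": d_nadph / 2.0,
        "scheme_gly_tca_min_sucrose": d_nadph / 24.0,
        "scheme_gly_tca_min_co2": d_nadph / 4.0,
        "scheme_gly_tca_1_min_sucrose": d_nadph / 24.0,
        "scheme_gly_tca_1_min_co2": d_nadph / 2.0,
        "scheme_gly_tca_2_min_sucrose": d_nadph / 8.0,
        "scheme_gly_tca_2_min_co2": d_nadph / 4.0,
        # growth fixed at the experimental 0.1824 1/h (heterocyst floor on)
        "fixed_growth_min_nitrogenase": (cfg.mu_exp + hc_floor) / 2.0,
        "fixed_growth_min_glu_exchange": cfg.mu_exp,
        # heterocyst hexose demand at fixed growth: biomass precursors (4h),
        # the 2-oxoglutarate skeleton for GDH-made glutamate (h, whose
        # glycolysis+TCA route also yields 4 NAD(P)H/hexose), and OPPP
        # oxidation covering the remaining NAD(P)H demand (2 mu - h)/12
        "fixed_growth_min_sucrose": (
            (p.biomass_g6p + 1.0) * hc_floor + (2.0 * cfg.mu_exp - hc_floor) / 12.0
        ) / 2.0,
        "min_ci_uptake_at_mu_exp": carbon * (cfg.mu_exp + hc_floor),
        # frozen from the release solve (no closed form; LETC- growth is
        # carbon/oxygen co-limited, the yields photon-limited); reproduced by
        # the independent GLPK oracle in tests/test_toy_fixtures.py
        "letc_minus_growth": 0.202888888888889,
        "valerolactam_theoretical_yield": 1.319137777777778,
        "caprolactam_theoretical_yield": 1.186920000000000,
        "valerolactam_k1_guaranteed_flux": 1.187224000000000,
        "caprolactam_k1_guaranteed_flux": 1.068228000000000,
    }
    return ToyManifest(
        template_reactions=30,
        two_cell_reactions=59,
        two_cell_metabolites=52,  # incl. shared CO2 pool and coupling pseudo-species
        vegetative_template_reactions=28,
        heterocyst_template_reactions=26,
        shared_template_reactions=25,
        reference_optima=ref,
        lumping_notes={
            "rubisco_calvin": "whole Calvin cycle in one reaction, 6 CO2 -> 1 hexose",
            "glycolysis": "G6P isomerase through pyruvate kinase in one reaction",
            "tca": "two lumps with a 2-oxoglutarate exit between them",
            "g6p": "hexose pool without phosphate bookkeeping",
            "letc": "PSII+b6f+PSI in one reaction; 8 photons -> 4 Fd_red + ATP",
        },
    )


def make_mfa_fixture(model: MetabolicModel, rel_width: float = 0.1) -> FluxRanges:
    """Emulated 13C-MFA flux ranges for the vegetative central-carbon subset.

    Ranges are +-``rel_width`` around the parsimonious-FBA fluxes of the toy
    model (a zero flux stays pinned at zero, as a measured-silent reaction).
    Deterministic; every covered range contains the pFBA flux by construction.
    """
    sol = pfba(model)
    if not sol.optimal:
        raise ValueError("toy model pFBA failed; cannot derive MFA fixture")
    ranges = {}
    for rxn_id in MFA_FIXTURE_REACTIONS:
        f = sol.fluxes[rxn_id]
        lo, hi = sorted(((1 - rel_width) * f, (1 + rel_width) * f))
        ranges[rxn_id] = (lo, hi)
    return FluxRanges(ranges, context={"source": "toy pFBA +-10% (synthetic MFA stand-in)"})


def make_pathway_fixtures() -> list[PathwaySpec]:
    """The two lactam production pathways, carbon/nitrogen balanced.

    ``five_aminovalerate``: lysine 2-monooxygenase (davB), 5-aminopentanamidase
    (davA) and lactam synthase turn lysine into valerolactam (C5 backbone + N
    conserved; one CO2 and one NH3 released along the way).

    ``adipyl_coa``: succinate-CoA ligase feeds succinyl-CoA which is condensed
    with acetyl-CoA (3-oxoadipyl-CoA thiolase), reduced (paaH/paaF/ter/ALDH
    lump), transaminated and cyclised to caprolactam (C6 backbone conserved).
    """
    five_av = PathwaySpec(
        name="five_aminovalerate",
        metabolites=[
            Metabolite("a5pam", name="5-aminopentanamide",
                       formula={"C": 5, "H": 12, "N": 2, "O": 1}),
            Metabolite("a5pa", name="5-aminopentanoate",
                       formula={"C": 5, "H": 11, "N": 1, "O": 2}),
            Metabolite("vlact", name="valerolactam (2-piperidinone)",
                       formula={"C": 5, "H": 9, "N": 1, "O": 1}),
        ],
        reactions=[
            Reaction("davB", {"lys": -1.0, "o2": -1.0,
                              "a5pam": 1.0, "co2": 1.0, "h2o": 1.0},
                     name="lysine 2-monooxygenase"),
            Reaction("davA", {"a5pam": -1.0, "h2o": -1.0, "a5pa": 1.0, "nh3": 1.0},
                     name="5-aminopentanamidase"),
            Reaction("lactam_synthase_v",
                     {"a5pa": -1.0, "atp": -1.0,
                      "vlact": 1.0, "h2o": 1.0, "adp": 1.0, "pi": 1.0},
                     name="lactam synthase"),
        ],
        product_metabolite="vlact",
        product_exchange="EX_valerolactam",
        precursors=("lys",),
    )
    adipyl = PathwaySpec(
        name="adipyl_coa",
        metabolites=[
            Metabolite("succoa", name="succinyl-CoA",
                       formula={"C": 4, "H": 6, "O": 4, "Cz": 1}),
            Metabolite("oacoa", name="3-oxoadipyl-CoA",
                       formula={"C": 6, "H": 8, "O": 5, "Cz": 1}),
            Metabolite("adsa", name="adipate semialdehyde",
                       formula={"C": 6, "H": 10, "O": 3}),
            Metabolite("aca6", name="6-aminocaproate",
                       formula={"C": 6, "H": 13, "N": 1, "O": 2}),
            Metabolite("clact", name="caprolactam",
                       formula={"C": 6, "H": 11, "N": 1, "O": 1}),
        ],
        reactions=[
            Reaction("sucl", {"suc": -1.0, "coa": -1.0, "atp": -1.0,
                              "succoa": 1.0, "adp": 1.0, "pi": 1.0},
                     name="succinate-CoA ligase"),
            Reaction("paaJ_thiolase",
                     {"succoa": -1.0, "accoa": -1.0, "oacoa": 1.0, "coa": 1.0},
                     name="3-oxoadipyl-CoA thiolase"),
            Reaction("adipyl_reduction",
                     {"oacoa": -1.0, "nadph": -3.0,
                      "adsa": 1.0, "coa": 1.0, "h2o": 2.0, "nadp": 3.0},
                     name="3-oxoadipyl-CoA -> adipate semialdehyde "
                          "(paaH/paaF/ter/ALDH lump)"),
            Reaction("aca_transaminase",
                     {"adsa": -1.0, "glu": -1.0, "aca6": 1.0, "akg": 1.0},
                     name="6-aminocaproate transaminase"),
            Reaction("lactam_synthase_c",
                     {"aca6": -1.0, "atp": -1.0,
                      "clact": 1.0, "h2o": 1.0, "adp": 1.0, "pi": 1.0},
                     name="lactam synthase"),
        ],
        product_metabolite="clact",
        product_exchange="EX_caprolactam",
        precursors=("suc", "accoa"),
    )
    return [five_av, adipyl]
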