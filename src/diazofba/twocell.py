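"""Construction of the two-super-compartment diazotrophic model.

A single-cell template is duplicated into vegetative (``__vc``) and
heterocyst (``__hc``) super-compartments.  The heterocyst copy loses
photosystem II, RuBisCo and GOGAT; the vegetative copy loses nitrogenase.
Sucrose and glutamate flow vegetative -> heterocyst, glutamine and
2-oxoglutarate flow heterocyst -> vegetative.  The simulation constraint set
(inorganic-carbon, photon, N2 and heterocyst-O2 bounds, the heterocyst
biomass floor and the glutamate/glutamine flux coupling) reproduces the
diazotrophic culture conditions of *Anabaena* sp. ATCC 33047: carbon-limited
growth at an experimentally estimated rate of 0.1824 1/h with ~9 % of cells
differentiated into heterocysts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

from .model import (
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    split_cell_suffix,
)

__all__ = [
    "TwoCellConfig",
    "BiomassComposition",
    "DEFAULT_CONFIG",
    "build_two_cell",
    "apply_diazotrophic_constraints",
    "heterocyst_o2_bound",
    "growth_rate_from_doubling_time",
    "build_biomass_reaction",
    "GLU_GLN_COUPLING_MET",
]

#: pseudo-metabolite implementing the glutamate/glutamine flux coupling as a
#: plain S v = 0 balance row (produced by the glu exchange, consumed by the
#: gln exchange), keeping the problem a pure LP
GLU_GLN_COUPLING_MET = "glu_gln_coupling"


@dataclass
class TwoCellConfig:
    """Configuration of the two-cell construction and its diazotrophic bounds.

    All flux bounds are in mmol/gDW/h; ``mu_exp`` in 1/h.  Defaults are the
    diazotrophic simulation conditions: inorganic carbon capped at the minimum
    uptake supporting the measured growth rate, photon uptake capped per
    photosystem to restrict futile cycles, N2 non-limiting, and the
    heterocyst O2 cap derived from the culture-level uptake scaled by the
    heterocyst fraction of the filament.
    """

    heterocyst_deletions: tuple[str, ...] = ()
    vegetative_deletions: tuple[str, ...] = ()
    intercell_exchanges: tuple[tuple[str, str], ...] = ()
    co2_uptake_ub: float = 8.5
    photon_ub_per_photosystem: float = 100.0
    n2_uptake_ub: float = 10.0
    mu_exp: float = 0.1824
    heterocyst_biomass_lb_fraction: float = 0.1
    culture_o2_uptake: float = 0.7
    heterocyst_fraction: float = 0.09
    couple_glu_gln: bool = True

    def __post_init__(self) -> None:
        for name in (
            "co2_uptake_ub",
            "photon_ub_per_photosystem",
            "n2_uptake_ub",
            "mu_exp",
            "heterocyst_biomass_lb_fraction",
            "culture_o2_uptake",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.heterocyst_fraction < 1.0:
            raise ValueError("heterocyst_fraction must lie in (0, 1)")
        exchange_mets = {met for met, _ in self.intercell_exchanges}
        overlap = (set(self.heterocyst_deletions) | set(self.vegetative_deletions)) & exchange_mets
        if overlap:
            raise ValueError(f"deletions overlap exchanged metabolites: {sorted(overlap)}")

    def to_dict(self) -> dict:
        return asdict(self)


def default_config(
    heterocyst_deletions: tuple[str, ...],
    vegetative_deletions: tuple[str, ...],
    intercell_exchanges: tuple[tuple[str, str], ...] | None = None,
    **overrides,
) -> TwoCellConfig:
    """TwoCellConfig with the canonical deletion/exchange layout.

    The deletion ids are model-specific (template reaction ids for PSII,
    RuBisCo and GOGAT in the heterocyst; nitrogenase in the vegetative cell),
    so they are required arguments; the exchanged metabolites default to
    sucrose/glutamate (vc->hc) and glutamine/2-oxoglutarate (hc->vc).
    """
    if intercell_exchanges is None:
        intercell_exchanges = (
            ("sucrose", "vc->hc"),
            ("glu", "vc->hc"),
            ("gln", "hc->vc"),
            ("akg", "hc->vc"),
        )
    return TwoCellConfig(
        heterocyst_deletions=tuple(heterocyst_deletions),
        vegetative_deletions=tuple(vegetative_deletions),
        intercell_exchanges=tuple(intercell_exchanges),
        **overrides,
    )


DEFAULT_CONFIG = TwoCellConfig()


def heterocyst_o2_bound(culture_uptake: float, heterocyst_fraction: float) -> float:
    """Heterocyst O2 uptake upper bound from the culture-level uptake rate.

    The culture O2 uptake (mmol/gDW/h, air-saturated suspension) is
    apportioned to the heterocyst compartment by the fraction of cells that
    are heterocysts: ``culture_uptake * heterocyst_fraction``.
    """
    if culture_uptake < 0 or heterocyst_fraction < 0:
        raise ValueError("inputs must be non-negative")
    if heterocyst_fraction > 1:
        raise ValueError("heterocyst_fraction must be <= 1")
    return culture_uptake * heterocyst_fraction


def growth_rate_from_doubling_time(td: float) -> float:
    """Specific growth rate (1/h) from a doubling time (h): ln(2)/td."""
    if td <= 0:
        raise ValueError("doubling time must be positive")
    return math.log(2.0) / td


# ---------------------------------------------------------------------------
# biomass


@dataclass
class BiomassComposition:
    """Macromolecule mass fractions and precursor molar masses.

    ``classes`` maps a macromolecule class name to ``(mass_fraction_g_per_g,
    {precursor metabolite id: molar mass g/mmol})``; multi-precursor classes
    split their mass equally unless per-precursor shares are given as
    ``{met: (share, molar_mass)}``.  Fractions are rescaled to 1 g total.
    """

    classes: dict[str, tuple[float, dict]] = field(default_factory=dict)
    gam_atp: float = 0.0  # growth-associated maintenance, mmol ATP/gDW
    atp_ids: tuple[str, str, str] | None = None  # (atp, adp, pi)

    def rescaled_fractions(self) -> dict[str, float]:
        total = sum(fraction for fraction, _ in self.classes.values())
        if total <= 0:
            raise ValueError("mass fractions sum to zero")
        return {name: fraction / total for name, (fraction, _) in self.classes.items()}


def build_biomass_reaction(
    comp: BiomassComposition, rxn_id: str = "biomass"
) -> Reaction:
    """Biomass formation reaction from a composition.

    Precursor coefficient (mmol/gDW) = rescaled mass fraction / molar mass
    (g/mmol), so the reaction consumes exactly 1 g of precursors per unit
    flux; ATP maintenance is added when configured.  Mass fractions not
    summing to 1 are rescaled (to within 1e-9).
    """
    fractions = comp.rescaled_fractions()
    assert abs(sum(fractions.values()) - 1.0) < 1e-9
    stoich: dict[str, float] = {}
    for name, (_, precursors) in comp.classes.items():
        fraction = fractions[name]
        shares: dict[str, tuple[float, float]] = {}
        for met, value in precursors.items():
            if isinstance(value, tuple):
                shares[met] = value
            else:
                shares[met] = (1.0 / len(precursors), float(value))
        for met, (share, molar_mass) in shares.items():
            if molar_mass <= 0:
                raise ValueError(f"molar mass for {met} must be positive")
            stoich[met] = stoich.get(met, 0.0) - fraction * share / molar_mass
    if comp.gam_atp and comp.atp_ids:
        atp, adp, pi = comp.atp_ids
        stoich[atp] = stoich.get(atp, 0.0) - comp.gam_atp
        stoich[adp] = stoich.get(adp, 0.0) + comp.gam_atp
        stoich[pi] = stoich.get(pi, 0.0) + comp.gam_atp
    return Reaction(id=rxn_id, stoichiometry=stoich, lower_bound=0.0, kind="biomass")


# ---------------------------------------------------------------------------
# two-cell construction

_SUFFIX_FOR_CELL = {"vc": "__vc", "hc": "__hc"}


def _suffix_id(identifier: str, cell: str) -> str:
    return f"{identifier}{_SUFFIX_FOR_CELL[cell]}"


def build_two_cell(template: MetabolicModel, config: TwoCellConfig) -> MetabolicModel:
    """Duplicate a single-cell template into a two-cell diazotrophic model.

    Every template reaction is duplicated with ``__vc`` and ``__hc`` suffixes,
    minus the cell-specific deletions; reactions touching only shared-external
    metabolites (culture-boundary exchanges) are copied once, unsuffixed.
    The configured inter-cell exchange reactions are added (named
    ``{met}_vc_hc_exch`` after the published id dialect) and the objective is
    set to the vegetative biomass reaction.
    """
    template.validate()
    template_ids = {r.id for r in template.reactions}
    unknown = (set(config.heterocyst_deletions) | set(config.vegetative_deletions)) - template_ids
    if unknown:
        raise ModelValidationError(f"deletion ids not in template: {sorted(unknown)}")

    model = MetabolicModel(id=f"{template.id}_two_cell")
    # metabolites: cell copies for cell species, single copies for shared-external
    for met in template.metabolites:
        if met.super_compartment == "shared-external":
            model.add_metabolite(
                Metabolite(
                    id=met.id,
                    name=met.name,
                    formula=None if met.formula is None else dict(met.formula),
                    charge=met.charge,
                    compartment=met.compartment,
                    super_compartment="shared-external",
                )
            )
        else:
            for cell, super_comp in (("vc", "vegetative"), ("hc", "heterocyst")):
                model.add_metabolite(
                    Metabolite(
                        id=_suffix_id(met.id, cell),
                        name=met.name,
                        formula=None if met.formula is None else dict(met.formula),
                        charge=met.charge,
                        compartment=met.compartment,
                        super_compartment=super_comp,
                    )
                )

    shared_ids = {
        m.id for m in template.metabolites if m.super_compartment == "shared-external"
    }
    deletions = {"vc": set(config.vegetative_deletions), "hc": set(config.heterocyst_deletions)}
    biomass_ids: dict[str, str] = {}
    for rxn in template.reactions:
        boundary = set(rxn.stoichiometry) <= shared_ids
        if boundary:
            model.add_reaction(
                Reaction(
                    id=rxn.id,
                    stoichiometry=dict(rxn.stoichiometry),
                    lower_bound=rxn.lower_bound,
                    upper_bound=rxn.upper_bound,
                    gpr=rxn.gpr,
                    subsystem=rxn.subsystem,
                    ec=rxn.ec,
                    name=rxn.name,
                    kind=rxn.kind,
                )
            )
            continue
        for cell in ("vc", "hc"):
            if rxn.id in deletions[cell]:
                continue
            stoich = {
                (met if met in shared_ids else _suffix_id(met, cell)): coef
                for met, coef in rxn.stoichiometry.items()
            }
            new_id = _suffix_id(rxn.id, cell)
            model.add_reaction(
                Reaction(
                    id=new_id,
                    stoichiometry=stoich,
                    lower_bound=rxn.lower_bound,
                    upper_bound=rxn.upper_bound,
                    gpr=rxn.gpr,
                    subsystem=rxn.subsystem,
                    ec=rxn.ec,
                    name=rxn.name,
                    kind=rxn.kind,
                )
            )
            if rxn.kind == "biomass":
                biomass_ids[cell] = new_id

    # inter-cell exchanges (non-facilitated)
    for met, direction in config.intercell_exchanges:
        if direction not in ("vc->hc", "hc->vc"):
            raise ValueError(f"bad exchange direction {direction!r} for {met}")
        src, dst = ("vc", "hc") if direction == "vc->hc" else ("hc", "vc")
        for cell in (src, dst):
            if not model.has_metabolite(_suffix_id(met, cell)):
                raise ModelValidationError(
                    f"exchange metabolite {met!r} missing in {cell} compartment"
                )
        model.add_reaction(
            Reaction(
                id=f"{met}_vc_hc_exch",
                stoichiometry={_suffix_id(met, src): -1.0, _suffix_id(met, dst): 1.0},
                lower_bound=0.0,
                upper_bound=1000.0,
                kind="intercell-exchange",
            )
        )

    if "vc" in biomass_ids:
        model.objective = (biomass_ids["vc"], "max")

    # propagate template role aliases to the cell copies
    roles: dict[str, object] = {}
    template_roles = template.annotations.get("roles", {})
    for role, value in template_roles.items():
        ids = [value] if isinstance(value, str) else list(value)
        for cell in ("vc", "hc"):
            mapped = [
                _suffix_id(i, cell)
                for i in ids
                if model.has_reaction(_suffix_id(i, cell))
                or model.has_metabolite(_suffix_id(i, cell))
            ]
            if mapped:
                roles[f"{role}__{cell}"] = mapped[0] if len(mapped) == 1 else mapped
        unsuffixed = [i for i in ids if model.has_reaction(i) or model.has_metabolite(i)]
        if unsuffixed:
            roles[role] = unsuffixed[0] if len(unsuffixed) == 1 else unsuffixed
    for met, direction in config.intercell_exchanges:
        roles[f"{met}_intercell"] = f"{met}_vc_hc_exch"
    for cell, rxn_id in biomass_ids.items():
        roles[f"biomass__{cell}"] = rxn_id
    model.annotations["roles"] = roles
    model.annotations["two_cell_config"] = config.to_dict()
    model.validate()
    return model


def _role_reactions(model: MetabolicModel, role: str, required: bool) -> list[str]:
    try:
        ids = model.resolve_role(role, required=required)
    except KeyError:
        raise ModelValidationError(
            f"model {model.id}: cannot apply diazotrophic constraints, "
            f"missing role {role!r}"
        ) from None
    return ids


def apply_diazotrophic_constraints(
    model: MetabolicModel, config: TwoCellConfig = DEFAULT_CONFIG
) -> MetabolicModel:
    """Apply the diazotrophic simulation bounds to a two-cell model (in place).

    Sets: inorganic-carbon uptake ub; photon uptake ub per photosystem; N2
    uptake ub; heterocyst O2 uptake ub from :func:`heterocyst_o2_bound`;
    heterocyst biomass lower bound at ``heterocyst_biomass_lb_fraction *
    mu_exp``; leaves the sucrose and 2-oxoglutarate inter-cell exchanges
    unbounded above; optionally couples the glutamate and glutamine exchange
    fluxes as an equality (pseudo-metabolite balance row); and sets the
    objective to the vegetative biomass drain.

    Role aliases consulted: ``co2_uptake``, ``photon_uptake__vc/__hc``,
    ``n2_uptake__vc/__hc``, ``o2_uptake__hc``, ``biomass__vc/__hc``,
    ``glu_intercell``, ``gln_intercell``, ``sucrose_intercell``,
    ``akg_intercell``.
    """
    for rxn_id in _role_reactions(model, "co2_uptake", required=True):
        model.set_bounds(rxn_id, upper=config.co2_uptake_ub)
    for role in ("photon_uptake__vc", "photon_uptake__hc"):
        for rxn_id in _role_reactions(model, role, required=True):
            model.set_bounds(rxn_id, upper=config.photon_ub_per_photosystem)
    for role in ("n2_uptake__vc", "n2_uptake__hc"):
        for rxn_id in model.resolve_role(role, required=False):
            model.set_bounds(rxn_id, upper=config.n2_uptake_ub)
    for rxn_id in _role_reactions(model, "o2_uptake__hc", required=True):
        model.set_bounds(
            rxn_id,
            upper=heterocyst_o2_bound(config.culture_o2_uptake, config.heterocyst_fraction),
        )
    hc_biomass = _role_reactions(model, "biomass__hc", required=True)[0]
    model.set_bounds(
        hc_biomass, lower=config.heterocyst_biomass_lb_fraction * config.mu_exp
    )
    for role in ("sucrose_intercell", "akg_intercell"):
        for rxn_id in model.resolve_role(role, required=False):
            model.set_bounds(rxn_id, upper=1000.0)
    if config.couple_glu_gln:
        couple_exchange_fluxes(
            model,
            _role_reactions(model, "glu_intercell", required=True)[0],
            _role_reactions(model, "gln_intercell", required=True)[0],
        )
    vc_biomass = _role_reactions(model, "biomass__vc", required=True)[0]
    model.objective = (vc_biomass, "max")
    model.validate()
    return model


def couple_exchange_fluxes(model: MetabolicModel, produced_by: str, consumed_by: str) -> None:
    """Force two reaction fluxes equal via a pseudo-metabolite balance row.

    The first reaction produces one unit of the pseudo-species per unit flux,
    the second consumes one; ``S v = 0`` then enforces equality.  Idempotent.
    """
    if model.has_metabolite(GLU_GLN_COUPLING_MET):
        return
    model.add_metabolite(
        Metabolite(
            id=GLU_GLN_COUPLING_MET,
            name="glutamate/glutamine exchange coupling (pseudo-species)",
            formula={},
            compartment="pseudo",
            super_compartment="shared-external",
        )
    )
    model.get_reaction(produced_by).stoichiometry[GLU_GLN_COUPLING_MET] = 1.0
    model.get_reaction(consumed_by).stoichiometry[GLU_GLN_COUPLING_MET] = -1.0
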