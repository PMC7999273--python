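"""Stoichiometric model data structures and consistency checks.

A :class:`MetabolicModel` holds the metabolites, reactions and objective of a
constraint-based model: the flux space ``S v = 0``, ``lb <= v <= ub``.  Models
may be single-cell templates or two-super-compartment (vegetative cell +
heterocyst) models in which reaction and metabolite ids carry a ``__vc`` /
``__hc`` cell suffix (ModelSEED-style template ids, e.g. ``rxn00558__hc``).
"""

from __future__ import annotations

import copy as _copy
import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelSummary",
    "Imbalance",
    "REACTION_KINDS",
    "SUPER_COMPARTMENTS",
    "CELL_SUFFIXES",
    "parse_formula",
    "format_formula",
    "split_cell_suffix",
    "count_unique",
    "check_mass_charge_balance",
]

REACTION_KINDS = frozenset(
    {
        "enzymatic",
        "transport",
        "exchange",
        "demand",
        "biomass",
        "intercell-exchange",
        "spontaneous",
    }
)

SUPER_COMPARTMENTS = frozenset({"vegetative", "heterocyst", "shared-external"})

#: cell-membership suffixes on template ids
CELL_SUFFIXES = ("__vc", "__hc")

# Elements with dedicated parsing support; any other [A-Z][a-z]* token is kept
# as a generic element symbol.  R-group / polymer tokens exempt a formula from
# balance checking.
_RGROUP_TOKENS = frozenset({"R", "X", "*"})
_FORMULA_RE = re.compile(r"([A-Z][a-z]*|\*)(\d*\.?\d*)")


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


def parse_formula(formula: str | None) -> dict[str, float] | None:
    """Parse an elemental formula string into an element -> count map.

    Returns ``None`` for an unknown formula (``None`` or empty string) and an
    empty dict for the literal massless formula ``""``... distinguishing the
    two at string level is impossible, so callers that need "massless" pass
    ``{}`` directly.  Counts may be fractional (average polymer units).
    """
    if formula is None:
        return None
    formula = formula.strip()
    if not formula:
        return None
    pos = 0
    counts: dict[str, float] = {}
    for match in _FORMULA_RE.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = match.end()
        element, number = match.groups()
        n = float(number) if number else 1.0
        counts[element] = counts.get(element, 0.0) + n
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
    return counts


def format_formula(counts: Mapping[str, float] | None) -> str:
    if counts is None:
        return ""
    parts = []
    for element in sorted(counts):
        n = counts[element]
        if n == int(n):
            n = int(n)
        parts.append(f"{element}{'' if n == 1 else n}")
    return "".join(parts)


def split_cell_suffix(identifier: str) -> tuple[str, str | None]:
    """Split ``rxn00558__hc`` into ``("rxn00558", "hc")``; no suffix -> ``(id, None)``."""
    for suffix in CELL_SUFFIXES:
        if identifier.endswith(suffix):
            return identifier[: -len(suffix)], suffix[2:]
    return identifier, None


@dataclass
class Metabolite:
    """A compartment-suffixed chemical species.

    ``formula`` is an element -> non-negative count map; ``None`` means
    unknown composition and ``{}`` means massless (photons, pseudo-species).
    """

    id: str
    name: str = ""
    formula: dict[str, float] | None = None
    charge: int = 0
    compartment: str = "c"
    super_compartment: str = "vegetative"

    def __post_init__(self) -> None:
        if self.super_compartment not in SUPER_COMPARTMENTS:
            raise ModelValidationError(
                f"metabolite {self.id}: unknown super_compartment "
                f"{self.super_compartment!r}"
            )
        if self.formula is not None:
            for element, n in self.formula.items():
                if n < 0:
                    raise ModelValidationError(
                        f"metabolite {self.id}: negative count for {element}"
                    )


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds in mmol/gDW/h.

    ``stoichiometry`` maps metabolite id -> signed coefficient (negative =
    consumed).  ``gpr`` is a boolean gene expression over gene ids (string,
    AND/OR/parentheses), possibly empty.
    """

    id: str
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: str = ""
    subsystem: str = ""
    ec: str = ""
    name: str = ""
    kind: str = "enzymatic"

    def __post_init__(self) -> None:
        if self.kind not in REACTION_KINDS:
            raise ModelValidationError(f"reaction {self.id}: unknown kind {self.kind!r}")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0.0 < self.upper_bound

    def genes(self) -> set[str]:
        """Gene ids appearing in the GPR string."""
        tokens = re.split(r"[()\s]+", self.gpr)
        return {t for t in tokens if t and t.lower() not in ("and", "or")}

    def equation(self, arrow: str | None = None) -> str:
        """Render the reaction as an equation string (tabular dialect)."""
        if arrow is None:
            arrow = "<=>" if self.lower_bound < 0 else "->"
        lhs, rhs = [], []
        for met_id in sorted(self.stoichiometry):
            coef = self.stoichiometry[met_id]
            mag = abs(coef)
            term = met_id if mag == 1 else f"{mag:.12g} {met_id}"
            (lhs if coef < 0 else rhs).append(term)
        return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


@dataclass
class MetabolicModel:
    """A genome-scale (or toy) stoichiometric model.

    The stoichiometric matrix ``S`` has one row per metabolite and one column
    per reaction, in list order.  ``objective`` is ``(reaction_id, direction)``
    with direction ``"max"`` or ``"min"``.  ``annotations`` is a free-form map;
    the key ``"roles"`` holds the role-alias table (role name -> reaction or
    metabolite id) that decouples analysis code from any one id dialect.
    """

    id: str = "model"
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective: tuple[str, str] | None = None
    annotations: dict = field(default_factory=dict)

    # -- indexing -------------------------------------------------------
    def metabolite_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    def reaction_index(self) -> dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def get_metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(f"no metabolite {met_id!r} in model {self.id}")

    def get_reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(f"no reaction {rxn_id!r} in model {self.id}")

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    def has_metabolite(self, met_id: str) -> bool:
        return any(m.id == met_id for m in self.metabolites)

    # -- editing --------------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if self.has_metabolite(met.id):
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites.append(met)

    def add_reaction(self, rxn: Reaction) -> None:
        if self.has_reaction(rxn.id):
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        missing = [m for m in rxn.stoichiometry if not self.has_metabolite(m)]
        if missing:
            raise ModelValidationError(
                f"reaction {rxn.id}: unknown metabolites {sorted(missing)}"
            )
        self.reactions.append(rxn)

    def remove_reaction(self, rxn_id: str) -> None:
        rxn = self.get_reaction(rxn_id)
        self.reactions.remove(rxn)

    def set_bounds(self, rxn_id: str, lower: float | None = None, upper: float | None = None) -> None:
        rxn = self.get_reaction(rxn_id)
        if lower is not None:
            rxn.lower_bound = lower
        if upper is not None:
            rxn.upper_bound = upper
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelValidationError(
                f"reaction {rxn_id}: bounds inverted "
                f"({rxn.lower_bound}, {rxn.upper_bound})"
            )

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    # -- roles ----------------------------------------------------------
    @property
    def roles(self) -> dict[str, object]:
        return self.annotations.setdefault("roles", {})

    def resolve_role(self, role: str, required: bool = True) -> list[str]:
        """Map a role alias (e.g. ``heterocyst_co2_evolution``) to model ids.

        A role may name one id or a list of ids.  If the role is absent and
        ``role`` itself is a model id, the id is returned as-is (§-style ids
        like ``rxn00558__hc`` can be used directly).
        """
        value = self.roles.get(role)
        if value is None:
            if self.has_reaction(role) or self.has_metabolite(role):
                return [role]
            if required:
                raise KeyError(
                    f"model {self.id}: role {role!r} is not mapped and is not an id"
                )
            return []
        if isinstance(value, str):
            return [value]
        return list(value)

    # -- matrices -------------------------------------------------------
    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (metabolites x reactions)."""
        midx = self.metabolite_index()
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met_id, coef in rxn.stoichiometry.items():
                S[midx[met_id], j] = coef
        return S

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def objective_vector(self) -> np.ndarray:
        if self.objective is None:
            raise ModelValidationError(f"model {self.id} has no objective")
        rxn_id, _ = self.objective
        c = np.zeros(len(self.reactions))
        c[self.reaction_index()[rxn_id]] = 1.0
        return c

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        """Check structural invariants; raise ModelValidationError on failure."""
        seen: set[str] = set()
        for m in self.metabolites:
            if m.id in seen:
                raise ModelValidationError(f"duplicate metabolite id {m.id!r}")
            seen.add(m.id)
        seen = set()
        met_ids = {m.id for m in self.metabolites}
        for r in self.reactions:
            if r.id in seen:
                raise ModelValidationError(f"duplicate reaction id {r.id!r}")
            seen.add(r.id)
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(f"reaction {r.id}: inverted bounds")
            unknown = set(r.stoichiometry) - met_ids
            if unknown:
                raise ModelValidationError(
                    f"reaction {r.id}: unknown metabolites {sorted(unknown)}"
                )
            if r.kind in ("exchange", "demand") and len(r.stoichiometry) != 1:
                raise ModelValidationError(
                    f"{r.kind} reaction {r.id} must touch exactly one metabolite, "
                    f"touches {len(r.stoichiometry)}"
                )
        if self.objective is not None:
            rxn_id, direction = self.objective
            if rxn_id not in {r.id for r in self.reactions}:
                raise ModelValidationError(f"objective reaction {rxn_id!r} not in model")
            if direction not in ("max", "min"):
                raise ModelValidationError(f"objective direction {direction!r} invalid")


# ---------------------------------------------------------------------------
# summaries


@dataclass
class ModelSummary:
    """Unique-content counts with cell-specific duplicates collapsed by template id."""

    n_unique_reactions: int
    n_unique_metabolites: int
    n_genes: int
    n_vegetative_reactions: int
    n_heterocyst_reactions: int
    n_shared_reactions: int
    warnings: list[str] = field(default_factory=list)


def count_unique(model: MetabolicModel) -> ModelSummary:
    """Summarise model content by template id.

    Cell-specific reaction copies (``__vc`` / ``__hc``) collapse onto their
    template id; ``shared`` counts templates present in both super-compartments.
    Unsuffixed reaction ids are counted once, with a warning record, and do not
    enter either per-cell count.
    """
    templates: set[str] = set()
    per_cell: dict[str, set[str]] = {"vc": set(), "hc": set()}
    notes: list[str] = []
    for r in model.reactions:
        template, cell = split_cell_suffix(r.id)
        templates.add(template)
        if cell is None:
            notes.append(f"reaction {r.id!r} has no cell suffix; counted once")
        else:
            per_cell[cell].add(template)
    met_templates = {split_cell_suffix(m.id)[0] for m in model.metabolites}
    genes: set[str] = set()
    for r in model.reactions:
        genes |= r.genes()
    return ModelSummary(
        n_unique_reactions=len(templates),
        n_unique_metabolites=len(met_templates),
        n_genes=len(genes),
        n_vegetative_reactions=len(per_cell["vc"]),
        n_heterocyst_reactions=len(per_cell["hc"]),
        n_shared_reactions=len(per_cell["vc"] & per_cell["hc"]),
        warnings=notes,
    )


# ---------------------------------------------------------------------------
# mass / charge balance


@dataclass(frozen=True)
class Imbalance:
    reaction_id: str
    element: str  # element symbol, "charge", or "unknown"
    imbalance: float


#: reaction kinds exempted from balance checks (boundary or lumped drains)
_BALANCE_EXEMPT_KINDS = frozenset({"exchange", "demand", "biomass"})


def check_mass_charge_balance(
    model: MetabolicModel, tol: float = 1e-6
) -> list[Imbalance]:
    """List mass/charge imbalances of all checkable reactions.

    A reaction is listed iff the coefficient-weighted element counts or charges
    do not sum to zero.  Exchange, demand and biomass reactions are exempt.  A
    checked reaction touching a metabolite of unknown formula is reported with
    element ``"unknown"``; metabolites whose formula contains an R-group token
    exempt their reactions with a warning.  The check is independent of
    reaction order and idempotent.
    """
    out: list[Imbalance] = []
    mets = {m.id: m for m in model.metabolites}
    for r in model.reactions:
        if r.kind in _BALANCE_EXEMPT_KINDS:
            continue
        element_sum: dict[str, float] = {}
        charge_sum = 0.0
        unknown = False
        rgroup = False
        for met_id, coef in r.stoichiometry.items():
            met = mets[met_id]
            if met.formula is None:
                unknown = True
                continue
            if _RGROUP_TOKENS & set(met.formula):
                rgroup = True
                continue
            for element, n in met.formula.items():
                element_sum[element] = element_sum.get(element, 0.0) + coef * n
            charge_sum += coef * met.charge
        if rgroup:
            warnings.warn(
                f"reaction {r.id}: R-group/polymer metabolite, balance not checked",
                stacklevel=2,
            )
            continue
        if unknown:
            out.append(Imbalance(r.id, "unknown", float("nan")))
            continue
        for element in sorted(element_sum):
            if abs(element_sum[element]) > tol:
                out.append(Imbalance(r.id, element, element_sum[element]))
        if abs(charge_sum) > tol:
            out.append(Imbalance(r.id, "charge", charge_sum))
    return out


def make_exchange(met_id: str, lb: float = 0.0, ub: float = 1000.0, direction: str = "in", rxn_id: str | None = None) -> Reaction:
    """Convenience constructor for a single-metabolite exchange reaction.

    ``direction="in"`` produces the metabolite at positive flux (uptake as a
    dedicated forward reaction, the convention used throughout this package);
    ``"out"`` consumes it (secretion).
    """
    coef = 1.0 if direction == "in" else -1.0
    if rxn_id is None:
        rxn_id = f"EX_{met_id}_{direction}"
    return Reaction(
        id=rxn_id,
        stoichiometry={met_id: coef},
        lower_bound=lb,
        upper_bound=ub,
        kind="exchange",
    )
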