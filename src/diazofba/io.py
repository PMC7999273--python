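"""Model readers and writers: tabular TSV dialect, JSON dump, SBML L3+fbc.

The tabular dialect is UTF-8, tab-separated with a header row.  Equation
strings use ``->`` (irreversible) and ``<=>`` (reversible); reversible
reactions default to bounds (-1000, 1000), irreversible to (0, 1000).  A file
may carry two sections introduced by ``## reactions`` and ``## metabolites``;
the metabolite section (id, name, formula, charge, compartment,
super_compartment) is optional and preserves elemental data across round
trips.  SBML goes through cobrapy/libsbml; the JSON dump mirrors the typed
model one-to-one.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

from .model import (
    MetabolicModel,
    Metabolite,
    Reaction,
    format_formula,
    parse_formula,
    split_cell_suffix,
)

__all__ = ["load_model", "write_model", "to_cobra", "from_cobra", "infer_reaction_kind"]

_ARROW_RE = re.compile(r"\s*(<=>|->|=>|<->)\s*")
_TERM_RE = re.compile(r"^(?:(\d+\.?\d*(?:[eE][+-]?\d+)?)\s+)?(\S+)$")

REACTION_COLUMNS = [
    "id",
    "equation",
    "lower_bound",
    "upper_bound",
    "gpr",
    "subsystem",
    "ec",
    "kind",
    "name",
]
METABOLITE_COLUMNS = ["id", "name", "formula", "charge", "compartment", "super_compartment"]


class ParseError(ValueError):
    """Unreadable model file; message names the offending line/element."""


def parse_equation(equation: str) -> tuple[dict[str, float], bool]:
    """Parse ``"2 A__vc + B__vc -> C__vc"`` into (stoichiometry, reversible)."""
    m = _ARROW_RE.search(equation)
    if m is None:
        raise ParseError(f"no reaction arrow in equation {equation!r}")
    reversible = m.group(1) in ("<=>", "<->")
    lhs, rhs = equation[: m.start()], equation[m.end() :]
    stoich: dict[str, float] = {}

    def _consume(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            tm = _TERM_RE.match(term)
            if tm is None:
                raise ParseError(f"bad term {term!r} in equation {equation!r}")
            coef, met = tm.groups()
            value = sign * (float(coef) if coef else 1.0)
            stoich[met] = stoich.get(met, 0.0) + value

    _consume(lhs, -1.0)
    _consume(rhs, +1.0)
    # drop cancelled species
    stoich = {k: v for k, v in stoich.items() if v != 0.0}
    return stoich, reversible


def infer_reaction_kind(rxn_id: str, stoich: dict[str, float]) -> str:
    """Heuristic reaction kind from id and stoichiometry (used when the
    serialisation format cannot carry the kind, e.g. SBML)."""
    low = rxn_id.lower()
    if len(stoich) == 1:
        return "demand" if low.startswith("dm_") else "exchange"
    if "biomass" in low:
        return "biomass"
    templates = {split_cell_suffix(m)[0] for m in stoich}
    cells = {split_cell_suffix(m)[1] for m in stoich}
    if len(templates) <= 2 and {"vc", "hc"} <= cells:
        return "intercell-exchange"
    if len({t for t in templates}) < len(stoich):
        return "transport"
    return "enzymatic"


def _default_super_compartment(met_id: str) -> str:
    cell = split_cell_suffix(met_id)[1]
    return {"vc": "vegetative", "hc": "heterocyst"}.get(cell, "shared-external")


# ---------------------------------------------------------------------------
# tabular


def _load_tabular(path: Path) -> MetabolicModel:
    text = path.read_text(encoding="utf-8")
    sections: dict[str, list[str]] = {"reactions": []}
    current = "reactions"
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if line.startswith("## "):
            current = line[3:].strip().lower()
            sections.setdefault(current, [])
            continue
        if not line.strip() or line.startswith("#"):
            continue
        sections[current].append(f"{lineno}\t{line}")

    model = MetabolicModel(id=path.stem)
    met_rows = sections.get("metabolites", [])
    declared: dict[str, Metabolite] = {}
    if met_rows:
        header = met_rows[0].split("\t")[1:]
        for row in met_rows[1:]:
            parts = row.split("\t")
            lineno, fields = parts[0], dict(zip(header, parts[1:]))
            if not fields.get("id"):
                raise ParseError(f"{path}:{lineno}: metabolite row without id")
            formula_str = fields.get("formula", "")
            formula = {} if formula_str == "." else parse_formula(formula_str)
            declared[fields["id"]] = Metabolite(
                id=fields["id"],
                name=fields.get("name", ""),
                formula=formula,
                charge=int(fields.get("charge") or 0),
                compartment=fields.get("compartment", "c"),
                super_compartment=fields.get("super_compartment")
                or _default_super_compartment(fields["id"]),
            )

    rxn_rows = sections["reactions"]
    if not rxn_rows:
        raise ParseError(f"{path}: no reaction rows")
    header = rxn_rows[0].split("\t")[1:]
    if "id" not in header or "equation" not in header:
        raise ParseError(f"{path}: reaction header must contain 'id' and 'equation'")
    seen: set[str] = set()
    pending: list[Reaction] = []
    for row in rxn_rows[1:]:
        parts = row.split("\t")
        lineno, fields = parts[0], dict(zip(header, parts[1:]))
        rxn_id = fields.get("id", "")
        if not rxn_id:
            raise ParseError(f"{path}:{lineno}: reaction row without id")
        if rxn_id in seen:
            raise ParseError(f"{path}:{lineno}: duplicate reaction id {rxn_id!r}")
        seen.add(rxn_id)
        try:
            stoich, reversible = parse_equation(fields["equation"])
        except ParseError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        lb_default, ub_default = (-1000.0, 1000.0) if reversible else (0.0, 1000.0)
        lb = float(fields["lower_bound"]) if fields.get("lower_bound") else lb_default
        ub = float(fields["upper_bound"]) if fields.get("upper_bound") else ub_default
        kind = fields.get("kind") or infer_reaction_kind(rxn_id, stoich)
        pending.append(
            Reaction(
                id=rxn_id,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=fields.get("gpr", ""),
                subsystem=fields.get("subsystem", ""),
                ec=fields.get("ec", ""),
                name=fields.get("name", ""),
                kind=kind,
            )
        )

    met_ids: list[str] = []
    seen_mets: set[str] = set()
    for rxn in pending:
        for met_id in rxn.stoichiometry:
            if met_id not in seen_mets:
                seen_mets.add(met_id)
                met_ids.append(met_id)
    for met_id in met_ids:
        model.metabolites.append(
            declared.get(met_id)
            or Metabolite(
                id=met_id, super_compartment=_default_super_compartment(met_id)
            )
        )
    for rxn in pending:
        model.add_reaction(rxn)
    model.validate()
    return model


def _write_tabular(model: MetabolicModel, path: Path) -> None:
    lines = ["## reactions", "\t".join(REACTION_COLUMNS)]
    for r in model.reactions:
        lines.append(
            "\t".join(
                [
                    r.id,
                    r.equation(),
                    f"{r.lower_bound:.12g}",
                    f"{r.upper_bound:.12g}",
                    r.gpr,
                    r.subsystem,
                    r.ec,
                    r.kind,
                    r.name,
                ]
            )
        )
    lines += ["", "## metabolites", "\t".join(METABOLITE_COLUMNS)]
    for m in model.metabolites:
        formula = "." if m.formula == {} else format_formula(m.formula)
        lines.append(
            "\t".join(
                [m.id, m.name, formula, str(m.charge), m.compartment, m.super_compartment]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# json


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "formula": m.formula,
                "charge": m.charge,
                "compartment": m.compartment,
                "super_compartment": m.super_compartment,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr,
                "subsystem": r.subsystem,
                "ec": r.ec,
                "name": r.name,
                "kind": r.kind,
            }
            for r in model.reactions
        ],
        "objective": list(model.objective) if model.objective else None,
        "annotations": model.annotations,
    }


def _model_from_dict(data: dict) -> MetabolicModel:
    model = MetabolicModel(id=data.get("id", "model"), annotations=data.get("annotations", {}))
    for m in data["metabolites"]:
        model.metabolites.append(Metabolite(**m))
    seen: set[str] = set()
    for r in data["reactions"]:
        if r["id"] in seen:
            raise ParseError(f"duplicate reaction id {r['id']!r}")
        seen.add(r["id"])
        model.add_reaction(Reaction(**r))
    if data.get("objective"):
        model.objective = tuple(data["objective"])  # type: ignore[assignment]
    model.validate()
    return model


# ---------------------------------------------------------------------------
# sbml via cobrapy


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy Model (used for SBML I/O and as a solver cross-check)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {}
    for m in model.metabolites:
        met = cobra.Metabolite(
            m.id,
            name=m.name,
            formula=None if m.formula is None else format_formula(m.formula),
            charge=m.charge,
            compartment=m.compartment or "c",
        )
        mets[m.id] = met
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for r in model.reactions:
        rxn = cobra.Reaction(r.id, name=r.name, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        rxn.subsystem = r.subsystem
        rxns.append(rxn)
    cm.add_reactions(rxns)
    for r in model.reactions:
        rxn = cm.reactions.get_by_id(r.id)
        rxn.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
        if r.gpr:
            rxn.gene_reaction_rule = r.gpr
    if model.objective is not None:
        rxn_id, direction = model.objective
        cm.objective = cm.reactions.get_by_id(rxn_id).flux_expression
        cm.objective_direction = direction
    return cm


def from_cobra(cm) -> MetabolicModel:
    model = MetabolicModel(id=cm.id or "model")
    for m in cm.metabolites:
        formula = parse_formula(m.formula) if m.formula else None
        model.metabolites.append(
            Metabolite(
                id=m.id,
                name=m.name or "",
                formula=formula,
                charge=int(m.charge or 0),
                compartment=m.compartment or "c",
                super_compartment=_default_super_compartment(m.id),
            )
        )
    for r in cm.reactions:
        stoich = {m.id: coef for m, coef in r.metabolites.items()}
        model.add_reaction(
            Reaction(
                id=r.id,
                stoichiometry=stoich,
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gpr=r.gene_reaction_rule or "",
                subsystem=r.subsystem or "",
                name=r.name or "",
                kind=infer_reaction_kind(r.id, stoich),
            )
        )
    # objective: first reaction with a nonzero objective coefficient
    try:
        from cobra.util.solver import linear_reaction_coefficients

        coefs = linear_reaction_coefficients(cm)
    except Exception:
        coefs = {}
    if coefs:
        rxn = next(iter(coefs))
        model.objective = (rxn.id, cm.objective_direction or "max")
    model.validate()
    return model


def _load_sbml(path: Path) -> MetabolicModel:
    from cobra.io import read_sbml_model

    return from_cobra(read_sbml_model(str(path)))


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    from cobra.io import write_sbml_model

    write_sbml_model(to_cobra(model), str(path))


# ---------------------------------------------------------------------------
# public entry points

_FORMATS = {"sbml", "tabular", "json"}
_SUFFIX_FORMAT = {".xml": "sbml", ".sbml": "sbml", ".tsv": "tabular", ".txt": "tabular", ".json": "json"}


def _resolve_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in _FORMATS:
            raise ValueError(f"unknown format {format!r}; choose from {sorted(_FORMATS)}")
        return format
    fmt = _SUFFIX_FORMAT.get(path.suffix.lower())
    if fmt is None:
        raise ValueError(f"cannot infer format from suffix of {path}")
    return fmt


def load_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Load a model from SBML, the tabular TSV dialect, or the JSON dump."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _resolve_format(path, format)
    if fmt == "tabular":
        return _load_tabular(path)
    if fmt == "json":
        try:
            data = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON at line {exc.lineno}") from exc
        return _model_from_dict(data)
    return _load_sbml(path)


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = _resolve_format(path, format)
    if fmt == "tabular":
        _write_tabular(model, path)
    elif fmt == "json":
        data = _model_to_dict(model)
        path.write_text(json.dumps(data, indent=1, sort_keys=False), encoding="utf-8")
    else:
        _write_sbml(model, path)
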