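"""FBA, parsimonious FBA, FVA and derived linear-programming queries.

All problems are solved with the deterministic HiGHS simplex/IPM solvers
shipped with scipy (``scipy.optimize.linprog``), over the flux space

    S v = 0,   lb <= v <= ub.

Feasibility tolerance is 1e-9; reported values are meaningful to ~1e-6.
Thermodynamically infeasible loops are not removed (the models control them
with finite photon bounds); :func:`report_loops` flags them for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel

__all__ = [
    "FluxSolution",
    "FluxRanges",
    "InfeasibleError",
    "fba",
    "pfba",
    "fva",
    "min_uptake_for_growth",
    "metabolite_turnover",
    "report_loops",
]

FEASIBILITY_TOL = 1e-9
#: relative objective offset used when fixing the FBA optimum for FVA/pFBA,
#: dodging degenerate-optimum chatter
OPTIMUM_FIX_RTOL = 1e-9


class InfeasibleError(RuntimeError):
    """LP infeasible (or unbounded where boundedness is required)."""


@dataclass
class FluxSolution:
    """An LP solution: objective value, flux vector and solver status."""

    objective_value: float
    fluxes: dict[str, float]
    status: str  # optimal | infeasible | unbounded

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.Series(self.fluxes, name="flux").rename_axis("reaction").to_frame().to_csv(
            path, sep="\t"
        )


@dataclass
class FluxRanges:
    """Per-reaction [min, max] flux ranges plus the context they were computed in.

    ``context`` records the bound edits / fixed constraints that defined the
    flux space, so downstream consumers (MUST-set identification, OptForce)
    can rebuild the same LP.
    """

    ranges: dict[str, tuple[float, float]]
    context: dict = field(default_factory=dict)

    def __getitem__(self, rxn_id: str) -> tuple[float, float]:
        return self.ranges[rxn_id]

    def __contains__(self, rxn_id: str) -> bool:
        return rxn_id in self.ranges

    def minimum(self, rxn_id: str) -> float:
        return self.ranges[rxn_id][0]

    def maximum(self, rxn_id: str) -> float:
        return self.ranges[rxn_id][1]

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            [(r, lo, hi) for r, (lo, hi) in self.ranges.items()],
            columns=["reaction", "min", "max"],
        )
        df.to_csv(path, sep="\t", index=False)


_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _solve(c, S, lb, ub, sense: str = "min"):
    """Solve min/max c'v s.t. S v = 0, lb <= v <= ub with HiGHS."""
    sign = 1.0 if sense == "min" else -1.0
    res = linprog(
        sign * np.asarray(c, dtype=float),
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options={"presolve": True},
    )
    status = _STATUS.get(res.status, "numerical")
    value = sign * res.fun if res.status == 0 else float("nan")
    return status, value, (res.x if res.status == 0 else None)


def _arrays(model: MetabolicModel, bound_edits: dict[str, tuple[float, float]] | None = None):
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    if bound_edits:
        ridx = model.reaction_index()
        for rxn_id, (lo, hi) in bound_edits.items():
            j = ridx[rxn_id]
            lb[j], ub[j] = lo, hi
    return S, lb, ub


def fba(
    model: MetabolicModel,
    bound_edits: dict[str, tuple[float, float]] | None = None,
    objective: str | None = None,
) -> FluxSolution:
    """Flux balance analysis: optimise the model objective over the flux space.

    ``bound_edits`` (reaction id -> (lb, ub)) are applied for this solve only;
    ``objective`` overrides the model's objective reaction (maximised).
    """
    S, lb, ub = _arrays(model, bound_edits)
    if objective is not None:
        c = np.zeros(len(model.reactions))
        c[model.reaction_index()[objective]] = 1.0
        sense = "max"
    else:
        c = model.objective_vector()
        sense = model.objective[1] if model.objective else "max"
    status, value, x = _solve(c, S, lb, ub, sense)
    if status != "optimal":
        return FluxSolution(float("nan"), {}, status)
    fluxes = {r.id: float(x[j]) for j, r in enumerate(model.reactions)}
    return FluxSolution(float(value), fluxes, "optimal")


def _fix_objective_bounds(model, lb, ub, value: float):
    """Pin the objective reaction's flux to (1 - rtol) * value (equality)."""
    rxn_id = model.objective[0]
    j = model.reaction_index()[rxn_id]
    fixed = value - OPTIMUM_FIX_RTOL * abs(value)
    lb[j] = ub[j] = fixed
    return fixed


def pfba(
    model: MetabolicModel,
    bound_edits: dict[str, tuple[float, float]] | None = None,
) -> FluxSolution:
    """Parsimonious FBA: minimise total absolute flux at the FBA optimum.

    The objective is first fixed (within 1e-9 relative) at its FBA optimum;
    the sum of absolute fluxes is then minimised via splitting every flux into
    non-negative forward/reverse parts.  The returned ``objective_value`` is
    the FBA optimum; the flux vector is the parsimonious one.
    """
    base = fba(model, bound_edits)
    if not base.optimal:
        return base
    S, lb, ub = _arrays(model, bound_edits)
    _fix_objective_bounds(model, lb, ub, base.objective_value)
    n = len(model.reactions)
    # v = v+ - v-, v+ in [max(lb,0), max(ub,0)], v- in [max(-ub,0), max(-lb,0)]
    S2 = np.hstack([S, -S])
    lb2 = np.concatenate([np.maximum(lb, 0.0), np.maximum(-ub, 0.0)])
    ub2 = np.concatenate([np.maximum(ub, 0.0), np.maximum(-lb, 0.0)])
    c2 = np.ones(2 * n)
    status, _, x = _solve(c2, S2, lb2, ub2, "min")
    if status != "optimal":
        return FluxSolution(float("nan"), {}, status)
    v = x[:n] - x[n:]
    fluxes = {r.id: float(v[j]) for j, r in enumerate(model.reactions)}
    return FluxSolution(base.objective_value, fluxes, "optimal")


def fva(
    model: MetabolicModel,
    fixed: dict[str, tuple[float, float]] | None = None,
    targets: Sequence[str] | None = None,
    fix_objective: bool = False,
) -> FluxRanges:
    """Flux variability analysis over the (optionally constrained) flux space.

    ``fixed`` maps reaction ids to bound edits applied before solving (e.g.
    pinning growth to an experimental value).  With ``fix_objective=True`` the
    model objective is first optimised and pinned at its optimum.  Ranges are
    returned for ``targets`` (default: all reactions).
    """
    fixed = dict(fixed or {})
    S, lb, ub = _arrays(model, fixed)
    context: dict = {"bounds": dict(fixed)}
    if fix_objective:
        base = fba(model, fixed)
        if not base.optimal:
            raise InfeasibleError(
                f"cannot fix objective: FBA status {base.status} under edits "
                f"{sorted(fixed)}"
            )
        fixed_value = _fix_objective_bounds(model, lb, ub, base.objective_value)
        context["objective_fixed_at"] = fixed_value
    if targets is None:
        targets = [r.id for r in model.reactions]
    ridx = model.reaction_index()
    ranges: dict[str, tuple[float, float]] = {}
    for rxn_id in targets:
        j = ridx[rxn_id]
        c = np.zeros(len(model.reactions))
        c[j] = 1.0
        lo_status, lo, _ = _solve(c, S, lb, ub, "min")
        hi_status, hi, _ = _solve(c, S, lb, ub, "max")
        if lo_status == "infeasible" or hi_status == "infeasible":
            raise InfeasibleError(
                f"flux space infeasible under fixed constraints {sorted(fixed)}"
            )
        if lo_status == "unbounded":
            lo = -np.inf
        if hi_status == "unbounded":
            hi = np.inf
        ranges[rxn_id] = (float(lo), float(hi))
    return FluxRanges(ranges, context)


def min_uptake_for_growth(
    model: MetabolicModel, uptake: str, mu_target: float
) -> float:
    """Minimum uptake flux supporting growth >= ``mu_target`` (mmol/gDW/h).

    Solves ``min v_uptake`` subject to the model constraints plus a lower
    bound of ``mu_target`` on the objective (growth) reaction.
    """
    if model.objective is None:
        raise ValueError("model has no objective (growth) reaction")
    growth_id = model.objective[0]
    growth = model.get_reaction(growth_id)
    edits = {growth_id: (mu_target, growth.upper_bound)}
    S, lb, ub = _arrays(model, edits)
    c = np.zeros(len(model.reactions))
    c[model.reaction_index()[uptake]] = 1.0
    status, value, _ = _solve(c, S, lb, ub, "min")
    if status != "optimal":
        raise InfeasibleError(
            f"growth target {mu_target} infeasible at any {uptake} uptake"
        )
    return float(value)


def metabolite_turnover(
    model: MetabolicModel, solution: FluxSolution, metabolite_id: str
) -> float:
    """Total production rate of a metabolite in a flux solution (mmol/gDW/h).

    Sum over reactions of ``max(0, coefficient * flux)``; at steady state this
    equals total consumption.
    """
    if not solution.optimal:
        raise ValueError("turnover requires an optimal solution")
    if not model.has_metabolite(metabolite_id):
        raise KeyError(f"no metabolite {metabolite_id!r}")
    total = 0.0
    for r in model.reactions:
        coef = r.stoichiometry.get(metabolite_id)
        if coef:
            total += max(0.0, coef * solution.fluxes[r.id])
    return total


def report_loops(model: MetabolicModel, tol: float = 1e-6) -> list[str]:
    """Reactions that can carry flux with every boundary reaction closed.

    Such reactions participate in internal (thermodynamically questionable)
    cycles.  Reported for inspection only; results of FBA/FVA are not altered.
    """
    edits = {
        r.id: (0.0, 0.0)
        for r in model.reactions
        if r.kind in ("exchange", "demand", "biomass")
    }
    ranges = fva(model, fixed=edits)
    return [
        rxn_id
        for rxn_id, (lo, hi) in ranges.ranges.items()
        if (abs(lo) > tol or abs(hi) > tol) and rxn_id not in edits
    ]
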