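"""Heterocyst ATP/NAD(P)H source analysis: energy-scheme scenarios and metrics.

Nitrogen fixation demands ATP and reducing equivalents in a 16:4 = 4:1 ratio
(16 ATP and 8 electrons, i.e. 4 NAD(P)H, per N2).  The scenarios probe which
heterocyst pathways can supply that demand by selectively blocking routes:

* ``LETC_minus``    — heterocyst photon uptake zeroed (no light-driven chain);
* ``OPPP_LETC``     — glucose-6-phosphate and pentose-phosphate intermediates
  barred from glycolysis (G6P isomerase, phosphoketolase, GAPDH off), so
  NAD(P)H comes from the oxidative pentose phosphate pathway and ATP from
  cyclic photosystem I;
* ``GLY_TCA_LETC``  — G6P dehydrogenase and phosphoketolase off, so reducing
  power comes from glycolysis plus the TCA cycle; variant ``(1)`` additionally
  caps the 2-oxoglutarate export at the base variant's FVA minimum (complete
  oxidation), variant ``(2)`` caps the heterocyst CO2 evolution instead
  (incomplete oxidation with 2-oxoglutarate export).

Metrics per scheme: maximum growth rate, then FVA minima of heterocyst
sucrose uptake and heterocyst CO2 evolution with growth fixed at that
maximum.  For this analysis the heterocyst is assumed to have no
macromolecule turnover (its biomass floor is lifted); nitrogenase and
glutamine synthetase are then its only energy sinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import MetabolicModel
from .solver import FluxSolution, fba, fva, metabolite_turnover, pfba

__all__ = [
    "Scenario",
    "SchemeMetrics",
    "SCENARIOS",
    "SCENARIO_ORDER",
    "apply_scenario",
    "evaluate_scheme",
    "atp_nadph_ratio",
]


@dataclass
class Scenario:
    """A named set of bound edits implementing one heterocyst energy scheme.

    ``bound_edits`` entries are (role-or-reaction-id, lb, ub, required); roles
    resolve through the model's role-alias table (published ids such as
    ``rxn00558__hc`` work directly on models that use them).  ``derived_cap``
    optionally caps one reaction's upper bound at the FVA minimum of that
    reaction under a base scenario, computed at the base scenario's own
    growth optimum.
    """

    name: str
    bound_edits: list[tuple[str, float, float, bool]] = field(default_factory=list)
    derived_cap: tuple[str, str] | None = None  # (role to cap, base scenario name)
    zero_heterocyst_turnover: bool = True


def _blocked(*roles: str, required=("__required__",)) -> list[tuple[str, float, float, bool]]:
    return [(role, 0.0, 0.0, role in required) for role in roles]


SCENARIOS: dict[str, Scenario] = {
    "default": Scenario(name="default"),
    "LETC_minus": Scenario(
        name="LETC_minus",
        bound_edits=[("photon_uptake__hc", 0.0, 0.0, True)],
    ),
    "OPPP_LETC": Scenario(
        name="OPPP_LETC",
        bound_edits=_blocked(
            "g6p_isomerase__hc",
            "phosphoketolase__hc",
            "phosphoketolase_2__hc",
            "gapdh__hc",
            required=("g6p_isomerase__hc",),
        ),
    ),
    "GLY_TCA_LETC": Scenario(
        name="GLY_TCA_LETC",
        bound_edits=_blocked(
            "g6p_dehydrogenase__hc",
            "phosphoketolase__hc",
            "phosphoketolase_2__hc",
            required=("g6p_dehydrogenase__hc",),
        ),
    ),
    "GLY_TCA_LETC_1": Scenario(
        name="GLY_TCA_LETC_1",
        bound_edits=_blocked(
            "g6p_dehydrogenase__hc",
            "phosphoketolase__hc",
            "phosphoketolase_2__hc",
            required=("g6p_dehydrogenase__hc",),
        ),
        derived_cap=("akg_intercell", "GLY_TCA_LETC"),
    ),
    "GLY_TCA_LETC_2": Scenario(
        name="GLY_TCA_LETC_2",
        bound_edits=_blocked(
            "g6p_dehydrogenase__hc",
            "phosphoketolase__hc",
            "phosphoketolase_2__hc",
            required=("g6p_dehydrogenase__hc",),
        ),
        derived_cap=("co2_evolution__hc", "GLY_TCA_LETC"),
    ),
}

SCENARIO_ORDER = [
    "default",
    "LETC_minus",
    "OPPP_LETC",
    "GLY_TCA_LETC",
    "GLY_TCA_LETC_1",
    "GLY_TCA_LETC_2",
]


@dataclass
class SchemeMetrics:
    """Growth and heterocyst-flux metrics of one energy scheme."""

    scenario: str
    max_growth: float
    min_sucrose_uptake_hc: float
    min_co2_evolution_hc: float
    atp_nadph_ratio: float | None = None
    feasible: bool = True


def _resolve_one(model: MetabolicModel, role: str, required: bool) -> str | None:
    ids = model.resolve_role(role, required=required)
    return ids[0] if ids else None


def apply_scenario(model: MetabolicModel, scenario: Scenario) -> MetabolicModel:
    """Return a copy of the model with a scenario's bound edits applied.

    The default scenario returns an unmodified copy.  Derived caps (scheme
    variants) are resolved by evaluating the base scenario first.  With
    ``zero_heterocyst_turnover`` the heterocyst biomass lower bound is lifted
    to zero for the copy.
    """
    out = model.copy()
    for role, lo, hi, required in scenario.bound_edits:
        rid = _resolve_one(out, role, required)
        if rid is None:
            continue
        out.set_bounds(rid, lower=lo, upper=hi)
    if scenario.zero_heterocyst_turnover:
        hc_biomass = _resolve_one(out, "biomass__hc", required=True)
        out.set_bounds(hc_biomass, lower=0.0)
    if scenario.derived_cap is not None:
        role, base_name = scenario.derived_cap
        base = SCENARIOS.get(base_name)
        if base is None:
            raise ValueError(
                f"scenario {scenario.name}: unknown base scenario {base_name!r}"
            )
        base_model = apply_scenario(model, base)
        sol = fba(base_model)
        if not sol.optimal:
            raise ValueError(
                f"scenario {scenario.name}: base scenario {base_name!r} infeasible, "
                "cannot derive cap"
            )
        rid = _resolve_one(base_model, role, required=True)
        base_min = fva(base_model, targets=[rid], fix_objective=True).minimum(rid)
        out.set_bounds(_resolve_one(out, role, required=True), upper=max(base_min, 0.0))
    return out


def evaluate_scheme(
    model: MetabolicModel,
    scenario: Scenario,
    with_ratio: bool = False,
) -> SchemeMetrics:
    """Evaluate one energy scheme: max growth, then FVA minima at that growth.

    The minimum heterocyst sucrose uptake (the inter-cell sucrose exchange)
    and minimum heterocyst CO2 evolution are computed with the biomass flux
    fixed at the scheme's own optimum.  Optionally reports the heterocyst
    ATP : NAD(P)H turnover ratio of the scheme's parsimonious solution.
    """
    m = apply_scenario(model, scenario)
    sol = fba(m)
    if not sol.optimal:
        return SchemeMetrics(scenario.name, float("nan"), float("nan"), float("nan"),
                             feasible=False)
    sucrose = _resolve_one(m, "sucrose_intercell", required=True)
    co2_ev = _resolve_one(m, "co2_evolution__hc", required=True)
    ranges = fva(m, targets=[sucrose, co2_ev], fix_objective=True)
    ratio = None
    if with_ratio:
        psol = pfba(m)
        if psol.optimal:
            ratio = atp_nadph_ratio(m, psol, "heterocyst")
    return SchemeMetrics(
        scenario=scenario.name,
        max_growth=sol.objective_value,
        min_sucrose_uptake_hc=ranges.minimum(sucrose),
        min_co2_evolution_hc=ranges.minimum(co2_ev),
        atp_nadph_ratio=ratio,
    )


def atp_nadph_ratio(
    model: MetabolicModel, solution: FluxSolution, compartment: str = "heterocyst"
) -> float | None:
    """ATP : NAD(P)H turnover ratio within one super-compartment.

    Turnovers come from :func:`metabolite_turnover` on the compartment's ATP
    and joint NADH+NADPH pools (role aliases ``atp__hc``/``nadph__hc``/
    ``nadh__hc`` or the vegetative equivalents).  NADH and NADPH are counted
    jointly.  Returns ``None`` when the NAD(P)H turnover is zero (undefined).
    """
    cell = {"heterocyst": "hc", "vegetative": "vc"}[compartment]
    atp_ids = model.resolve_role(f"atp__{cell}", required=True)
    nad_ids = model.resolve_role(f"nadph__{cell}", required=True) + model.resolve_role(
        f"nadh__{cell}", required=False
    )
    atp = sum(metabolite_turnover(model, solution, i) for i in atp_ids)
    nad = sum(metabolite_turnover(model, solution, i) for i in nad_ids)
    if nad <= 0:
        return None
    return atp / nad
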