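"""OptForce strain design: flux-space comparison, MUST sets, FORCE sets.

The procedure contrasts the wild-type flux space (the model constrained by
measured 13C-MFA flux ranges on central carbon) with an overproduction flux
space (product secretion forced to >= 90 % of its theoretical yield, biomass
>= 10 % of its maximum).  Reactions whose flux ranges separate strictly must
change -- up (MUST^U), down (MUST^L) or off (MUST^X) -- for the network to
overproduce; pairwise sets (MUST^UU/LL/UL/LU) apply the same rule to flux
sums and differences.  A bi-level program then picks at most ``k`` of these
candidate interventions maximising the *guaranteed* (worst-case) product
flux; it is collapsed to a single-level MILP through LP duality and
alternative FORCE sets are enumerated with integer cuts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import LinearConstraint, linprog, milp
from scipy.optimize import Bounds as OptBounds

from .model import MetabolicModel, Metabolite, Reaction
from .solver import FluxRanges, InfeasibleError, fba, fva

__all__ = [
    "PathwaySpec",
    "MustSets",
    "Intervention",
    "InterventionStrategy",
    "add_production_pathway",
    "wild_type_flux_space",
    "overproduction_flux_space",
    "identify_must_single",
    "identify_must_pairs",
    "filter_must_sets",
    "find_growth_coupled",
    "find_essential",
    "solve_force_set",
    "fold_changes",
]

EPS_SEPARATION = 1e-6


# ---------------------------------------------------------------------------
# production pathways


@dataclass
class PathwaySpec:
    """A heterologous production pathway added to the vegetative compartment.

    Reactions and metabolites are given in template (unsuffixed) ids; native
    precursors are referenced by their template ids and must already exist in
    the vegetative compartment.
    """

    name: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    product_metabolite: str
    product_exchange: str
    precursors: tuple[str, ...] = ()


def add_production_pathway(model: MetabolicModel, spec: PathwaySpec) -> MetabolicModel:
    """Append a production pathway plus product exchange to a two-cell model.

    Pathway species and reactions are instantiated in the vegetative
    compartment (``__vc`` suffix); the product secretion reaction keeps the
    spec's exchange id.  Raises if a native precursor is missing.
    """
    out = model.copy()
    missing = [p for p in spec.precursors if not out.has_metabolite(f"{p}__vc")]
    if missing:
        raise KeyError(
            f"pathway {spec.name}: precursors missing in vegetative compartment: "
            f"{missing}"
        )

    def _vc(met_id: str) -> str:
        return f"{met_id}__vc" if out.has_metabolite(f"{met_id}__vc") or any(
            m.id == met_id for m in spec.metabolites
        ) else met_id

    for met in spec.metabolites:
        out.add_metabolite(
            Metabolite(
                id=f"{met.id}__vc",
                name=met.name,
                formula=None if met.formula is None else dict(met.formula),
                charge=met.charge,
                compartment=met.compartment,
                super_compartment="vegetative",
            )
        )
    for rxn in spec.reactions:
        out.add_reaction(
            Reaction(
                id=f"{rxn.id}__vc",
                stoichiometry={_vc(m): c for m, c in rxn.stoichiometry.items()},
                lower_bound=rxn.lower_bound,
                upper_bound=rxn.upper_bound,
                name=rxn.name,
                subsystem=rxn.subsystem or "production pathway",
                kind="enzymatic",
            )
        )
    out.add_reaction(
        Reaction(
            id=spec.product_exchange,
            stoichiometry={f"{spec.product_metabolite}__vc": -1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
            kind="exchange",
            name=f"{spec.name} product secretion",
        )
    )
    out.roles[f"product_exchange__{spec.name}"] = spec.product_exchange
    out.validate()
    return out


# ---------------------------------------------------------------------------
# flux spaces


def wild_type_flux_space(model: MetabolicModel, mfa_ranges: FluxRanges) -> FluxRanges:
    """Wild-type flux ranges: MFA ranges imposed as bounds, then whole-model FVA.

    Measured ranges map directly onto vegetative-cell reactions; the remaining
    reactions (including the heterocyst) are constrained only through the
    network, as FVA propagates the measurements.
    """
    unknown = [r for r in mfa_ranges.ranges if not model.has_reaction(r)]
    if unknown:
        raise KeyError(f"MFA ranges reference unknown reactions: {unknown}")
    edits = dict(mfa_ranges.ranges)
    try:
        ranges = fva(model, fixed=edits)
    except InfeasibleError as exc:
        conflict = _locate_infeasible_range(model, edits)
        raise InfeasibleError(
            f"MFA ranges infeasible with model; first conflicting reaction: "
            f"{conflict}"
        ) from exc
    ranges.context = {"bounds": edits, "space": "wild_type"}
    return ranges


def _locate_infeasible_range(model, edits):
    applied: dict[str, tuple[float, float]] = {}
    for rxn_id, rng in edits.items():
        applied[rxn_id] = rng
        sol = fba(model, bound_edits=applied)
        if not sol.optimal:
            return rxn_id
    return "unknown"


def overproduction_flux_space(
    model: MetabolicModel,
    product: str,
    yield_frac: float = 0.9,
    biomass_frac: float = 0.1,
) -> FluxRanges:
    """Overproduction flux ranges for a product exchange reaction.

    The theoretical yield is the maximum product flux under the model's own
    uptake bounds with the growth objective left free (lower bound 0); the
    space is then the model plus ``product >= yield_frac * yield`` and
    ``biomass >= biomass_frac * max growth``, characterised by FVA.
    """
    if model.objective is None:
        raise ValueError("model needs a biomass objective")
    biomass_id = model.objective[0]
    free_biomass = {biomass_id: (0.0, model.get_reaction(biomass_id).upper_bound)}
    yield_sol = fba(model, bound_edits=free_biomass, objective=product)
    if not yield_sol.optimal or yield_sol.objective_value <= 0:
        raise InfeasibleError(f"no positive theoretical yield for {product}")
    theoretical = yield_sol.objective_value
    mu_max = fba(model).objective_value
    edits = {
        product: (yield_frac * theoretical, model.get_reaction(product).upper_bound),
        biomass_id: (biomass_frac * mu_max, model.get_reaction(biomass_id).upper_bound),
    }
    try:
        ranges = fva(model, fixed=edits)
    except InfeasibleError as exc:
        raise InfeasibleError(
            f"product floor {yield_frac * theoretical:.6g} and biomass floor "
            f"{biomass_frac * mu_max:.6g} jointly infeasible"
        ) from exc
    ranges.context = {
        "bounds": edits,
        "space": "overproduction",
        "theoretical_yield": theoretical,
        "max_growth": mu_max,
        "product": product,
    }
    return ranges


# ---------------------------------------------------------------------------
# MUST sets


@dataclass
class MustSets:
    """Single and pairwise MUST sets with the flux spaces they came from."""

    must_u: set[str] = field(default_factory=set)
    must_l: set[str] = field(default_factory=set)
    must_x: set[str] = field(default_factory=set)
    must_uu: set[tuple[str, str]] = field(default_factory=set)
    must_ll: set[tuple[str, str]] = field(default_factory=set)
    must_ul: set[tuple[str, str]] = field(default_factory=set)
    must_lu: set[tuple[str, str]] = field(default_factory=set)
    provenance: tuple[FluxRanges, FluxRanges] | None = None  # (wild-type, over)

    def single_counts(self) -> tuple[int, int, int]:
        return len(self.must_u), len(self.must_l), len(self.must_x)


def identify_must_single(wt: FluxRanges, over: FluxRanges) -> MustSets:
    """Classify reactions whose single-flux ranges separate strictly.

    MUST^U: overproduction minimum above the wild-type maximum; MUST^L:
    overproduction maximum below the wild-type minimum; MUST^X: the
    overproduction range is {0} while the wild-type range excludes zero.
    """
    if set(wt.ranges) != set(over.ranges):
        raise ValueError("wild-type and overproduction ranges cover different reactions")
    out = MustSets(provenance=(wt, over))
    e = EPS_SEPARATION
    for rxn_id, (wlo, whi) in wt.ranges.items():
        olo, ohi = over.ranges[rxn_id]
        if abs(olo) <= e and abs(ohi) <= e and (wlo > e or whi < -e):
            out.must_x.add(rxn_id)  # checked first: the more specific class
        elif olo > whi + e:
            out.must_u.add(rxn_id)
        elif ohi < wlo - e:
            out.must_l.add(rxn_id)
    return out


def default_pair_universe(model: MetabolicModel, candidates: set[str]) -> list[tuple[str, str]]:
    """Reaction pairs sharing at least one metabolite (local pairwise scan)."""
    by_met: dict[str, set[str]] = {}
    for r in model.reactions:
        if r.id not in candidates:
            continue
        for met in r.stoichiometry:
            by_met.setdefault(met, set()).add(r.id)
    pairs: set[tuple[str, str]] = set()
    for members in by_met.values():
        for a, b in itertools.combinations(sorted(members), 2):
            pairs.add((a, b))
    return sorted(pairs)


def identify_must_pairs(
    model: MetabolicModel,
    wt: FluxRanges,
    over: FluxRanges,
    pairs: list[tuple[str, str]] | None = None,
    must: MustSets | None = None,
) -> MustSets:
    """Classify pairwise MUST sets from flux sums and differences.

    For each candidate pair, the ranges of ``v_i + v_j`` and ``v_i - v_j`` are
    computed by FVA in both spaces and compared with the same strict-separation
    rule as single reactions: a sum that must rise puts the pair in MUST^UU, a
    sum that must fall in MUST^LL; a difference that must rise/fall yields
    MUST^UL / MUST^LU.  Pairs already resolved at the single-reaction level
    are skipped.  The default pair universe is metabolite-sharing enzymatic
    pairs (a full quadratic scan is possible by passing ``pairs`` explicitly).
    """
    out = must if must is not None else identify_must_single(wt, over)
    resolved = out.must_u | out.must_l | out.must_x
    if pairs is None:
        candidates = {
            r.id
            for r in model.reactions
            if r.kind == "enzymatic" and r.id not in resolved
        }
        pairs = default_pair_universe(model, candidates)
    if not pairs:
        import warnings

        warnings.warn("empty pairwise MUST candidate universe", stacklevel=2)
        return out
    e = EPS_SEPARATION
    for a, b in pairs:
        for combo, (uu, ll) in (
            ("sum", (out.must_uu, out.must_ll)),
            ("diff", (out.must_ul, out.must_lu)),
        ):
            sign = 1.0 if combo == "sum" else -1.0
            wlo, whi = _combination_range(model, wt.context.get("bounds", {}), a, b, sign)
            olo, ohi = _combination_range(model, over.context.get("bounds", {}), a, b, sign)
            if olo > whi + e:
                uu.add((a, b))
            elif ohi < wlo - e:
                ll.add((a, b))
    return out


def _combination_range(model, bounds, a, b, sign_b):
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    ridx = model.reaction_index()
    for rxn_id, (lo, hi) in bounds.items():
        lb[ridx[rxn_id]], ub[ridx[rxn_id]] = lo, hi
    c = np.zeros(len(model.reactions))
    c[ridx[a]] = 1.0
    c[ridx[b]] += sign_b
    bnds = np.column_stack([lb, ub])
    lo_res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bnds, method="highs")
    hi_res = linprog(-c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bnds, method="highs")
    if lo_res.status != 0 or hi_res.status != 0:
        raise InfeasibleError(f"pairwise FVA failed for ({a}, {b})")
    return lo_res.fun, -hi_res.fun


# ---------------------------------------------------------------------------
# filtering


_EXCLUDED_KINDS = frozenset(
    {"transport", "exchange", "demand", "spontaneous", "intercell-exchange", "biomass"}
)


def _linear_chain_edges(model: MetabolicModel) -> dict[str, str]:
    """Upstream edges of linear pathways: chained reaction -> its predecessor.

    Two reactions are chained when a metabolite has them as its unique
    producer and unique consumer (structural full coupling).
    """
    producers: dict[str, list[str]] = {}
    consumers: dict[str, list[str]] = {}
    for r in model.reactions:
        for met, coef in r.stoichiometry.items():
            if coef > 0:
                producers.setdefault(met, []).append(r.id)
            elif coef < 0:
                consumers.setdefault(met, []).append(r.id)
    upstream: dict[str, str] = {}
    for met in producers:
        if len(producers.get(met, [])) == 1 and len(consumers.get(met, [])) == 1:
            pred, succ = producers[met][0], consumers[met][0]
            if pred != succ:
                upstream[succ] = pred
    return upstream


def filter_must_sets(
    must: MustSets,
    model: MetabolicModel,
    essential: set[str] = frozenset(),
    growth_coupled: set[str] = frozenset(),
    low_flux_eps: float = 1e-3,
) -> MustSets:
    """Apply the published pruning rules to raw MUST sets.

    In order: (1) transport, exchange, demand, spontaneous and lumped/boundary
    reactions are removed from all sets; (2) reactions inside a linear pathway
    collapse onto the pathway's first reaction (all members are flux-coupled,
    one perturbation suffices); (3) growth-coupled reactions leave MUST^L
    (downregulating them would trade growth for product); (4) essential
    reactions and reactions of very low wild-type flux leave MUST^X.  Filters
    only ever shrink sets.
    """
    kinds = {r.id: r.kind for r in model.reactions}
    keep = lambda rid: kinds.get(rid, "enzymatic") not in _EXCLUDED_KINDS

    upstream = _linear_chain_edges(model)

    def _collapse(members: set[str]) -> set[str]:
        # within the set, walk each member up its linear chain as long as the
        # predecessor is also a set member; keep only the chain entries
        out: set[str] = set()
        for rid in members:
            cur, seen = rid, {rid}
            while True:
                pred = upstream.get(cur)
                if pred is None or pred not in members or pred in seen:
                    break
                seen.add(pred)
                cur = pred
            out.add(cur)
        return out

    filtered = MustSets(provenance=must.provenance)
    filtered.must_u = _collapse({r for r in must.must_u if keep(r)})
    filtered.must_l = _collapse({r for r in must.must_l if keep(r)}) - set(growth_coupled)
    wt = must.provenance[0] if must.provenance else None
    low_flux = set()
    if wt is not None:
        for rid in must.must_x:
            lo, hi = wt.ranges.get(rid, (0.0, 0.0))
            if max(abs(lo), abs(hi)) < low_flux_eps:
                low_flux.add(rid)
    filtered.must_x = (
        _collapse({r for r in must.must_x if keep(r)}) - set(essential) - low_flux
    )
    pair_keep = lambda pair: keep(pair[0]) and keep(pair[1])
    filtered.must_uu = {p for p in must.must_uu if pair_keep(p)}
    filtered.must_ll = {p for p in must.must_ll if pair_keep(p)}
    filtered.must_ul = {p for p in must.must_ul if pair_keep(p)}
    filtered.must_lu = {p for p in must.must_lu if pair_keep(p)}
    return filtered


def find_growth_coupled(model: MetabolicModel, tol: float = 1e-6) -> set[str]:
    """Reactions forced to carry flux at the growth optimum (FVA min > 0)."""
    ranges = fva(model, fix_objective=True)
    return {
        rid for rid, (lo, hi) in ranges.ranges.items() if lo > tol or hi < -tol
    }


def find_essential(
    model: MetabolicModel, candidates: list[str] | None = None, tol: float = 1e-6
) -> set[str]:
    """Reactions whose knockout abolishes growth."""
    if candidates is None:
        candidates = [r.id for r in model.reactions if r.kind == "enzymatic"]
    essential = set()
    for rid in candidates:
        sol = fba(model, bound_edits={rid: (0.0, 0.0)})
        if not sol.optimal or sol.objective_value < tol:
            essential.add(rid)
    return essential


# ---------------------------------------------------------------------------
# FORCE sets (bi-level MILP)


@dataclass(frozen=True)
class Intervention:
    reaction_id: str
    kind: str  # up | down | knockout
    level: float  # imposed lb (up) / ub (down); 0 for knockout


@dataclass
class InterventionStrategy:
    """A FORCE set: chosen interventions and the product flux they guarantee."""

    k: int
    members: list[Intervention]
    guaranteed_product_flux: float
    fold_changes: dict[str, str] = field(default_factory=dict)

    def member_ids(self) -> frozenset[str]:
        return frozenset(m.reaction_id for m in self.members)


def _candidate_interventions(
    must: MustSets, extra_knockouts: set[str]
) -> list[Intervention]:
    if must.provenance is None:
        raise ValueError("MustSets must carry provenance (wild-type, over) ranges")
    _, over = must.provenance
    cands = []
    for rid in sorted(must.must_u):
        cands.append(Intervention(rid, "up", over.minimum(rid)))
    for rid in sorted(must.must_l):
        cands.append(Intervention(rid, "down", over.maximum(rid)))
    for rid in sorted(must.must_x | set(extra_knockouts)):
        cands.append(Intervention(rid, "knockout", 0.0))
    return cands


def _intervened_bounds(
    model: MetabolicModel,
    wt_bounds: dict[str, tuple[float, float]],
    chosen: list[Intervention],
) -> tuple[np.ndarray, np.ndarray]:
    """Inner flux space: wild-type (MFA) bounds with interventions imposed.

    An intervention replaces its reaction's bounds: up -> [level, model ub],
    down -> [model lb, level], knockout -> [0, 0]; all other reactions keep
    the MFA-constrained wild-type bounds.
    """
    lb, ub = model.bounds_arrays()
    ridx = model.reaction_index()
    for rxn_id, (lo, hi) in wt_bounds.items():
        lb[ridx[rxn_id]], ub[ridx[rxn_id]] = lo, hi
    model_lb, model_ub = model.bounds_arrays()
    for iv in chosen:
        j = ridx[iv.reaction_id]
        if iv.kind == "up":
            lb[j], ub[j] = iv.level, max(model_ub[j], iv.level)
        elif iv.kind == "down":
            lb[j], ub[j] = min(model_lb[j], iv.level), iv.level
        else:
            lb[j], ub[j] = 0.0, 0.0
    return lb, ub


def evaluate_intervention_set(
    model: MetabolicModel,
    wt_bounds: dict[str, tuple[float, float]],
    product: str,
    chosen: list[Intervention],
) -> float | None:
    """Worst-case (minimum) product flux under a chosen intervention set.

    Returns ``None`` when the intervened space is infeasible.
    """
    lb, ub = _intervened_bounds(model, wt_bounds, chosen)
    S = model.stoichiometric_matrix()
    c = np.zeros(len(model.reactions))
    c[model.reaction_index()[product]] = 1.0
    res = linprog(
        c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if res.status != 0:
        return None
    return float(res.fun)


def solve_force_set(
    model: MetabolicModel,
    wt_space: FluxRanges,
    must: MustSets,
    k: int,
    product: str | None = None,
    extra_knockouts: set[str] = frozenset(),
    n_strategies: int = 1,
    big_m: float = 1e4,
) -> list[InterventionStrategy]:
    """Find FORCE sets of at most ``k`` interventions maximising guaranteed flux.

    The bi-level program (outer: choose interventions; inner: nature minimises
    product flux over the intervened wild-type space) is collapsed to a single
    MILP by dualising the inner LP; binary-times-dual products are linearised
    with a big-M envelope.  The reported guaranteed flux is re-verified by
    solving the inner LP for the chosen binaries, so a too-small ``big_m``
    cannot silently inflate it.  Alternative strategies are enumerated by
    adding integer cuts over previously returned FORCE sets; results come
    back sorted by guaranteed flux (non-increasing).

    With ``k = 0`` the single returned "strategy" is the wild-type worst case.
    """
    if product is None:
        product = wt_space.context.get("product") or (
            must.provenance[1].context.get("product") if must.provenance else None
        )
    if product is None:
        raise ValueError("product exchange reaction must be given")
    wt_bounds = dict(wt_space.context.get("bounds", {}))
    candidates = _candidate_interventions(must, set(extra_knockouts))
    if k == 0 or not candidates:
        base = evaluate_intervention_set(model, wt_bounds, product, [])
        if base is None:
            return []
        return [InterventionStrategy(k=k, members=[], guaranteed_product_flux=base)]

    baseline = evaluate_intervention_set(model, wt_bounds, product, [])
    baseline = -np.inf if baseline is None else baseline
    cuts: list[frozenset[int]] = []
    strategies: list[InterventionStrategy] = []
    guard = 0
    while len(strategies) < n_strategies and guard < 50:
        guard += 1
        selection = _solve_dual_milp(model, wt_bounds, product, candidates, k, cuts, big_m)
        if selection is None:
            break
        chosen_idx, _milp_value = selection
        if not chosen_idx:
            break  # no remaining intervention beats doing nothing
        chosen = [candidates[i] for i in chosen_idx]
        verified = evaluate_intervention_set(model, wt_bounds, product, chosen)
        cuts.append(frozenset(chosen_idx))
        if verified is None:
            # intervention combination kills the inner space; exclude and retry
            continue
        if verified <= baseline + EPS_SEPARATION:
            break  # remaining strategies guarantee nothing beyond the wild type
        strategy = InterventionStrategy(
            k=k, members=chosen, guaranteed_product_flux=verified
        )
        strategy.fold_changes = fold_changes(strategy, wt_space)
        strategies.append(strategy)
    strategies.sort(key=lambda s: -s.guaranteed_product_flux)
    return strategies


def _solve_dual_milp(model, wt_bounds, product, candidates, k, cuts, big_m):
    """Single-level dual MILP: max over binaries of the inner LP's dual optimum."""
    S = model.stoichiometric_matrix()
    m, n = S.shape
    ridx = model.reaction_index()
    lb0, ub0 = model.bounds_arrays()
    for rxn_id, (lo, hi) in wt_bounds.items():
        lb0[ridx[rxn_id]], ub0[ridx[rxn_id]] = lo, hi
    model_lb, model_ub = model.bounds_arrays()

    n_iv = len(candidates)
    # per-candidate bound shifts when selected: L_j(y)=lb0_j + y*dlb, same for ub
    dlb = np.zeros(n_iv)
    dub = np.zeros(n_iv)
    iv_rxn = np.zeros(n_iv, dtype=int)
    for i, iv in enumerate(candidates):
        j = ridx[iv.reaction_id]
        iv_rxn[i] = j
        if iv.kind == "up":
            dlb[i] = iv.level - lb0[j]
            dub[i] = max(model_ub[j], iv.level) - ub0[j]
        elif iv.kind == "down":
            dlb[i] = min(model_lb[j], iv.level) - lb0[j]
            dub[i] = iv.level - ub0[j]
        else:
            dlb[i] = -lb0[j]
            dub[i] = -ub0[j]

    # variables: lam (m, free) | mu (n, >=0) | nu (n, >=0) | y (n_iv, binary)
    #            | zmu (n_iv) | znu (n_iv)   with z* = y * dual at the
    # intervened reaction (big-M linearised products)
    off_lam, off_mu, off_nu = 0, m, m + n
    off_y, off_zmu, off_znu = m + 2 * n, m + 2 * n + n_iv, m + 2 * n + 2 * n_iv
    n_var = m + 2 * n + 3 * n_iv

    # objective (maximise): sum_j lb0_j mu_j - ub0_j nu_j
    #                       + sum_i dlb_i zmu_i - dub_i znu_i
    c = np.zeros(n_var)
    c[off_mu : off_mu + n] = lb0
    c[off_nu : off_nu + n] = -ub0
    c[off_zmu : off_zmu + n_iv] = dlb
    c[off_znu : off_znu + n_iv] = -dub

    constraints = []
    # dual feasibility: S' lam + mu - nu = e_product
    A = np.zeros((n, n_var))
    A[:, :m] = S.T
    A[np.arange(n), off_mu + np.arange(n)] = 1.0
    A[np.arange(n), off_nu + np.arange(n)] = -1.0
    rhs = np.zeros(n)
    rhs[ridx[product]] = 1.0
    constraints.append(LinearConstraint(A, rhs, rhs))

    # budget
    row = np.zeros(n_var)
    row[off_y : off_y + n_iv] = 1.0
    constraints.append(LinearConstraint(row, -np.inf, k))

    # big-M envelopes: z <= M y ; z <= dual ; z >= dual - M (1 - y) ; z >= 0
    for i in range(n_iv):
        j = iv_rxn[i]
        for z_off, d_off in ((off_zmu, off_mu), (off_znu, off_nu)):
            r1 = np.zeros(n_var)
            r1[z_off + i] = 1.0
            r1[off_y + i] = -big_m
            constraints.append(LinearConstraint(r1, -np.inf, 0.0))
            r2 = np.zeros(n_var)
            r2[z_off + i] = 1.0
            r2[d_off + j] = -1.0
            constraints.append(LinearConstraint(r2, -np.inf, 0.0))
            r3 = np.zeros(n_var)
            r3[z_off + i] = 1.0
            r3[d_off + j] = -1.0
            r3[off_y + i] = big_m
            constraints.append(LinearConstraint(r3, -np.inf, big_m))

    # integer cuts excluding previously returned FORCE sets
    for cut in cuts:
        row = np.zeros(n_var)
        for i in range(n_iv):
            row[off_y + i] = 1.0 if i in cut else -1.0
        constraints.append(LinearConstraint(row, -np.inf, len(cut) - 1))

    lower = np.full(n_var, -np.inf)
    upper = np.full(n_var, np.inf)
    lower[off_mu : off_mu + n] = 0.0
    upper[off_mu : off_mu + n] = big_m
    lower[off_nu : off_nu + n] = 0.0
    upper[off_nu : off_nu + n] = big_m
    lower[off_y : off_y + 3 * n_iv] = 0.0
    upper[off_y : off_y + n_iv] = 1.0
    upper[off_zmu : off_zmu + 2 * n_iv] = big_m
    integrality = np.zeros(n_var)
    integrality[off_y : off_y + n_iv] = 1.0

    res = milp(
        -c,
        constraints=constraints,
        bounds=OptBounds(lower, upper),
        integrality=integrality,
    )
    if res.status != 0 or res.x is None:
        return None
    y = res.x[off_y : off_y + n_iv]
    chosen = tuple(i for i in range(n_iv) if y[i] > 0.5)
    return chosen, -res.fun


def fold_changes(strategy: InterventionStrategy, wt_space: FluxRanges) -> dict[str, str]:
    """Fold changes of a FORCE set relative to the wild-type flux ranges.

    Overexpression: imposed lower bound / wild-type maximum; downregulation:
    wild-type minimum / imposed upper bound; knockouts are reported as
    deletions.  Division by zero yields the infinity symbol rather than an
    exception.
    """
    out: dict[str, str] = {}
    for iv in strategy.members:
        if iv.kind == "knockout":
            out[iv.reaction_id] = "Δ"
            continue
        if iv.kind == "up":
            denom = wt_space.maximum(iv.reaction_id)
            ratio = iv.level / denom if denom != 0 else float("inf")
            arrow = "↑"
        else:
            num = wt_space.minimum(iv.reaction_id)
            ratio = num / iv.level if iv.level != 0 else float("inf")
            arrow = "↓"
        out[iv.reaction_id] = ("∞" if np.isinf(ratio) else f"{ratio:.3g}") + arrow
    return out
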