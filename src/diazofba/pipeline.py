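"""End-to-end commands behind the command-line interface.

Each ``cmd_*`` function loads/constructs its inputs, runs the corresponding
analysis and writes TSV/JSON outputs into a run directory, returning the
paths it wrote.  Everything is deterministic: identical inputs give
byte-identical outputs (timestamps only ever appear in the log).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .energetics import SCENARIO_ORDER, SCENARIOS, evaluate_scheme
from .io import load_model, write_model
from .model import MetabolicModel, count_unique
from .optforce import (
    add_production_pathway,
    filter_must_sets,
    find_growth_coupled,
    identify_must_single,
    overproduction_flux_space,
    solve_force_set,
    wild_type_flux_space,
)
from .solver import FluxRanges, fba, fva
from .toy import make_mfa_fixture, make_pathway_fixtures, make_toy_two_cell
from .twocell import TwoCellConfig, apply_diazotrophic_constraints, build_two_cell

log = logging.getLogger("diazofba")

#: Table-1 style default watchlist for the packaged toy network (role/ids)
DEFAULT_WATCHLIST = [
    ("RuBisCo (vegetative)", "rubisco_calvin__vc"),
    ("Photosystem II (vegetative)", "psii_letc__vc"),
    ("Sucrose uptake by heterocyst", "sucrose_vc_hc_exch"),
    ("Nitrogenase", "nitrogenase__hc"),
    ("Cyclic PSI in heterocyst", "cef_psi__hc"),
    ("Glutamate/glutamine exchange flux", "glu_vc_hc_exch"),
]


@dataclass
class RunConfig:
    """Configuration of a pipeline run (mirrors the YAML config file)."""

    model_path: str | None = None  # None -> packaged toy network
    out_dir: str = "results"
    growth_rate: float = 0.1824
    watchlist: list[tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_WATCHLIST))
    scenarios: list[str] = field(default_factory=lambda: list(SCENARIO_ORDER))
    product: str = "five_aminovalerate"  # pathway name
    k: int = 1
    yield_frac: float = 0.9
    biomass_frac: float = 0.1
    mfa_path: str | None = None  # None -> packaged synthetic MFA fixture
    extra_knockouts: list[str] = field(default_factory=list)
    n_strategies: int = 3
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise KeyError(f"unknown config key {key!r}")
            setattr(cfg, key, value)
        cfg.watchlist = [tuple(w) for w in cfg.watchlist]
        return cfg


def _load(config: RunConfig) -> MetabolicModel:
    if config.model_path:
        model = load_model(config.model_path)
        log.info("loaded model %s (%d reactions)", model.id, len(model.reactions))
        return model
    model, _ = make_toy_two_cell()
    log.info("using packaged toy two-cell network (%d reactions)", len(model.reactions))
    return model


def _out(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def load_mfa_table(path: str | Path) -> FluxRanges:
    """Read an MFA flux-range TSV (reaction, lower, upper)."""
    df = pd.read_csv(path, sep="\t")
    ranges = {
        str(row.iloc[0]): (float(row.iloc[1]), float(row.iloc[2]))
        for _, row in df.iterrows()
    }
    return FluxRanges(ranges, context={"source": str(path)})


def cmd_make_toy(config: RunConfig) -> list[Path]:
    """Write the toy network (tabular + SBML + JSON) and its manifest."""
    out = _out(config)
    model, manifest = make_toy_two_cell()
    paths = []
    for suffix in ("tsv", "json", "xml"):
        p = out / f"toy_two_cell.{suffix}"
        write_model(model, p)
        paths.append(p)
    p = out / "toy_manifest.json"
    p.write_text(
        json.dumps(
            {
                "counts": {
                    "template_reactions": manifest.template_reactions,
                    "two_cell_reactions": manifest.two_cell_reactions,
                    "two_cell_metabolites": manifest.two_cell_metabolites,
                    "vegetative_template_reactions": manifest.vegetative_template_reactions,
                    "heterocyst_template_reactions": manifest.heterocyst_template_reactions,
                    "shared_template_reactions": manifest.shared_template_reactions,
                },
                "reference_optima": manifest.reference_optima,
                "lumping_notes": manifest.lumping_notes,
            },
            indent=1,
        )
    )
    paths.append(p)
    mfa = make_mfa_fixture(model)
    p = out / "toy_mfa_ranges.tsv"
    mfa.to_tsv(p)
    paths.append(p)
    return paths


def cmd_build_two_cell(
    template_path: str, config: RunConfig, two_cell: TwoCellConfig
) -> Path:
    """Build a two-cell model from a single-cell template file and save it.

    When the passed config carries no deletions/exchanges, the canonical
    layout is derived from the template's role aliases (psii/rubisco/gogat
    deleted from the heterocyst, nitrogenase from the vegetative cell) and
    the standard four exchanged metabolites.
    """
    template = load_model(template_path)
    if not two_cell.intercell_exchanges:
        roles = template.annotations.get("roles", {})
        hc_del = tuple(
            roles[r] for r in ("psii", "rubisco", "gogat") if roles.get(r)
        )
        vc_del = (roles["nitrogenase"],) if roles.get("nitrogenase") else ()
        from diazofba.twocell import default_config

        two_cell = default_config(hc_del, vc_del)
    model = build_two_cell(template, two_cell)
    apply_diazotrophic_constraints(model, two_cell)
    out = _out(config) / f"{model.id}.json"
    write_model(model, out)
    summary = count_unique(model)
    log.info(
        "two-cell model: %d unique reactions, vc %d / hc %d / shared %d",
        summary.n_unique_reactions,
        summary.n_vegetative_reactions,
        summary.n_heterocyst_reactions,
        summary.n_shared_reactions,
    )
    return out


def cmd_simulate(config: RunConfig) -> dict[str, Path]:
    """FBA at maximum growth plus a Table-1 style watchlist of FVA minima.

    The watchlist minima are computed with growth fixed at ``growth_rate``
    (the experimental value), reproducing the minimum-flux-for-optimal-growth
    table.  Exits nonzero (raises) when the model is infeasible.
    """
    model = _load(config)
    out = _out(config)
    sol = fba(model)
    if not sol.optimal:
        raise RuntimeError(f"FBA not optimal: status {sol.status}")
    log.info("maximum growth rate %.6g 1/h", sol.objective_value)
    paths = {}
    p = out / "flux_solution.tsv"
    sol.to_tsv(p)
    paths["solution"] = p

    growth_id = model.objective[0]
    watch_ids = [rid for _, rid in config.watchlist if model.has_reaction(rid)]
    rows = []
    if watch_ids:
        ranges = fva(
            model,
            fixed={growth_id: (config.growth_rate, config.growth_rate)},
            targets=watch_ids,
        )
        for label, rid in config.watchlist:
            if rid in ranges:
                rows.append((label, rid, ranges.minimum(rid)))
                log.info("watchlist %-40s min flux %.6g", label, ranges.minimum(rid))
    df = pd.DataFrame(rows, columns=["reaction", "id", "min_flux_for_optimal_growth"])
    p = out / "watchlist_minima.tsv"
    df.to_csv(p, sep="\t", index=False)
    paths["watchlist"] = p
    return paths


def cmd_scenarios(config: RunConfig) -> Path:
    """Evaluate the heterocyst energy schemes and write the metrics table."""
    model = _load(config)
    out = _out(config)
    rows = []
    for name in config.scenarios:
        scenario = SCENARIOS.get(name)
        if scenario is None:
            rows.append((name, "skipped: unknown scenario", None, None, None))
            continue
        try:
            m = evaluate_scheme(model, scenario, with_ratio=True)
        except (KeyError, ValueError) as exc:
            log.warning("scenario %s skipped: %s", name, exc)
            rows.append((name, f"skipped: {exc}", None, None, None))
            continue
        status = "ok" if m.feasible else "infeasible"
        rows.append(
            (name, status, m.max_growth, m.min_sucrose_uptake_hc, m.min_co2_evolution_hc)
        )
        log.info(
            "scheme %-16s growth %.6g, min sucrose %.6g, min CO2 evolution %.6g",
            name, m.max_growth, m.min_sucrose_uptake_hc, m.min_co2_evolution_hc,
        )
    df = pd.DataFrame(
        rows,
        columns=["scenario", "status", "max_growth", "min_sucrose_uptake_hc",
                 "min_co2_evolution_hc"],
    )
    p = out / "scheme_metrics.tsv"
    df.to_csv(p, sep="\t", index=False)
    return p


def cmd_optforce(config: RunConfig) -> Path:
    """Run the OptForce workflow and write a strategy report table."""
    model = _load(config)
    out = _out(config)
    spec = {s.name: s for s in make_pathway_fixtures()}.get(config.product)
    if spec is not None and not model.has_reaction(spec.product_exchange):
        model = add_production_pathway(model, spec)
        product = spec.product_exchange
    elif spec is not None:
        product = spec.product_exchange
    else:
        product = config.product  # assume a native product exchange id
    if config.mfa_path:
        mfa = load_mfa_table(config.mfa_path)
    else:
        base, _ = make_toy_two_cell()
        mfa = make_mfa_fixture(base)
    wt = wild_type_flux_space(model, mfa)
    over = overproduction_flux_space(
        model, product, yield_frac=config.yield_frac, biomass_frac=config.biomass_frac
    )
    must = identify_must_single(wt, over)
    log.info("raw MUST sets: %d up, %d down, %d knockout", *must.single_counts())
    filtered = filter_must_sets(must, model, growth_coupled=find_growth_coupled(model))
    log.info("filtered MUST sets: %d up, %d down, %d knockout", *filtered.single_counts())
    rows = []
    if not (filtered.must_u or filtered.must_l or filtered.must_x or config.extra_knockouts):
        log.warning("all MUST sets empty after filtering; no strategies to search")
    else:
        strategies = solve_force_set(
            model,
            wt,
            filtered,
            k=config.k,
            product=product,
            extra_knockouts=set(config.extra_knockouts),
            n_strategies=config.n_strategies,
        )
        for i, s in enumerate(strategies, start=1):
            log.info(
                "strategy %d: %s -> guaranteed %.6g mmol/gDW/h",
                i,
                ", ".join(f"{m.kind} {m.reaction_id}" for m in s.members) or "(none)",
                s.guaranteed_product_flux,
            )
            for m in s.members:
                rows.append(
                    (i, m.reaction_id, m.kind, s.fold_changes.get(m.reaction_id, ""),
                     s.guaranteed_product_flux)
                )
            if not s.members:
                rows.append((i, "", "none", "", s.guaranteed_product_flux))
    df = pd.DataFrame(
        rows,
        columns=["mutant", "intervention", "kind", "fold_change", "product_flux"],
    )
    p = out / f"optforce_{config.product}_k{config.k}.tsv"
    df.to_csv(p, sep="\t", index=False)
    return p
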