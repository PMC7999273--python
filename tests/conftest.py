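import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from diazofba.model import MetabolicModel, Metabolite, Reaction
from diazofba.optforce import (
    add_production_pathway,
    overproduction_flux_space,
    wild_type_flux_space,
)
from diazofba.toy import (
    ToyParams,
    make_mfa_fixture,
    make_pathway_fixtures,
    make_toy_template,
    make_toy_two_cell,
)


@pytest.fixture(scope="session")
def toy():
    """The constrained two-cell toy model and its manifest."""
    return make_toy_two_cell()


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def manifest(toy):
    return toy[1]


@pytest.fixture(scope="session")
def template():
    return make_toy_template()


@pytest.fixture(scope="session")
def pathways():
    return {spec.name: spec for spec in make_pathway_fixtures()}


@pytest.fixture(scope="session")
def mfa_fixture(toy_model):
    return make_mfa_fixture(toy_model)


@pytest.fixture(scope="session")
def valerolactam_case(toy_model, pathways, mfa_fixture):
    """Model + wild-type and overproduction spaces for the valerolactam pathway."""
    spec = pathways["five_aminovalerate"]
    model = add_production_pathway(toy_model, spec)
    wt = wild_type_flux_space(model, mfa_fixture)
    over = overproduction_flux_space(model, spec.product_exchange)
    return {"model": model, "spec": spec, "wt": wt, "over": over}


@pytest.fixture(scope="session")
def caprolactam_case(toy_model, pathways, mfa_fixture):
    spec = pathways["adipyl_coa"]
    model = add_production_pathway(toy_model, spec)
    wt = wild_type_flux_space(model, mfa_fixture)
    over = overproduction_flux_space(model, spec.product_exchange)
    return {"model": model, "spec": spec, "wt": wt, "over": over}


def make_mini_model(reactions, objective=None, metabolite_ids=None):
    """Small helper building abstract LP models for oracle comparisons.

    ``reactions``: list of (id, stoichiometry, lb, ub[, kind]).
    """
    model = MetabolicModel(id="mini")
    met_ids = set()
    for entry in reactions:
        met_ids |= set(entry[1])
    for met in sorted(met_ids | set(metabolite_ids or [])):
        model.add_metabolite(Metabolite(id=met, formula=None))
    for entry in reactions:
        rid, stoich, lb, ub = entry[:4]
        kind = entry[4] if len(entry) > 4 else ("exchange" if len(stoich) == 1 else "enzymatic")
        model.add_reaction(
            Reaction(id=rid, stoichiometry=dict(stoich), lower_bound=lb, upper_bound=ub, kind=kind)
        )
    if objective:
        model.objective = (objective, "max")
    return model


@pytest.fixture
def mini_branch():
    """Two routes of different yield from a bounded substrate; optimum 6."""
    return make_mini_model(
        [
            ("in_A", {"A": 1}, 0, 4),
            ("r1", {"A": -1, "B": 1}, 0, 3),
            ("r2", {"A": -1, "B": 2}, 0, 2),
            ("out_B", {"B": -1}, 0, 1000),
        ],
        objective="out_B",
    )


@pytest.fixture
def mini_cycle():
    """A cost-free 2-reaction cycle parallel to a productive path."""
    return make_mini_model(
        [
            ("in_A", {"A": 1}, 0, 5),
            ("fwd", {"A": -1, "B": 1}, 0, 1000),
            ("back", {"B": -1, "A": 1}, 0, 1000),
            ("out_B", {"B": -1}, 0, 1000),
        ],
        objective="out_B",
    )
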