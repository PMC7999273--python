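"""Two-cell construction, diazotrophic constraints and their invariants."""

import math

import pytest

from diazofba.model import ModelValidationError
from diazofba.solver import fba, fva
from diazofba.twocell import (
    BiomassComposition,
    TwoCellConfig,
    apply_diazotrophic_constraints,
    build_biomass_reaction,
    build_two_cell,
    growth_rate_from_doubling_time,
    heterocyst_o2_bound,
)
from diazofba.toy import ToyParams, make_toy_template, make_toy_two_cell, _toy_config


class TestHeterocystO2Bound:
    def test_published_culture_values(self):
        """0.7 mmol/gDW/h culture uptake x 9 % heterocysts = 0.063."""
        assert heterocyst_o2_bound(0.7, 0.09) == pytest.approx(0.063)

    @pytest.mark.parametrize("uptake", [0.0, 0.3, 1.7])
    def test_zero_fraction_zero_bound(self, uptake):
        assert heterocyst_o2_bound(uptake, 0.0) == 0.0

    def test_identity_at_full_fraction(self):
        assert heterocyst_o2_bound(1.0, 1.0) == 1.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            heterocyst_o2_bound(-0.1, 0.09)


class TestGrowthRate:
    def test_published_doubling_time(self):
        """A 3.8 h doubling time gives 0.1824 1/h to four decimals."""
        assert round(growth_rate_from_doubling_time(3.8), 4) == 0.1824

    def test_one_hour_gives_ln2(self):
        assert growth_rate_from_doubling_time(1.0) == pytest.approx(math.log(2))

    @pytest.mark.parametrize("td", [0.5, 2.0, 9.7])
    def test_doubling_td_halves_rate(self, td):
        assert growth_rate_from_doubling_time(2 * td) == pytest.approx(
            growth_rate_from_doubling_time(td) / 2
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            growth_rate_from_doubling_time(0.0)


class TestBiomassReaction:
    def test_single_precursor_coefficient(self):
        comp = BiomassComposition(classes={"carb": (1.0, {"g6p": 0.1})})
        rxn = build_biomass_reaction(comp)
        assert rxn.stoichiometry["g6p"] == pytest.approx(-10.0)
        assert rxn.kind == "biomass"

    def test_fractions_rescaled_to_unit_mass(self):
        comp = BiomassComposition(
            classes={"a": (0.6, {"p1": 0.1}), "b": (0.6, {"p2": 0.1})}
        )
        rxn = build_biomass_reaction(comp)
        assert rxn.stoichiometry["p1"] == pytest.approx(-5.0)  # 0.5 g / 0.1 g/mmol
        assert rxn.stoichiometry["p2"] == pytest.approx(-5.0)

    def test_spreadsheet_style_hand_computation(self):
        # protein 55 %, carbohydrate 35 %, lipid 10 %; molar masses g/mmol
        comp = BiomassComposition(
            classes={
                "protein": (0.55, {"aa": 0.11}),
                "carbohydrate": (0.35, {"hexose": 0.162}),
                "lipid": (0.10, {"acyl": 0.76}),
            },
            gam_atp=30.0,
            atp_ids=("atp", "adp", "pi"),
        )
        rxn = build_biomass_reaction(comp)
        assert rxn.stoichiometry["aa"] == pytest.approx(-0.55 / 0.11)
        assert rxn.stoichiometry["hexose"] == pytest.approx(-0.35 / 0.162)
        assert rxn.stoichiometry["acyl"] == pytest.approx(-0.10 / 0.76)
        assert rxn.stoichiometry["atp"] == pytest.approx(-30.0)
        # consumed precursor mass sums to 1 g per unit flux
        masses = {"aa": 0.11, "hexose": 0.162, "acyl": 0.76}
        total = -sum(rxn.stoichiometry[m] * masses[m] for m in masses)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_zero_fractions_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            build_biomass_reaction(BiomassComposition(classes={"a": (0.0, {"p": 1.0})}))


class TestBuildTwoCell:
    def test_construction_arithmetic(self, template):
        """n duplicable reactions -> (n-3) hc + (n-1) vc + 4 exchanges + boundary."""
        model = build_two_cell(template, _toy_config())
        n = len(template.reactions) - 1  # one culture-boundary exchange
        vc = sum(1 for r in model.reactions if r.id.endswith("__vc"))
        hc = sum(1 for r in model.reactions if r.id.endswith("__hc"))
        exch = sum(1 for r in model.reactions if r.kind == "intercell-exchange")
        assert vc == n - 1
        assert hc == n - 3
        assert exch == 4
        assert len(model.reactions) == vc + hc + exch + 1

    def test_unknown_deletion_rejected(self, template):
        cfg = _toy_config()
        bad = TwoCellConfig(
            heterocyst_deletions=("no_such_reaction",),
            vegetative_deletions=cfg.vegetative_deletions,
            intercell_exchanges=cfg.intercell_exchanges,
        )
        with pytest.raises(ModelValidationError, match="no_such_reaction"):
            build_two_cell(template, bad)

    def test_missing_exchange_metabolite_rejected(self, template):
        cfg = _toy_config(intercell_exchanges=(("unobtainium", "vc->hc"),))
        with pytest.raises(ModelValidationError, match="unobtainium"):
            build_two_cell(template, cfg)

    def test_heterocyst_biomass_floor_applied(self, toy_model):
        rxn = toy_model.get_reaction("biomass__hc")
        assert rxn.lower_bound == pytest.approx(0.1 * 0.1824)

    def test_constraint_bounds_applied(self, toy_model):
        assert toy_model.get_reaction("EX_ci").upper_bound == 8.5
        assert toy_model.get_reaction("photon_in__vc").upper_bound == 100.0
        assert toy_model.get_reaction("photon_in__hc").upper_bound == 100.0
        assert toy_model.get_reaction("n2_in__hc").upper_bound == 10.0
        assert toy_model.get_reaction("o2_in__hc").upper_bound == pytest.approx(0.063)
        assert toy_model.objective == ("biomass__vc", "max")


class TestGlutamateGlutamineCoupling:
    def test_fluxes_equal_in_optimum(self, toy_model):
        sol = fba(toy_model)
        assert sol.fluxes["glu_vc_hc_exch"] == pytest.approx(
            sol.fluxes["gln_vc_hc_exch"], abs=1e-6
        )

    def test_difference_range_is_zero(self, toy_model):
        """Every feasible flux vector has equal glu/gln exchange fluxes."""
        from diazofba.optforce import _combination_range

        lo, hi = _combination_range(
            toy_model, {}, "glu_vc_hc_exch", "gln_vc_hc_exch", -1.0
        )
        assert lo == pytest.approx(0.0, abs=1e-7)
        assert hi == pytest.approx(0.0, abs=1e-7)

    def test_uncoupled_model_can_split(self):
        params = ToyParams(config=_toy_config(couple_glu_gln=False))
        model, _ = make_toy_two_cell(params)
        from diazofba.optforce import _combination_range

        lo, hi = _combination_range(model, {}, "glu_vc_hc_exch", "gln_vc_hc_exch", -1.0)
        assert hi > 1e-3  # heterocyst may now consume glutamate as carbon


class TestDiazotrophicInvariants:
    def test_no_nitrogen_route_no_growth(self, toy_model):
        """Without nitrogenase and inter-cell exchange, nitrogen cannot enter
        biomass and maximal growth is zero."""
        edits = {
            r.id: (0.0, 0.0)
            for r in toy_model.reactions
            if r.kind == "intercell-exchange"
        }
        edits["biomass__hc"] = (0.0, 1000.0)
        sol = fba(toy_model, bound_edits=edits)
        assert sol.optimal and sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_heterocyst_never_evolves_oxygen(self, toy_model):
        """With PSII absent, the heterocyst has no photolytic O2 source: its O2
        export can only re-export the capped uptake."""
        ranges = fva(
            toy_model,
            fixed={"o2_in__hc": (0.0, 0.0), "biomass__hc": (0.0, 1000.0)},
            targets=["o2_out__hc"],
        )
        assert ranges["o2_out__hc"] == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_closing_sucrose_shuttle_stops_fixation_and_growth(self, toy_model):
        edits = {
            "sucrose_vc_hc_exch": (0.0, 0.0),
            "biomass__hc": (0.0, 1000.0),
        }
        ranges = fva(toy_model, fixed=edits, targets=["nitrogenase__hc"])
        assert ranges["nitrogenase__hc"] == pytest.approx((0.0, 0.0), abs=1e-9)
        assert fba(toy_model, bound_edits=edits).objective_value == pytest.approx(
            0.0, abs=1e-9
        )
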