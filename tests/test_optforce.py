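"""MUST-set identification, filtering and the FORCE-set MILP vs brute force."""

import itertools

import pytest

from diazofba.model import MetabolicModel, Metabolite, Reaction
from diazofba.optforce import (
    Intervention,
    InterventionStrategy,
    MustSets,
    _candidate_interventions,
    _combination_range,
    add_production_pathway,
    evaluate_intervention_set,
    filter_must_sets,
    find_essential,
    find_growth_coupled,
    fold_changes,
    identify_must_pairs,
    identify_must_single,
    overproduction_flux_space,
    solve_force_set,
    wild_type_flux_space,
)
from diazofba.solver import FluxRanges, fva


def _ranges(d, context=None):
    return FluxRanges(dict(d), context=context or {})


class TestMustSingle:
    def test_strict_separation_up(self):
        wt = _ranges({"r": (0.0, 1.0)})
        over = _ranges({"r": (2.0, 3.0)})
        must = identify_must_single(wt, over)
        assert must.must_u == {"r"} and not must.must_l and not must.must_x

    def test_overlap_is_no_set(self):
        must = identify_must_single(
            _ranges({"r": (0.0, 1.0)}), _ranges({"r": (0.5, 0.8)})
        )
        assert must.single_counts() == (0, 0, 0)

    def test_down_and_knockout(self):
        wt = _ranges({"a": (1.0, 2.0), "b": (0.5, 2.0)})
        over = _ranges({"a": (0.0, 0.5), "b": (0.0, 0.0)})
        must = identify_must_single(wt, over)
        assert must.must_l == {"a"} and must.must_x == {"b"}

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError):
            identify_must_single(_ranges({"a": (0, 1)}), _ranges({"b": (0, 1)}))


class TestMustPairs:
    @pytest.fixture()
    def parallel_paths(self):
        """Two parallel routes with overlapping individual ranges whose SUM
        must rise in the overproduction space."""
        m = MetabolicModel(id="pairs")
        for met in ("A", "B", "P"):
            m.add_metabolite(Metabolite(id=met, formula=None))
        m.add_reaction(Reaction("in_A", {"A": 1}, 0, 10, kind="exchange"))
        m.add_reaction(Reaction("r1", {"A": -1, "B": 1}, 0, 10))
        m.add_reaction(Reaction("r2", {"A": -1, "B": 1}, 0, 10))
        m.add_reaction(Reaction("mk_P", {"B": -1, "P": 1}, 0, 10))
        m.add_reaction(Reaction("out_P", {"P": -1}, 0, 10, kind="exchange"))
        m.objective = ("out_P", "max")
        return m

    def test_sum_separation_found_by_pair_scan(self, parallel_paths):
        m = parallel_paths
        wt = fva(m, fixed={"out_P": (0.0, 1.0)})
        wt.context = {"bounds": {"out_P": (0.0, 1.0)}}
        over = fva(m, fixed={"out_P": (4.0, 10.0)})
        over.context = {"bounds": {"out_P": (4.0, 10.0)}}
        must = identify_must_pairs(m, wt, over, pairs=[("r1", "r2")])
        # individually each route can stay low (the other covers the demand)
        assert "r1" not in must.must_u and "r2" not in must.must_u
        assert ("r1", "r2") in must.must_uu
        # oracle check by direct FVA of the sum
        lo_wt, hi_wt = _combination_range(m, {"out_P": (0.0, 1.0)}, "r1", "r2", 1.0)
        lo_ov, _ = _combination_range(m, {"out_P": (4.0, 10.0)}, "r1", "r2", 1.0)
        assert lo_ov > hi_wt

    def test_identical_blocked_pair_in_no_set(self, parallel_paths):
        m = parallel_paths.copy()
        m.set_bounds("r1", upper=0.0)
        wt = fva(m)
        wt.context = {"bounds": {}}
        must = identify_must_pairs(m, wt, wt, pairs=[("r1", "r1")])
        assert not (must.must_uu or must.must_ll or must.must_ul or must.must_lu)

    def test_self_pair_sum_is_twice_single_range(self, parallel_paths):
        m = parallel_paths
        single = fva(m, targets=["r1"])
        lo, hi = _combination_range(m, {}, "r1", "r1", 1.0)
        assert lo == pytest.approx(2 * single.minimum("r1"), abs=1e-7)
        assert hi == pytest.approx(2 * single.maximum("r1"), abs=1e-7)

    def test_empty_universe_warns(self, parallel_paths):
        wt = fva(parallel_paths)
        wt.context = {"bounds": {}}
        with pytest.warns(UserWarning, match="empty pairwise"):
            identify_must_pairs(parallel_paths, wt, wt, pairs=[])


class TestFiltering:
    def _chain_model(self):
        m = MetabolicModel(id="chain")
        for met in ("A", "B", "C", "D"):
            m.add_metabolite(Metabolite(id=met, formula=None))
        m.add_reaction(Reaction("in_A", {"A": 1}, 0, 10, kind="exchange"))
        m.add_reaction(Reaction("s1", {"A": -1, "B": 1}, 0, 10))
        m.add_reaction(Reaction("s2", {"B": -1, "C": 1}, 0, 10))
        m.add_reaction(Reaction("s3", {"C": -1, "D": 1}, 0, 10))
        m.add_reaction(Reaction("out_D", {"D": -1}, 0, 10, kind="exchange"))
        return m

    def test_boundary_kinds_removed_everywhere(self):
        m = self._chain_model()
        must = MustSets(
            must_u={"in_A", "s1"},
            must_l={"out_D"},
            provenance=(_ranges({}), _ranges({})),
        )
        filtered = filter_must_sets(must, m)
        assert filtered.must_u == {"s1"} and not filtered.must_l

    def test_linear_chain_collapses_to_first(self):
        m = self._chain_model()
        must = MustSets(
            must_u={"s1", "s2", "s3"}, provenance=(_ranges({}), _ranges({}))
        )
        assert filter_must_sets(must, m).must_u == {"s1"}

    def test_partial_chain_keeps_upstream_member(self):
        m = self._chain_model()
        must = MustSets(must_u={"s2", "s3"}, provenance=(_ranges({}), _ranges({})))
        assert filter_must_sets(must, m).must_u == {"s2"}

    def test_growth_coupled_leaves_must_l(self):
        m = self._chain_model()
        must = MustSets(must_l={"s2"}, provenance=(_ranges({}), _ranges({})))
        assert filter_must_sets(must, m, growth_coupled={"s2"}).must_l == set()

    def test_essential_removed_from_must_x(self):
        m = self._chain_model()
        wt = _ranges({"s1": (1.0, 2.0), "s2": (1.0, 2.0)})
        must = MustSets(must_x={"s1", "s2"}, provenance=(wt, wt))
        # the chain collapses onto s1, which is essential in vivo: nothing left
        assert filter_must_sets(must, m, essential={"s1"}).must_x == set()

    def test_low_flux_removed_from_must_x(self):
        m = self._chain_model()
        wt = _ranges({"s1": (0.0, 5e-4), "s2": (1.0, 2.0)})
        must = MustSets(must_x={"s1"}, provenance=(wt, wt))
        assert filter_must_sets(must, m).must_x == set()
        # above the threshold the reaction stays
        must2 = MustSets(must_x={"s2"}, provenance=(wt, wt))
        assert filter_must_sets(must2, m).must_x == {"s2"}

    def test_filters_only_shrink(self, valerolactam_case):
        case = valerolactam_case
        must = identify_must_single(case["wt"], case["over"])
        filtered = filter_must_sets(must, case["model"])
        assert filtered.must_u <= must.must_u
        assert filtered.must_l <= must.must_l
        assert filtered.must_x <= must.must_x


class TestHelpers:
    def test_growth_coupled_includes_nitrogenase(self, toy_model):
        coupled = find_growth_coupled(toy_model)
        assert "nitrogenase__hc" in coupled
        assert "rubisco_calvin__vc" in coupled
        assert "ethanol_fermentation__hc" not in coupled

    def test_essential_reactions(self, toy_model):
        ess = find_essential(
            toy_model, candidates=["rubisco_calvin__vc", "gs__hc", "ethanol_fermentation__hc"]
        )
        assert ess == {"rubisco_calvin__vc", "gs__hc"}


class TestFluxSpaces:
    def test_empty_mfa_is_plain_fva(self, toy_model):
        plain = fva(toy_model, targets=["nitrogenase__hc"])
        wt = wild_type_flux_space(toy_model, _ranges({}))
        assert wt.ranges["nitrogenase__hc"] == pytest.approx(
            plain.ranges["nitrogenase__hc"], abs=1e-7
        )

    def test_point_range_is_pinned(self, toy_model, mfa_fixture):
        wt = wild_type_flux_space(toy_model, _ranges({"oppp__vc": (0.2, 0.2)}))
        assert wt.ranges["oppp__vc"] == pytest.approx((0.2, 0.2), abs=1e-7)

    def test_infeasible_mfa_names_reaction(self, toy_model):
        # a measured-zero nitrogenase conflicts with the heterocyst turnover
        # floor, which needs fixed nitrogen
        bad = _ranges({"nitrogenase__hc": (0.0, 0.0)})
        with pytest.raises(Exception, match="nitrogenase__hc"):
            wild_type_flux_space(toy_model, bad)

    def test_unknown_reaction_rejected(self, toy_model):
        with pytest.raises(KeyError):
            wild_type_flux_space(toy_model, _ranges({"ghost": (0, 1)}))

    def test_overproduction_floors_hold(self, valerolactam_case):
        over = valerolactam_case["over"]
        product = valerolactam_case["spec"].product_exchange
        y = over.context["theoretical_yield"]
        assert over.minimum(product) >= 0.9 * y - 1e-6

    def test_zero_fractions_reduce_to_plain_fva(self, toy_model, pathways):
        spec = pathways["five_aminovalerate"]
        model = add_production_pathway(toy_model, spec)
        over = overproduction_flux_space(
            model, spec.product_exchange, yield_frac=0.0, biomass_frac=0.0
        )
        plain = fva(model, targets=["nitrogenase__hc", spec.product_exchange])
        for rxn in plain.ranges:
            assert over.ranges[rxn] == pytest.approx(plain.ranges[rxn], abs=1e-6)


class TestPathways:
    def test_missing_precursor_rejected(self, toy_model, pathways):
        broken = toy_model.copy()
        spec = pathways["adipyl_coa"]
        broken.remove_reaction("tca_2__vc")  # succinate still exists as species
        stripped = toy_model.copy()
        for rxn in list(stripped.reactions):
            if "suc__vc" in rxn.stoichiometry:
                stripped.remove_reaction(rxn.id)
        stripped.metabolites = [m for m in stripped.metabolites if m.id != "suc__vc"]
        with pytest.raises(KeyError, match="precursor"):
            add_production_pathway(stripped, spec)

    def test_product_needs_its_exchange(self, valerolactam_case):
        model = valerolactam_case["model"]
        product = valerolactam_case["spec"].product_exchange
        ranges = fva(
            model, fixed={product: (0.0, 0.0)}, targets=["lactam_synthase_v__vc"]
        )
        assert ranges["lactam_synthase_v__vc"] == pytest.approx((0.0, 0.0), abs=1e-9)


class TestForceSets:
    def test_k0_returns_wild_type_worst_case(self, valerolactam_case):
        case = valerolactam_case
        must = filter_must_sets(
            identify_must_single(case["wt"], case["over"]), case["model"]
        )
        strategies = solve_force_set(
            case["model"], case["wt"], must, k=0,
            product=case["spec"].product_exchange,
        )
        assert len(strategies) == 1 and not strategies[0].members
        assert strategies[0].guaranteed_product_flux == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("case_name", ["valerolactam_case", "caprolactam_case"])
    def test_milp_equals_brute_force_k1_and_k2(self, case_name, request):
        case = request.getfixturevalue(case_name)
        model, wt = case["model"], case["wt"]
        product = case["spec"].product_exchange
        must = filter_must_sets(identify_must_single(wt, case["over"]), model)
        candidates = _candidate_interventions(must, set())
        wt_bounds = dict(wt.context["bounds"])
        for k in (1, 2):
            best = 0.0
            for size in range(1, k + 1):
                for combo in itertools.combinations(range(len(candidates)), size):
                    value = evaluate_intervention_set(
                        model, wt_bounds, product, [candidates[i] for i in combo]
                    )
                    if value is not None:
                        best = max(best, value)
            strategies = solve_force_set(model, wt, must, k=k, product=product)
            got = strategies[0].guaranteed_product_flux if strategies else 0.0
            assert got == pytest.approx(best, abs=1e-6), f"k={k}"

    def test_guaranteed_flux_nondecreasing_in_k(self, valerolactam_case):
        case = valerolactam_case
        must = filter_must_sets(
            identify_must_single(case["wt"], case["over"]), case["model"]
        )
        product = case["spec"].product_exchange
        previous = -1.0
        for k in (0, 1, 2):
            strategies = solve_force_set(case["model"], case["wt"], must, k=k, product=product)
            value = strategies[0].guaranteed_product_flux if strategies else 0.0
            assert value >= previous - 1e-9
            previous = value

    def test_members_come_from_must_or_extra_knockouts(self, caprolactam_case):
        case = caprolactam_case
        must = filter_must_sets(
            identify_must_single(case["wt"], case["over"]), case["model"]
        )
        allowed = must.must_u | must.must_l | must.must_x | {"sdh_tca3__hc"}
        strategies = solve_force_set(
            case["model"], case["wt"], must, k=2,
            product=case["spec"].product_exchange,
            extra_knockouts={"sdh_tca3__hc"}, n_strategies=3,
        )
        for s in strategies:
            assert s.member_ids() <= allowed

    def test_integer_cuts_give_distinct_nonincreasing_strategies(self, caprolactam_case):
        case = caprolactam_case
        must = filter_must_sets(
            identify_must_single(case["wt"], case["over"]), case["model"]
        )
        strategies = solve_force_set(
            case["model"], case["wt"], must, k=2,
            product=case["spec"].product_exchange, n_strategies=4,
        )
        seen = set()
        fluxes = [s.guaranteed_product_flux for s in strategies]
        for s in strategies:
            assert s.member_ids() not in seen
            seen.add(s.member_ids())
        assert fluxes == sorted(fluxes, reverse=True)


class TestFoldChanges:
    def test_stated_arithmetic(self):
        wt = _ranges({"up_r": (0.0, 2.0), "down_r": (1.0, 3.0)})
        strategy = InterventionStrategy(
            k=2,
            members=[
                Intervention("up_r", "up", 2.4),
                Intervention("down_r", "down", 0.1),
            ],
            guaranteed_product_flux=1.0,
        )
        fc = fold_changes(strategy, wt)
        assert fc["up_r"] == "1.2↑"
        assert fc["down_r"] == "10↓"

    def test_zero_denominator_reports_infinity(self):
        wt = _ranges({"r": (0.0, 0.0)})
        strategy = InterventionStrategy(
            k=1, members=[Intervention("r", "up", 1.5)], guaranteed_product_flux=1.0
        )
        assert fold_changes(strategy, wt)["r"] == "∞↑"

    def test_knockout_reported_as_deletion(self):
        wt = _ranges({"r": (0.5, 1.0)})
        strategy = InterventionStrategy(
            k=1, members=[Intervention("r", "knockout", 0.0)], guaranteed_product_flux=0.5
        )
        assert fold_changes(strategy, wt)["r"] == "Δ"
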