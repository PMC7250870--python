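"""Uptake bounds, the growth LP, and pool updates against hand arithmetic."""
import math

import numpy as np
import pytest
from cobra import Metabolite, Model, Reaction

from acbm.metabolism import (
    MetabolicModelHandle,
    apply_expression_bounds,
    delta_concentration,
    local_biomass_concentration,
    michaelis_menten_bound,
    solve_growth,
    spawn_product_packages,
    update_biomass,
    update_product,
    update_substrate,
    uptake_bound_from_intake,
)


class TestDeltaConcentration:
    def test_zero_molecules(self):
        assert delta_concentration(0, 10.0) == 0.0

    def test_hand_value_package_in_ten_micron_sphere(self):
        # 5e5 / (6.022e23 * 4.188790e-12 l) by hand
        assert delta_concentration(5e5, 10.0) == pytest.approx(
            1.9821688362491116e-07, rel=1e-12
        )

    def test_linearity(self):
        assert delta_concentration(2e6, 7.0) == pytest.approx(
            2 * delta_concentration(1e6, 7.0)
        )

    def test_bad_radius(self):
        with pytest.raises(ValueError):
            delta_concentration(1.0, 0.0)


class TestLocalBiomass:
    def test_single_picogram_cell(self):
        assert local_biomass_concentration([1.0], 10.0) == pytest.approx(
            0.238732414637843, rel=1e-12
        )

    def test_crowding_monotone(self):
        lone = local_biomass_concentration([1.0], 10.0)
        crowd = local_biomass_concentration([1.0, 2.0, 3.0], 10.0)
        assert crowd > lone

    def test_colony_scaling_linear(self):
        assert local_biomass_concentration([1000.0], 5.0) == pytest.approx(
            1000 * local_biomass_concentration([1.0], 5.0)
        )


class TestUptakeBound:
    def test_zero_delta(self):
        assert uptake_bound_from_intake(0.0, 1.0, 1 / 60, 1000.0) == 0.0

    def test_hand_quotient(self):
        # 1000 * 1e-3 / (2 * 1/60) = 30
        assert uptake_bound_from_intake(1e-3, 2.0, 1 / 60, 1000.0) == pytest.approx(30.0)

    def test_panel_caps_computed_rate(self):
        # computed rate 2500 against the published glucose panel value 1000
        assert uptake_bound_from_intake(2.5, 1.0, 1.0, 1000.0) == 1000.0

    def test_no_biomass_is_an_error(self):
        with pytest.raises(ValueError):
            uptake_bound_from_intake(1.0, 0.0, 1 / 60, 1000.0)


class TestMichaelisMenten:
    def test_zero_concentration(self):
        assert michaelis_menten_bound(0.0, 10.0, 2.72e-6) == 0.0

    def test_half_saturation(self):
        assert michaelis_menten_bound(2.72e-6, 10.0, 2.72e-6) == pytest.approx(5.0)

    def test_saturates_at_vmax(self):
        assert michaelis_menten_bound(100 * 2.72e-6, 10.0, 2.72e-6) == pytest.approx(
            10.0, rel=0.01
        )


class TestSolveGrowth:
    def test_toy_optimum_by_hand(self, toy):
        sol = solve_growth(toy, {"glc": 10.0})
        assert sol.feasible
        assert sol.mu == pytest.approx(1.0, rel=1e-9)
        assert sol.v_p["ac"] == pytest.approx(5.0, rel=1e-9)
        assert sol.v_s["glc"] == pytest.approx(10.0, rel=1e-9)

    def test_no_glucose_no_growth(self, toy):
        sol = solve_growth(toy, {"glc": 0.0})
        assert not sol.feasible and sol.mu == 0.0

    def test_mu_linear_in_bound(self, toy, rng):
        for bound in rng.uniform(0.5, 50.0, 20):
            sol = solve_growth(toy, {"glc": bound})
            assert sol.mu == pytest.approx(0.1 * bound, rel=1e-6)

    def test_negative_bound_rejected(self, toy):
        with pytest.raises(ValueError):
            solve_growth(toy, {"glc": -1.0})


class TestExpressionBounds:
    LEVELS = {"gT": 5.0, "gG1": 2.0, "gG2": 3.0, "gA": 7.0}

    def test_bounds_equal_scale_times_summed_levels(self, toy_genes):
        capped = apply_expression_bounds(toy_genes, self.LEVELS, scale=2.0)
        rxns = capped.model.reactions
        assert rxns.get_by_id("T_glc").upper_bound == pytest.approx(10.0)
        assert rxns.get_by_id("R_growth").upper_bound == pytest.approx(10.0)
        assert rxns.get_by_id("T_ac").upper_bound == pytest.approx(14.0)
        # exchanges have no gene association: bounds untouched
        assert rxns.get_by_id("EX_glc").upper_bound == 1000.0

    def test_zero_expression_zeroes_the_reaction(self, toy_genes):
        capped = apply_expression_bounds(toy_genes, {"gT": 0.0}, scale=1.0)
        assert capped.model.reactions.get_by_id("T_glc").upper_bound == 0.0
        assert solve_growth(capped, {"glc": 10.0}).mu == 0.0

    def test_doubling_scale_doubles_bounds(self, toy_genes):
        b1 = apply_expression_bounds(toy_genes, self.LEVELS, 1.0)
        b2 = apply_expression_bounds(toy_genes, self.LEVELS, 2.0)
        for rid in ("T_glc", "R_growth", "T_ac"):
            assert b2.model.reactions.get_by_id(rid).upper_bound == pytest.approx(
                2 * b1.model.reactions.get_by_id(rid).upper_bound
            )

    def test_reversible_reactions_bounded_symmetrically(self):
        m = Model("rev")
        a = Metabolite("a_c", compartment="c")
        b = Metabolite("b_c", compartment="c")
        r = Reaction("R_rev")
        r.lower_bound, r.upper_bound = -1000.0, 1000.0
        m.add_reactions([r])
        r.add_metabolites({a: -1, b: 1})
        r.gene_reaction_rule = "g1"
        sink = Reaction("EX_b")
        m.add_reactions([sink])
        sink.add_metabolites({b: -1})
        m.objective = "EX_b"
        handle = MetabolicModelHandle(m, "EX_b")
        capped = apply_expression_bounds(handle, {"g1": 4.0}, scale=1.5)
        rr = capped.model.reactions.get_by_id("R_rev")
        assert (rr.lower_bound, rr.upper_bound) == (-6.0, 6.0)

    def test_empty_table_is_an_error(self, toy_genes):
        with pytest.raises(ValueError):
            apply_expression_bounds(toy_genes, {}, 1.0)


class TestPoolUpdates:
    def test_no_growth_no_change(self):
        assert update_biomass(3.0, 0.0, 1 / 60) == 3.0

    def test_ln2_per_step_doubles(self):
        assert update_biomass(3.0, math.log(2.0), 1.0) == pytest.approx(6.0)

    def test_published_rate_one_minute_factor(self):
        assert update_biomass(1.0, 0.65, 1 / 60) == pytest.approx(
            1.010892226366042, rel=1e-12
        )

    def test_product_hand_triple(self):
        # 1 + 2 mmol/gDW/h * 3 g/l * 0.5 h * 60 g/mol / 1000 = 1.18 g/l
        assert update_product(1.0, 2.0, 3.0, 0.5, 60.0) == pytest.approx(1.18)

    def test_product_increment_linear_in_biomass(self):
        inc1 = update_product(0.0, 2.0, 3.0, 0.5, 60.0)
        inc2 = update_product(0.0, 2.0, 6.0, 0.5, 60.0)
        assert inc2 == pytest.approx(2 * inc1)

    def test_substrate_mirrors_product(self):
        assert update_substrate(2.0, 2.0, 3.0, 0.5, 60.0) == pytest.approx(2.0 - 0.18)
        assert update_substrate(2.0, 0.0, 3.0, 0.5, 60.0) == 2.0

    def test_substrate_overshoot_clamps_with_warning(self):
        with pytest.warns(UserWarning):
            assert update_substrate(0.01, 50.0, 3.0, 0.5, 60.0) == 0.0


class TestSpawnPackages:
    AVO = 6.022e23

    def test_exactly_two_packages(self, rng):
        mass = 2 * 5e5 * 180.16 / self.AVO
        pkgs, rem = spawn_product_packages(mass, 180.16, 5e5, np.zeros(3), 10.0, rng)
        assert len(pkgs) == 2
        assert rem == pytest.approx(0.0, abs=1e-3)

    def test_below_one_package_accumulates(self, rng):
        mass = 0.4 * 5e5 * 180.16 / self.AVO
        pkgs, rem = spawn_product_packages(mass, 180.16, 5e5, np.zeros(3), 10.0, rng)
        assert pkgs == [] and rem == pytest.approx(0.4 * 5e5, rel=1e-9)

    def test_molecule_conservation_with_carry(self, rng):
        mass = 3.7 * 1e4 * 88.11 / self.AVO
        pkgs, rem = spawn_product_packages(
            mass, 88.11, 1e4, np.zeros(3), 5.0, rng, carry_molecules=4000.0
        )
        total = sum(n for _, n in pkgs) + rem
        assert total == pytest.approx(3.7 * 1e4 + 4000.0, rel=1e-9)
        for pos, _ in pkgs:
            assert np.linalg.norm(pos) <= 5.0 + 1e-9
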