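import dataclasses

import numpy as np
import pytest

from strokecea import (
    MrsDistribution,
    compare_strategies,
    default_tornado_bounds,
    one_way_sensitivity,
    population_scale,
    price_performance_grid,
    random_params,
    scenario_grid,
    set_param,
    threshold_price,
)


def with_clinical(params, **kw):
    return dataclasses.replace(params, clinical=dataclasses.replace(params.clinical, **kw))


def with_costs(params, **kw):
    return dataclasses.replace(params, costs=dataclasses.replace(params.costs, **kw))


def with_settings(params, **kw):
    return dataclasses.replace(params, settings=dataclasses.replace(params.settings, **kw))


class TestCompareStrategies:
    def test_reduction_zero_differs_only_by_fee(self, params, uk_table):
        res = compare_strategies(with_clinical(params, reduction=0.0), uk_table)
        assert res.ic_pp == pytest.approx(params.costs.ai_per_analysis, abs=1e-9)
        assert res.ie_pp == pytest.approx(0.0, abs=1e-12)
        assert not res.dominant

    def test_base_case_dominant_with_phase_additivity(self, params, uk_table):
        res = compare_strategies(params, uk_table)
        assert res.dominant and res.icer is None
        assert res.ic_pp == pytest.approx(res.acute_ic_pp + res.longterm_ic_pp, abs=1e-9)
        assert res.ie_pp == pytest.approx(res.acute_ie_pp + res.longterm_ie_pp, abs=1e-12)
        assert res.ic_pop == pytest.approx(res.ic_pp * 71_840)

    def test_nmb_worked_example(self):
        # 0.0095 QALYs at $25,662/QALY is worth $244 (rounded)
        assert round(0.0095 * 25_662) == 244

    def test_nmb_field_arithmetic(self, params, uk_table):
        res = compare_strategies(params, uk_table)
        assert res.nmb_pp == pytest.approx(25_662 * res.ie_pp - res.ic_pp, abs=1e-9)

    def test_icer_reported_when_not_dominant(self, params, uk_table):
        res = compare_strategies(with_costs(params, ai_per_analysis=500.0), uk_table)
        assert not res.dominant
        assert res.icer == pytest.approx(res.ic_pp / res.ie_pp)

    def test_increments_invariant_to_non_lvo_profile(self, params, uk_table):
        base = compare_strategies(params, uk_table)
        for profile in ("non_iat", "custom"):
            p = with_settings(
                params, non_lvo_profile=profile,
                custom_profile=MrsDistribution.point_mass(1),
            )
            res = compare_strategies(p, uk_table)
            assert res.ic_pp == pytest.approx(base.ic_pp, abs=1e-6)
            assert res.ie_pp == pytest.approx(base.ie_pp, abs=1e-9)
            # only the percent-of-usual-care denominators change
            assert res.pct_cost != pytest.approx(base.pct_cost)

    def test_invalid_params_rejected(self, params, uk_table):
        bad = with_clinical(params, p_lvo=1.5)
        with pytest.raises(ValueError, match="p_lvo"):
            compare_strategies(bad, uk_table)


class TestScenarioGrid:
    def test_equal_miss_mass_cells_identical(self, params, uk_table):
        # (6%, 50%) and (3%, 100%) recover the same miss mass
        cells = scenario_grid(params, uk_table, [0.06, 0.03], [0.50, 1.00], ai_cost=0.0)
        by_coord = {(c.p_missed, c.reduction): c for c in cells}
        a, b = by_coord[(0.06, 0.50)], by_coord[(0.03, 1.00)]
        assert a.ic_pp == pytest.approx(b.ic_pp, abs=1e-6)
        assert a.ie_pp == pytest.approx(b.ie_pp, abs=1e-9)

    def test_zero_coordinate_gives_zero(self, params, uk_table):
        cells = scenario_grid(params, uk_table, [0.0, 0.06], [0.0, 0.5], ai_cost=0.0)
        for c in cells:
            if c.p_missed == 0.0 or c.reduction == 0.0:
                assert c.ic_pp == pytest.approx(0.0, abs=1e-9)
                assert c.ie_pp == pytest.approx(0.0, abs=1e-12)

    def test_linearity_in_recovered_miss_mass(self, params, uk_table):
        # at zero AI cost, increments scale with p_missed * reduction
        cells = scenario_grid(params, uk_table, [0.02, 0.08], [0.25, 1.00], ai_cost=0.0)
        by_coord = {(c.p_missed, c.reduction): c for c in cells}
        ref = by_coord[(0.02, 0.25)]
        for (m, r), cell in by_coord.items():
            scale = (m * r) / (0.02 * 0.25)
            assert cell.ic_pp == pytest.approx(ref.ic_pp * scale, rel=1e-9)
            assert cell.ie_pp == pytest.approx(ref.ie_pp * scale, rel=1e-9)

    def test_row_major_order(self, params, uk_table):
        cells = scenario_grid(params, uk_table, [0.01, 0.03], [0.25, 0.5], ai_cost=0.0)
        assert [(c.p_missed, c.reduction) for c in cells] == [
            (0.01, 0.25), (0.01, 0.5), (0.03, 0.25), (0.03, 0.5),
        ]


class TestPriceGrid:
    def test_affine_in_price_slope_one(self, params, uk_table):
        df = price_performance_grid(params, uk_table, [0, 40, 200], [0.25, 0.5])
        for col in df.columns:
            diffs = np.diff(df[col].to_numpy())
            assert diffs == pytest.approx([40.0, 160.0], abs=1e-9)

    def test_matches_full_model_evaluation(self, params, uk_table):
        # the affine shortcut must agree with actually re-running the model
        df = price_performance_grid(params, uk_table, [40], [0.5])
        full = compare_strategies(params, uk_table)
        assert df.loc[40, 0.5] == pytest.approx(full.ic_pp, abs=1e-6)

    def test_zero_reduction_row_is_price(self, params, uk_table):
        df = price_performance_grid(params, uk_table, [0, 10, 100], [0.0])
        assert df[0.0].to_numpy() == pytest.approx([0.0, 10.0, 100.0], abs=1e-9)

    def test_negative_price_rejected(self, params, uk_table):
        with pytest.raises(ValueError):
            price_performance_grid(params, uk_table, [-1], [0.5])


class TestThresholdPrice:
    def test_small_scenario_headroom(self, params, uk_table):
        # 1% missed, 25% recovered: headroom on the order of $15-16
        p = with_clinical(params, p_missed=0.01, reduction=0.25)
        assert threshold_price(p, uk_table) == pytest.approx(16, abs=2)

    def test_zero_reduction_gives_zero(self, params, uk_table):
        assert threshold_price(with_clinical(params, reduction=0.0), uk_table) == 0.0

    def test_consistent_with_base_increment(self, params, uk_table):
        ic = compare_strategies(params, uk_table).ic_pp
        fee = params.costs.ai_per_analysis
        assert threshold_price(params, uk_table) == pytest.approx(-(ic - fee), abs=0.5)


class TestOneWaySensitivity:
    def test_zero_width_bounds_zero_spread(self, params, uk_table):
        base = compare_strategies(params, uk_table)
        rows = one_way_sensitivity(
            params, uk_table, {"tx_iat": (11_728, 11_728), "p_lvo": (0.306, 0.306)}
        )
        for r in rows:
            assert r.ic_spread == pytest.approx(0.0, abs=1e-9)
            assert r.ic_low == pytest.approx(base.ic_pp, abs=1e-9)

    def test_longterm_costs_dominate_acute_costs(self, params, uk_table):
        rows = one_way_sensitivity(
            params, uk_table,
            {"acute_costs_scale": (0.8, 1.2), "longterm_costs_scale": (0.8, 1.2)},
        )
        spreads = {r.parameter: r.ic_spread for r in rows}
        assert spreads["longterm_costs_scale"] > spreads["acute_costs_scale"]
        assert rows[0].parameter == "longterm_costs_scale"  # tornado order

    def test_signs_stable_at_default_bounds(self, params, uk_table):
        for r in one_way_sensitivity(params, uk_table):
            assert r.ic_low < 0 and r.ic_high < 0
            assert r.ie_low > 0 and r.ie_high > 0

    def test_unknown_parameter_rejected(self, params, uk_table):
        with pytest.raises(ValueError, match="no_such"):
            one_way_sensitivity(params, uk_table, {"no_such": (0, 1)})

    def test_unordered_bounds_rejected(self, params, uk_table):
        with pytest.raises(ValueError):
            one_way_sensitivity(params, uk_table, {"tx_iat": (2.0, 1.0)})

    def test_default_bounds_cover_age_and_costs(self, params):
        bounds = default_tornado_bounds(params)
        assert bounds["age0"] == (56, 76)
        assert bounds["tx_iat"] == (pytest.approx(0.8 * 11_728), pytest.approx(1.2 * 11_728))

    def test_set_param_utilities_capped_at_one(self, params):
        p = set_param(params, "utilities_scale", 1.2)
        assert max(p.utilities.utility_by_state) == 1.0


class TestPopulationScale:
    def test_identity_at_n_one(self, params, uk_table):
        res = compare_strategies(params, uk_table)
        assert population_scale(res, 1) == (res.ic_pp, res.ie_pp)

    def test_cohort_totals(self, params, uk_table):
        res = compare_strategies(params, uk_table)
        ic_pop, ie_pop = population_scale(res, 71_840)
        assert ic_pop == pytest.approx(res.ic_pp * 71_840)
        assert ie_pop == pytest.approx(res.ie_pp * 71_840)

    def test_nonpositive_n_rejected(self, params, uk_table):
        res = compare_strategies(params, uk_table)
        with pytest.raises(ValueError):
            population_scale(res, 0)


class TestRandomDrawInvariants:
    def test_increments_affine_in_price_for_random_params(self, uk_table):
        for seed in range(10):
            p = random_params(seed, jitter=0.2)
            ic0 = compare_strategies(with_costs(p, ai_per_analysis=0.0), uk_table).ic_pp
            ic50 = compare_strategies(with_costs(p, ai_per_analysis=50.0), uk_table).ic_pp
            assert ic50 - ic0 == pytest.approx(50.0, abs=1e-9)
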