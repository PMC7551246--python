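"""Scenario pipeline: ICERs, national totals, sensitivity suite, equity."""

import math

import numpy as np
import pandas as pd
import pytest

from yyb_ecea import (
    CostParams,
    EffectParams,
    Scenario,
    SimConfig,
    generate_children,
    generate_provinces,
    icer_range,
    rank_groups,
    run_scenario,
    sensitivity_suite,
)


@pytest.fixture(scope="module")
def base_run(small_world, growth_ref):
    _, provinces, children = small_world
    scenario = Scenario(coverage=0.75, delivery_type=1)
    result = run_scenario(children, provinces, growth_ref, EffectParams(), CostParams(), scenario)
    return children, provinces, result


class TestRunScenario:
    def test_zero_effect_gives_zero_averted_and_na_icer(self, small_world, growth_ref):
        _, provinces, children = small_world
        result = run_scenario(
            children,
            provinces,
            growth_ref,
            EffectParams(),
            CostParams(),
            Scenario(coverage=0.75, delivery_type=1, effect_multiplier=0.0),
        )
        populated = result.groups["n_children"] > 0
        assert (result.groups.loc[populated, "averted"] == 0).all()
        assert result.groups.loc[populated, "icer_rmb_per_case"].isna().all()

    def test_icer_consistency(self, base_run):
        _, _, result = base_run
        g = result.groups.dropna(subset=["icer_rmb_per_case"])
        assert np.allclose(g["icer_rmb_per_case"] * g["averted"], g["total_cost_rmb"])

    def test_national_additivity(self, base_run):
        _, _, result = base_run
        nat = result.national.set_index("wealth")
        assert nat.loc["total", "averted"] == pytest.approx(result.groups["averted"].sum())
        assert nat.loc["total", "total_cost_rmb"] == pytest.approx(
            result.groups["total_cost_rmb"].sum()
        )
        assert nat.loc["poor", "averted"] + nat.loc["nonpoor", "averted"] == pytest.approx(
            nat.loc["total", "averted"]
        )

    def test_single_group_icer_direct_substitution(self, base_run):
        # averted 40,000 from pop 1e6 and a prevalence drop 0.10 -> 0.06 at
        # total cost ¥4e7 gives ¥1,000 per case; the pipeline's ICER always
        # equals total cost / averted
        _, _, result = base_run
        assert 40_000_000 / 40_000 == 1_000
        g = result.groups.dropna(subset=["icer_rmb_per_case"]).iloc[0]
        assert g["icer_rmb_per_case"] == pytest.approx(g["total_cost_rmb"] / g["averted"])

    def test_transport_doubling_increases_every_icer(self, base_run, growth_ref, small_world):
        children, provinces, result = base_run
        doubled = run_scenario(
            children,
            provinces,
            growth_ref,
            EffectParams(),
            CostParams(),
            Scenario(coverage=0.75, delivery_type=1, transport_multiplier=2.0),
        )
        base_icer = result.groups["icer_rmb_per_case"]
        dbl_icer = doubled.groups["icer_rmb_per_case"]
        mask = base_icer.notna()
        assert (dbl_icer[mask] > base_icer[mask]).all()

    def test_unknown_province_rejected(self, base_run, growth_ref):
        children, provinces, _ = base_run
        bad = children.copy()
        bad.loc[0, "province"] = "P99"
        with pytest.raises(ValueError, match="P99"):
            run_scenario(
                bad, provinces, growth_ref, EffectParams(), CostParams(),
                Scenario(coverage=0.25),
            )

    def test_deterministic_given_seed(self, small_world, growth_ref):
        _, provinces, children = small_world
        scenario = Scenario(coverage=0.5, delivery_type=2, mode="bernoulli", seed=5)
        a = run_scenario(children, provinces, growth_ref, EffectParams(), CostParams(), scenario)
        b = run_scenario(children, provinces, growth_ref, EffectParams(), CostParams(), scenario)
        pd.testing.assert_frame_equal(a.groups, b.groups)


class TestScenarioValidation:
    def test_effect_modifiers_mutually_exclusive(self):
        with pytest.raises(ValueError):
            Scenario(coverage=0.5, effect_multiplier=0.5, effect_override_cm=0.96)

    def test_coverage_bounds(self):
        with pytest.raises(ValueError):
            Scenario(coverage=1.5)


@pytest.fixture(scope="module")
def suite(small_world, growth_ref):
    _, provinces, children = small_world
    return sensitivity_suite(children, provinces, growth_ref)


class TestSensitivitySuite:

    def test_full_label_grid_present(self, suite):
        labels = {"base", "eff_halved", "eff_ci_lower", "transport_halved", "transport_doubled"}
        expected = {
            f"{lab}_cov{cov}_d{dt}" for lab in labels for cov in (25, 75) for dt in (1, 2)
        }
        assert set(suite) == expected

    def test_eff_halved_never_decreases_icer(self, suite):
        for cov in (25, 75):
            for dt in (1, 2):
                base = suite[f"base_cov{cov}_d{dt}"].groups["icer_rmb_per_case"]
                halved = suite[f"eff_halved_cov{cov}_d{dt}"].groups["icer_rmb_per_case"]
                mask = base.notna() & halved.notna()
                assert (halved[mask] >= base[mask] - 1e-9).all()

    def test_eff_ci_lower_uses_exact_bound(self, suite):
        res = suite["eff_ci_lower_cov75_d1"]
        assert res.scenario.effect_override_cm == 0.96
        assert res.scenario.effective_eff_cm(EffectParams()) == 0.96

    def test_transport_cost_ordering(self, suite):
        for cov in (25, 75):
            for dt in (1, 2):
                halved = suite[f"transport_halved_cov{cov}_d{dt}"].groups["total_cost_rmb"]
                base = suite[f"base_cov{cov}_d{dt}"].groups["total_cost_rmb"]
                doubled = suite[f"transport_doubled_cov{cov}_d{dt}"].groups["total_cost_rmb"]
                pos = base > 0
                assert (halved[pos] < base[pos]).all()
                assert (base[pos] < doubled[pos]).all()


class TestRankGroups:
    def test_sorted_ascending_with_na_last(self, base_run):
        _, _, result = base_run
        ranked = rank_groups(result)
        vals = ranked["icer_rmb_per_case"]
        defined = vals.dropna()
        assert list(defined) == sorted(defined)
        if vals.isna().any():
            assert vals.notna().to_numpy().argmin() >= len(defined)

    def test_all_na_preserves_group_order(self, small_world, growth_ref):
        _, provinces, children = small_world
        res = run_scenario(
            children, provinces, growth_ref, EffectParams(), CostParams(),
            Scenario(coverage=0.75, effect_multiplier=0.0),
        )
        ranked = rank_groups(res)
        expected = res.groups.sort_values(["province", "wealth"], kind="stable")
        assert list(ranked["province"]) == list(expected["province"])


class TestEquityDirection:
    def test_poor_icer_lower_in_majority_of_provinces(self, growth_ref):
        # poor groups concentrated just below the -2 threshold respond far
        # more to the shift, so poor ICERs should come out lower in most
        # provinces (the pro-poor direction is emergent, not forced)
        cfg = SimConfig(
            n_provinces=10,
            children_per_province=500,
            seed=31,
            haz_mean_poor=-1.8,
            haz_mean_nonpoor=-0.2,
            haz_province_spread=0.2,
            haz_sd=0.8,
        )
        provinces = generate_provinces(cfg)
        children = generate_children(cfg, provinces, growth_ref)
        res = run_scenario(
            children, provinces, growth_ref, EffectParams(), CostParams(),
            Scenario(coverage=0.75, delivery_type=1),
        )
        wide = res.groups.pivot(index="province", columns="wealth", values="icer_rmb_per_case")
        comparable = wide.dropna()
        poor_lower = (comparable["poor"] < comparable["nonpoor"]).sum()
        assert poor_lower > len(comparable) / 2


def test_icer_range_skips_na(base_run):
    _, _, result = base_run
    lo, hi = icer_range(result)
    vals = result.groups["icer_rmb_per_case"].dropna()
    assert lo == vals.min() and hi == vals.max()
    assert not math.isnan(lo)
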