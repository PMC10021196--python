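import numpy as np
import pytest

import diabesim as ds
from diabesim.scenarios import (InfoCampaign, ScenarioSpec, TrendMod, apply_scenario,
                                builtin_scenarios, dose_response, run_scenario)
from diabesim.trends import DriverBundle, TrendSeries


def _mini_bundle():
    bundle = DriverBundle()
    bundle.add(TrendSeries("mvpa", years=[2020.0, 2021.0, 2022.0],
                           values=[30.0, 28.0, 26.0]))
    bundle.add(TrendSeries("upf", years=[2020.0, 2021.0], values=[400.0, 410.0]))
    bundle.add(TrendSeries("ssb", years=[2020.0, 2021.0], values=[2.0, 2.1]))
    bundle.add(TrendSeries("fv", years=[2020.0, 2021.0], values=[1.5, 1.5]))
    return bundle


class TestApplyScenario:
    def test_scaling_preserves_relative_trend(self):
        spec = ScenarioSpec("double_mvpa", start_year=2020.0,
                            trend_mods=[TrendMod("mvpa", "scale", 2.0)])
        out = apply_scenario(_mini_bundle(), spec, grid=[2019.0, 2020.0, 2021.0, 2022.0])
        got = out.get("mvpa").value_at(np.array([2020.0, 2021.0, 2022.0]))
        assert np.allclose(got, [60.0, 56.0, 52.0])

    def test_pre_start_values_untouched(self):
        spec = ScenarioSpec("late", start_year=2021.0,
                            trend_mods=[TrendMod("mvpa", "scale", 2.0)])
        out = apply_scenario(_mini_bundle(), spec, grid=[2020.0, 2021.0, 2022.0])
        assert out.get("mvpa").value_at(2020.0) == pytest.approx(30.0)
        assert out.get("mvpa").value_at(2021.0) == pytest.approx(56.0)

    def test_unit_scale_is_identity(self):
        bundle = _mini_bundle()
        spec = ScenarioSpec("null", start_year=2020.0,
                            trend_mods=[TrendMod("mvpa", "scale", 1.0)])
        out = apply_scenario(bundle, spec, grid=[2020.0, 2021.0, 2022.0])
        years = np.array([2020.0, 2020.5, 2021.0, 2022.0])
        assert np.allclose(out.get("mvpa").value_at(years),
                           bundle.get("mvpa").value_at(years), rtol=0, atol=0)

    def test_baseline_bundle_untouched(self):
        bundle = _mini_bundle()
        before = bundle.get("upf").values.copy()
        apply_scenario(bundle, ScenarioSpec("x", 2020.0,
                                            [TrendMod("upf", "scale", 0.5)]))
        assert np.array_equal(bundle.get("upf").values, before)

    def test_fopl_composition_on_upf(self):
        # ssb scale 0.75 plus the FOPL block: upf gets only its own 0.87
        spec = ScenarioSpec("combo", start_year=2020.0,
                            trend_mods=[TrendMod("ssb", "scale", 0.75)],
                            info=InfoCampaign())
        out = apply_scenario(_mini_bundle(), spec, grid=[2020.0, 2021.0])
        assert np.allclose(out.get("upf").value_at(np.array([2020.0, 2021.0])),
                           [348.0, 356.7])
        assert out.get("ssb").value_at(2020.0) == pytest.approx(2.0 * 0.75 * 0.934)

    def test_scales_commute_then_adds(self):
        spec = ScenarioSpec("mix", start_year=2020.0,
                            trend_mods=[TrendMod("mvpa", "add", 10.0),
                                        TrendMod("mvpa", "scale", 2.0)])
        out = apply_scenario(_mini_bundle(), spec, grid=[2020.0, 2021.0, 2022.0])
        assert out.get("mvpa").value_at(2020.0) == pytest.approx(30.0 * 2 + 10)

    def test_unknown_variable_rejected(self):
        with pytest.raises(KeyError, match="tobacco"):
            apply_scenario(_mini_bundle(), ScenarioSpec(
                "bad", 2020.0, [TrendMod("tobacco", "scale", 0.5)]))

    def test_mod_validation(self):
        with pytest.raises(ValueError):
            TrendMod("ssb", "scale", -1.0)
        with pytest.raises(ValueError):
            TrendMod("ssb", "divide", 2.0)


class TestRunScenario:
    def test_null_scenario_identical_to_baseline(self, jamaica, baseline):
        spec = ScenarioSpec("null", start_year=2020.0)
        table = run_scenario(spec, jamaica.params, jamaica.bundle,
                             baseline_traj=baseline)
        assert np.all(table.frame["delta_pp"].to_numpy() == 0.0)
        assert table.dm_deaths_rel_change_2050 == 0.0

    def test_zero_magnitude_mods_bitwise_identical(self, jamaica, baseline):
        spec = ScenarioSpec("null_mods", start_year=2020.0,
                            trend_mods=[TrendMod("ssb", "scale", 1.0),
                                        TrendMod("mvpa", "add", 0.0)])
        scen = ds.simulate(jamaica.params, apply_scenario(jamaica.bundle, spec),
                           coverage=spec.coverage, coverage_start=spec.start_year)
        assert scen.frame.equals(baseline.frame)

    def test_relative_equals_absolute_over_baseline(self, jamaica, baseline):
        spec = builtin_scenarios()["ssb25"]
        table = run_scenario(spec, jamaica.params, jamaica.bundle,
                             baseline_traj=baseline)
        f = table.frame
        assert np.allclose(f["delta_rel_pct"], f["delta_pp"] / f["baseline"])

    def test_dsme_paradox(self, jamaica, baseline):
        # lowering DM mortality raises DM prevalence while lowering DM deaths
        table = run_scenario(builtin_scenarios()["dsme_only"], jamaica.params,
                             jamaica.bundle, baseline_traj=baseline)
        assert table.delta_pp("dm_prev", 2050.0) > 0
        assert table.dm_deaths_rel_change_2050 < 0

    def test_combined_dominates_components(self, jamaica, baseline):
        sc = builtin_scenarios()
        combined = run_scenario(sc["combined_intensive"], jamaica.params,
                                jamaica.bundle, baseline_traj=baseline)
        best = combined.delta_pp("dm_prev", 2050.0)
        for name in ("mvpa30", "ssb25", "upf25", "fv25", "lifestyle_only"):
            single = run_scenario(sc[name], jamaica.params, jamaica.bundle,
                                  baseline_traj=baseline)
            assert best <= single.delta_pp("dm_prev", 2050.0) + 1e-9, name


class TestBuiltinScenarios:
    def test_modest_upstream_contents(self):
        spec = builtin_scenarios()["modest_upstream"]
        mods = {(m.variable, m.mode): m.magnitude for m in spec.trend_mods}
        assert mods[("ssb", "scale")] == 0.85
        assert mods[("upf", "scale")] == 0.85
        assert mods[("fv", "scale")] == 1.15
        assert mods[("mvpa", "add")] == 15.0
        assert spec.info is not None

    def test_intensive_upstream_scales(self):
        spec = builtin_scenarios()["intensive_upstream"]
        mods = {(m.variable, m.mode): m.magnitude for m in spec.trend_mods}
        assert mods[("ssb", "scale")] == 0.75 and mods[("fv", "scale")] == 1.25
        assert mods[("mvpa", "add")] == 30.0

    def test_downstream_is_coverage_only(self):
        spec = builtin_scenarios()["downstream"]
        assert spec.trend_mods == [] and spec.info is None
        assert spec.coverage.lifestyle_cov == 0.25
        assert spec.coverage.dsme_cov == pytest.approx(1.0 / 3.0)

    def test_default_start_year(self):
        assert all(s.start_year == 2020.0 for s in builtin_scenarios().values())


class TestDoseResponse:
    def test_zero_level_gives_zero_delta(self, jamaica):
        curve = dose_response("ssb", [0.0, 0.25], [2030.0, 2050.0],
                              jamaica.params, jamaica.bundle)
        zero = curve[curve.level == 0.0]
        assert np.all(zero["delta_pp"] == 0.0)
        nonzero = curve[(curve.level == 0.25) & (curve.metric == "dm_prev")]
        assert np.all(nonzero["delta_pp"] < 0.0)

    def test_levels_must_be_sorted(self, jamaica):
        with pytest.raises(ValueError):
            dose_response("ssb", [0.5, 0.1], [2050.0], jamaica.params, jamaica.bundle)
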