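import numpy as np
import pytest

import diabesim as ds
from diabesim.core import advance_state, prevalence_series


def _state(ng, predm, dm):
    return ds.GlycemicState(year=2000.0, ng=ng, predm=predm, dm=dm,
                            weight=70.0, bmi=70.0 / 1.7**2)


def _flows(**kw):
    base = {k: 0.0 for k in ("ng_to_pre", "pre_to_ng", "pre_to_dm",
                             "deaths_ng", "deaths_pre", "deaths_dm")}
    base.update(kw)
    return base


class TestAdvanceState:
    def test_hand_euler_arithmetic(self):
        s = advance_state(_state(100.0, 20.0, 10.0),
                          _flows(ng_to_pre=5.0, pre_to_ng=1.0, pre_to_dm=2.0),
                          inflow=2.0, dt=1.0)
        assert np.allclose(s.ng, 98.0) and np.allclose(s.predm, 22.0)
        assert np.allclose(s.dm, 12.0)
        assert s.total == pytest.approx(2 * 132.0)  # per-sex copies

    def test_zero_flows_identity(self):
        s0 = _state(100.0, 20.0, 10.0)
        s1 = advance_state(s0, _flows(), inflow=0.0, dt=1.0)
        assert np.array_equal(s1.ng, s0.ng) and np.array_equal(s1.dm, s0.dm)

    def test_mortality_only_drains_dm(self):
        s = advance_state(_state(100.0, 20.0, 10.0), _flows(deaths_dm=3.0),
                          inflow=0.0, dt=1.0)
        assert np.allclose(s.dm, 7.0)
        assert s.total == pytest.approx(2 * 127.0)

    def test_bookkeeping_identity(self):
        s0 = _state(100.0, 20.0, 10.0)
        s1 = advance_state(s0, _flows(ng_to_pre=4.0, pre_to_dm=1.0, deaths_ng=0.5,
                                      deaths_pre=0.2, deaths_dm=0.3), inflow=2.0, dt=0.5)
        assert s1.total - s0.total == pytest.approx(0.5 * 2 * (2.0 - 1.0), rel=1e-12)

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            advance_state(_state(1, 1, 1), _flows(), inflow=0.0, dt=-1.0)

    def test_non_finite_flow_named(self):
        with pytest.raises(ValueError, match="pre_to_dm"):
            advance_state(_state(1, 1, 1), _flows(pre_to_dm=np.nan), inflow=0.0, dt=1.0)

    def test_overdrawn_stock_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="overdrawn"):
            s = advance_state(_state(100.0, 1.0, 10.0), _flows(pre_to_dm=5.0),
                              inflow=0.0, dt=1.0)
        assert np.all(s.predm == 0.0)


class TestSimConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            ds.SimConfig(t_start=2000, t_end=1990)
        with pytest.raises(ValueError):
            ds.SimConfig(dt=0.0)
        with pytest.raises(ValueError):
            ds.SimConfig(t_start=1990, t_end=2050, dt=0.7)
        assert ds.SimConfig(dt=0.25).n_steps == 240


class TestSimulate:
    def test_flat_world_is_an_equilibrium(self, flat_world):
        params, bundle = flat_world
        traj = ds.simulate(params, bundle)
        f = traj.frame
        for col in ("dm_prev", "predm_prev", "ng_prev", "ob_prev",
                    "weight_female", "weight_male"):
            assert np.allclose(f[col], f[col].iloc[0], rtol=0, atol=1e-12), col

    def test_deterministic_given_identical_inputs(self, jamaica):
        a = ds.simulate(jamaica.params, jamaica.bundle).frame
        b = ds.simulate(jamaica.params, jamaica.bundle).frame
        assert a.equals(b)

    def test_conservation_of_persons(self, jamaica, baseline):
        f = baseline.frame
        d_tot = np.diff(f["total"].to_numpy())
        inflow = np.array([sum(jamaica.bundle.value("inflow", y, s) for s in ds.SEXES)
                           for y in f["year"].to_numpy()[:-1]])
        deaths = f["total_deaths"].to_numpy()[1:]
        rel_err = np.abs(d_tot - (inflow - deaths)) / f["total"].to_numpy()[1:]
        assert np.max(rel_err) < 1e-9

    def test_stocks_never_negative_and_prevalences_partition(self, baseline):
        f = baseline.frame
        for col in ("ng_female", "ng_male", "predm_female", "predm_male",
                    "dm_female", "dm_male"):
            assert np.all(f[col] >= 0)
        assert np.allclose(f["dm_prev"] + f["predm_prev"] + f["ng_prev"], 1.0)
        for col in ("dm_prev", "predm_prev", "ob_prev"):
            assert np.all((f[col] >= 0) & (f[col] <= 1))

    def test_missing_driver_reported(self, jamaica):
        broken = jamaica.bundle.copy()
        del broken.series[("mvpa", None)]
        with pytest.raises((KeyError, ValueError), match="mvpa"):
            ds.simulate(jamaica.params, broken)

    def test_energy_failure_reports_year(self, jamaica):
        params = jamaica.params.copy()
        params.energy.forbes_k = 2.0  # absurd: one day's surplus moves kg
        with pytest.raises(ValueError, match="year"):
            ds.simulate(params, jamaica.bundle)

    def test_step_refinement_stability(self, jamaica, baseline):
        fine = ds.simulate(jamaica.params, jamaica.bundle, ds.SimConfig(dt=0.5))
        for col in ("dm_prev", "predm_prev", "ob_prev"):
            d = abs(fine.value(col, 2050.0) - baseline.value(col, 2050.0))
            assert d < 0.005, col

    def test_quarter_step_close_to_annual(self, jamaica, baseline):
        quarter = ds.simulate(jamaica.params, jamaica.bundle, ds.SimConfig(dt=0.25))
        d = abs(quarter.value("dm_prev", 2050.0) - baseline.value("dm_prev", 2050.0))
        assert d < 0.003


class TestTrajectoryAndPrevalences:
    def test_prevalence_is_stock_ratio(self, baseline):
        r = baseline.at(2030.0)
        total = sum(r[f"ng_{s}"] + r[f"predm_{s}"] + r[f"dm_{s}"] for s in ds.SEXES)
        assert r["dm_prev"] == pytest.approx((r["dm_female"] + r["dm_male"]) / total)

    def test_overall_obesity_is_population_weighted(self, baseline):
        r = baseline.at(2040.0)
        tot = {s: r[f"ng_{s}"] + r[f"predm_{s}"] + r[f"dm_{s}"] for s in ds.SEXES}
        expected = sum(r[f"ob_prev_{s}"] * tot[s] for s in ds.SEXES) / sum(tot.values())
        assert r["ob_prev"] == pytest.approx(expected, rel=1e-12)

    def test_equal_weights_example(self):
        # per-sex obesity 38.4% / 12.5% with equal sex weights -> 25.45%
        assert 0.5 * (0.384 + 0.125) == pytest.approx(0.2545)

    def test_prevalence_series_interface(self, baseline):
        s = prevalence_series(baseline, "dm")
        assert s.index[0] == 1990.0 and s.index[-1] == 2050.0
        sf = prevalence_series(baseline, "obesity", sex="female")
        assert sf.loc[2020.0] == pytest.approx(0.384, abs=1e-6)
        with pytest.raises(ValueError, match="metric"):
            prevalence_series(baseline, "bananas")
        with pytest.raises(ValueError):
            prevalence_series(baseline, "dm", sex="unknown")

    def test_empty_trajectory_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError, match="empty"):
            ds.Trajectory(pd.DataFrame())

    def test_tidy_export_roundtrip(self, baseline, tmp_path):
        path = tmp_path / "traj.csv"
        baseline.to_csv(path)
        import pandas as pd
        tidy = pd.read_csv(path)
        assert set(tidy.columns) == {"year", "sex", "variable", "value"}
        dm = tidy[(tidy.variable == "dm_prev") & (tidy.sex.isna())]
        assert len(dm) == 61
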