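import numpy as np
import pytest

import diabesim as ds


@pytest.fixture(scope="session")
def jamaica():
    return ds.jamaica_fixture()


@pytest.fixture(scope="session")
def baseline(jamaica):
    """Baseline 1990-2050 trajectory of the packaged Jamaica fixture."""
    return ds.simulate(jamaica.params, jamaica.bundle)


@pytest.fixture(scope="session")
def synth_truth():
    """Synthetic bundle with known ground-truth parameters + its trajectory."""
    cfg = ds.SynthConfig()
    bundle, params = ds.make_bundle(cfg)
    traj = ds.simulate(params, bundle)
    return cfg, bundle, params, traj


@pytest.fixture()
def flat_world():
    """A constant-driver world at energy equilibrium with no flows.

    All hazards, mortality and inflow are zero and intake exactly balances
    expenditure, so every stock, weight and prevalence must stay constant.
    """
    years = np.array([1990.0, 2050.0])
    energy = ds.EnergyParams()
    weight = np.array([65.0, 78.0])
    age, mvpa, ssb, fv, upf = 40.0, 45.0, 0.5, 1.5, 120.0
    rmr = ds.harris_benedict_rmr(list(ds.SEXES), weight, energy.height_cm, age, energy)
    act = ds.activity_expenditure(mvpa, weight, energy)
    intake = energy.paf * rmr + act
    other = intake - upf - ssb * energy.ssb_kcal_per_serving

    bundle = ds.DriverBundle()
    def const(name, value, sex=None):
        bundle.add(ds.TrendSeries(name, years=years, values=np.full(2, value), sex=sex))
    const("mvpa", mvpa), const("ssb", ssb), const("fv", fv), const("upf", upf)
    const("mean_age", age), const("m_base", 0.0)
    for i, sex in enumerate(ds.SEXES):
        const("inflow", 0.0, sex=sex)
        const("other_kcal", other[i], sex=sex)

    flows = ds.FlowParams(h_ng_pre=0.0, h_pre_ng=0.0, h_pre_dm=0.0, m_base=0.0,
                          ref=ds.ReferenceConditions(ssb=ssb, fv=fv, mvpa=mvpa,
                                                     ob_prev=np.array([0.3, 0.15]),
                                                     age_index=age))
    init = ds.InitialConditions(pop=np.array([500_000.0, 500_000.0]),
                                dm_share=np.array([0.08, 0.06]),
                                predm_share=np.array([0.15, 0.12]),
                                weight=weight)
    return ds.ModelParams(flows=flows, energy=energy, init=init), bundle
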