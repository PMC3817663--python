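"""Oil palm model: reserve pools, sigmoid expansion, postponement, senescence."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from sourcesink.palm import (
    PalmGenotype,
    PalmState,
    allocate_surplus,
    internode_demand,
    leaf_demand,
    mobilize_reserves,
    monthly_aggregates,
    nsc_concentration,
    sigmoid_fraction,
    simulate_palm,
)
from tests.conftest import constant_weather, irrigated_scenario, rainfed_scenario

DENSITY = 0.0143  # trees m-2


def test_leaf_and_internode_demand_pricing():
    assert leaf_demand(100.0, 1.44, 250.0) == pytest.approx(0.576)
    assert leaf_demand(0.0, 1.44, 250.0) == 0.0
    assert leaf_demand(100.0, 2.88, 250.0) == pytest.approx(1.152)  # linear in cost
    assert internode_demand(10.0, 1.3, 0.2) == pytest.approx(2.6)
    assert internode_demand(0.0, 1.3, 0.2) == 0.0


def test_sigmoid_fraction_normalized():
    g = PalmGenotype()
    t50, s = g.sigmoid_t50, g.sigmoid_scale
    assert sigmoid_fraction(0.0, t50, s) == pytest.approx(0.0, abs=1e-12)
    assert sigmoid_fraction(g.expansion_end_tt, t50, s) == pytest.approx(1.0)
    ages = np.linspace(0, g.expansion_end_tt, 500)
    fr = sigmoid_fraction(ages, t50, s)
    assert (np.diff(fr) >= 0).all()
    # Daily increment is maximal around the inflection point.
    inc = np.diff(sigmoid_fraction(np.arange(0, 1400, 10.0), t50, s))
    assert abs(np.argmax(inc) * 10 - t50) <= 20


def test_increments_sum_to_potential():
    g = PalmGenotype()
    ages = np.arange(0.0, g.active_duration, 11.5)
    fr = sigmoid_fraction(ages, g.sigmoid_t50, g.sigmoid_scale)
    total = np.diff(fr).sum() + fr[0]
    assert total == pytest.approx(1.0, rel=1e-3)


def test_allocate_surplus_proportional_to_headroom():
    adds, overflow = allocate_surplus(
        excess=100.0 / 3.0,
        reserves=np.array([0.0, 0.0]),
        capacities=np.array([30.0, 10.0]),
        reserve_ratio_storage=0.6,
    )
    assert adds == pytest.approx([15.0, 5.0])
    assert overflow == pytest.approx(100.0 / 3.0 - 20.0)
    # Full pools: everything overflows.
    adds, overflow = allocate_surplus(
        5.0, np.array([30.0, 10.0]), np.array([30.0, 10.0]), 0.6
    )
    assert adds == pytest.approx([0.0, 0.0]) and overflow == 5.0
    adds, overflow = allocate_surplus(0.0, np.array([1.0]), np.array([5.0]), 0.6)
    assert adds == pytest.approx([0.0]) and overflow == 0.0


def test_mobilize_reserves_proportional_to_offers():
    # Pools at full filling status: offers are mob_frac * reserve = 3 and 1.
    draws, mobilized = mobilize_reserves(
        2.0, np.array([30.0, 10.0]), np.array([30.0, 10.0]), mob_frac=0.1
    )
    assert mobilized == pytest.approx(2.0)
    assert draws == pytest.approx([1.5, 0.5])
    draws, mobilized = mobilize_reserves(
        0.0, np.array([30.0, 10.0]), np.array([30.0, 10.0]), 0.1
    )
    assert mobilized == 0.0
    draws, mobilized = mobilize_reserves(
        4.0, np.array([0.0, 0.0]), np.array([30.0, 10.0]), 0.1
    )
    assert mobilized == 0.0  # empty reserves: full postponement upstream


def test_nsc_concentration():
    assert nsc_concentration(70.0, 30.0) == pytest.approx(0.30)
    assert nsc_concentration(70.0, 0.0) == 0.0
    with pytest.raises(ValueError):
        nsc_concentration(0.0, 0.0)
    # A reserve-saturated leaf sits at 1 - min_sla/max_sla.
    g = PalmGenotype()
    area = 1000.0
    struct = area / g.max_sla
    reserve = area * g.leaf_reserve_capacity_per_area()
    assert nsc_concentration(struct, reserve) == pytest.approx(
        1.0 - g.min_sla / g.max_sla
    )


def test_leaf_production_accumulator_and_stress():
    g = PalmGenotype(prod_rate=0.01, leaf_appearance_th=0.2)
    state = PalmState.establish(g)
    acc0 = state.appear_acc
    n0 = state.leaf_age.size
    state.produce_leaves(d_tt=15.4, ftsw=1.0)
    assert state.appear_acc + (state.leaf_age.size - n0) - acc0 == pytest.approx(0.154)
    # At FTSW 0.1 with threshold 0.2 the production rate is halved.
    state2 = PalmState.establish(g)
    acc2 = state2.appear_acc
    n2 = state2.leaf_age.size
    state2.produce_leaves(d_tt=15.4, ftsw=0.1)
    assert state2.appear_acc + (state2.leaf_age.size - n2) - acc2 == pytest.approx(
        0.154 / 2
    )


def test_age_senescence_and_drought_acceleration(palm_genotype):
    g = palm_genotype
    state = PalmState.establish(g)
    oldest = state.leaf_age.max()
    state.senesce(d_tt=g.active_duration - oldest + 1.0, ftsw=1.0)
    assert not state.leaf_alive.all()
    # Identical twins, one droughted below the senescence threshold: the
    # stressed one loses its oldest leaves strictly earlier.
    wet = PalmState.establish(g)
    dry = PalmState.establish(g)
    for _ in range(30):
        wet.senesce(11.5, ftsw=1.0)
        dry.senesce(11.5, ftsw=0.1)
    assert dry.leaf_count() < wet.leaf_count()


def test_stress_free_run_reaches_potential_areas(palm_genotype):
    sc = irrigated_scenario(500, density=DENSITY, rain=0.0)
    res = simulate_palm(palm_genotype, sc)
    st = res.state
    done = st.leaf_alive & (st.leaf_age >= palm_genotype.expansion_end_tt)
    assert done.any()
    assert np.allclose(st.leaf_realized[done], st.leaf_potential[done], rtol=1e-3)


def test_postponement_conserves_growth_through_drought(palm_genotype):
    """A mid-life drought delays but never shrinks final leaf size."""
    tm, par, etp = 26.5, 8.5, 4.0
    rain = np.full(500, 8.0)
    rain[100:180] = 0.0  # hard dry-down, then full recovery
    weather = constant_weather(500, tm, par, etp).frame
    weather["water_in_mm"] = rain
    from sourcesink.weather import WeatherSeries

    sc = rainfed_scenario(WeatherSeries(weather), density=DENSITY, ttsw=150.0)
    res = simulate_palm(palm_genotype, sc)
    st = res.state
    f = res.frame
    assert f.ftsw.min() < 0.3  # the drought actually bit
    done = st.leaf_alive & (st.leaf_age >= palm_genotype.expansion_end_tt)
    assert done.sum() > 10
    assert np.allclose(st.leaf_realized[done], st.leaf_potential[done], rtol=1e-3)


def test_invariants_hold_daily(palm_genotype):
    sc = irrigated_scenario(200, density=DENSITY)
    simulate_palm(palm_genotype, sc, check_invariants_every=1)  # raises on breach


def test_carbon_budget_identity_each_day(palm_genotype):
    from sourcesink.scenarios import palm_sweep_scenario

    res = simulate_palm(palm_genotype, palm_sweep_scenario(-179.0))
    for b in res.budgets:
        b.check_conservation()


def test_trunk_nsc_declines_in_severe_dry_season():
    g = PalmGenotype(transpiration_th=0.1, leaf_appearance_th=0.1)
    from sourcesink.scenarios import palm_field_scenario

    sc = palm_field_scenario((-179.0, -2.0), years=2, seed=0)
    f = simulate_palm(g, sc).frame
    severe = f.iloc[245:365]
    assert severe.trunk_nsc_gg.iloc[-1] < severe.trunk_nsc_gg.max()
    assert severe.mobilized.sum() > 0


def test_end_nsc_nondecreasing_in_leaf_appearance_threshold():
    from sourcesink.scenarios import palm_sweep_scenario

    sc = palm_sweep_scenario(-179.0)
    ends = []
    for th in (0.02, 0.5, 1.0):
        g = PalmGenotype(transpiration_th=0.3, leaf_appearance_th=th)
        ends.append(simulate_palm(g, sc).frame.trunk_nsc_gg.iloc[-1])
    assert ends[0] <= ends[1] + 1e-9 and ends[1] <= ends[2] + 1e-9


def test_threshold_invariance_under_full_irrigation(palm_genotype):
    sc = irrigated_scenario(150, density=DENSITY)
    alt = dataclasses.replace(
        palm_genotype, transpiration_th=0.9, leaf_appearance_th=0.9,
        senescence_drought_th=0.9,
    )
    a = simulate_palm(palm_genotype, sc).frame
    b = simulate_palm(alt, sc).frame
    pd.testing.assert_frame_equal(a, b, check_exact=True)


def test_monthly_aggregates_units(palm_genotype):
    sc = irrigated_scenario(90, density=DENSITY)
    res = simulate_palm(palm_genotype, sc)
    monthly = monthly_aggregates(res)
    assert len(monthly) == 3
    assert monthly.supply_kg.iloc[0] == pytest.approx(
        res.frame.supply.iloc[:30].sum() / 1000.0
    )


def test_water_balance_closes(palm_genotype):
    from sourcesink.scenarios import palm_field_scenario

    sc = palm_field_scenario(-60.0, years=1, seed=2)
    f = simulate_palm(palm_genotype, sc).frame
    start = sc.soil.ttsw_mm * sc.soil.initial_fill
    lhs = f.swc.iloc[-1] - start
    rhs = (f.irrigation_mm + f.rain_mm - f.transpiration_mm - f.drainage_mm).sum()
    assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)
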