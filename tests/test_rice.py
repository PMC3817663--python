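"""Rice morphogenesis: development, expansion, demand, deficit responses."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from sourcesink.rice import (
    RiceAxis,
    RiceGenotype,
    RiceLeaf,
    daily_expansion,
    predimension_leaf,
    schedule_initiation,
    simulate_rice,
    structural_demand,
    structural_sla,
)
from tests.conftest import irrigated_scenario, rainfed_scenario, constant_weather


def test_schedule_initiation_threshold_crossings():
    axis = RiceAxis(axis_id=0, thermal_time=49.0)
    assert schedule_initiation(axis, 2.0, 50.0) == 1
    assert schedule_initiation(axis, 0.0, 50.0) == 0
    fresh = RiceAxis(axis_id=1)
    total = sum(schedule_initiation(fresh, 10.0, 50.0) for _ in range(20))
    assert total == math.floor(200.0 / 50.0)  # 4 phytomers after 200 degCd


def test_predimension_increment_rule():
    assert predimension_leaf(20.0, 10.0, 1.2) == 30.0
    assert predimension_leaf(20.0, 10.0, 0.5) == 25.0  # increment scaled by Ic
    assert predimension_leaf(20.0, 10.0, 0.0) == 20.0  # never shrinks


def test_structural_sla_and_demand():
    assert structural_sla(1, 450.0, 0.3) == 450.0  # rank 1 uses the reference
    assert structural_demand(10.0, 1, 200.0, 0.0) == pytest.approx(0.05)
    # demand per cm2 decreases with rank when sla_p > 0
    costs = [structural_demand(1.0, r, 450.0, 0.3) for r in range(1, 12)]
    assert all(a > b for a, b in zip(costs, costs[1:]))
    with pytest.raises(ValueError):
        structural_sla(3, 100.0, -2.0)  # negative SLA


def test_daily_expansion_stress_and_caps():
    g = RiceGenotype(ler_th=0.4)
    leaf = RiceLeaf(axis_id=0, rank=1, potential_final_length=50.0, length=10.0)
    dl_full, _ = daily_expansion(leaf, g, d_tt=10.0, ftsw=1.0)
    assert dl_full == pytest.approx(50.0 / 50.0 * 10.0)
    dl_half, _ = daily_expansion(leaf, g, d_tt=10.0, ftsw=0.2)
    assert dl_half == pytest.approx(dl_full / 2.0)  # FTSW 0.2 at th 0.4
    leaf.length = 49.5
    dl_cap, _ = daily_expansion(leaf, g, d_tt=10.0, ftsw=1.0)
    assert dl_cap == pytest.approx(0.5)
    leaf.status = "mature"
    assert daily_expansion(leaf, g, 10.0, 1.0) == (0.0, 0.0)


def test_main_stem_leaf_count_follows_plastochron(rice_genotype):
    # 300 degCd at 25.4 degC over tbase 12 -> floor(300/50) = 6 leaves.
    days = math.ceil(300.0 / (25.4 - rice_genotype.tbase))
    sc = irrigated_scenario(days, density=30.0, tmean=25.4, par=7.6, etp=1.85)
    res = simulate_rice(rice_genotype, sc)
    main = res.state.axes[0]
    assert main.thermal_time >= 300.0
    assert len(main.leaves) == 6


def test_potential_lengths_increase_by_mgc_when_unlimited():
    # Saturating supply keeps Ic >= 1 whenever a pre-dimensioning happens.
    g = RiceGenotype(rue=100.0, ict=1e9)  # no tillering, carbon-rich
    sc = irrigated_scenario(40, density=30.0, tmean=25.4, par=7.6, etp=1.85)
    res = simulate_rice(g, sc)
    pots = [lf.potential_final_length for lf in res.state.axes[0].leaves]
    assert len(pots) > 4
    diffs = np.diff(pots)
    assert np.allclose(diffs, g.mgc)


def test_tillering_threshold_comparative(short_severe):
    base = RiceGenotype()
    low = dataclasses.replace(base, ict=0.5)
    high = dataclasses.replace(base, ict=1.5)
    n_low = simulate_rice(low, short_severe).frame.tiller_count.iloc[-1]
    n_high = simulate_rice(high, short_severe).frame.tiller_count.iloc[-1]
    assert n_low >= n_high


def test_green_biomass_nondecreasing_without_deficit(rice_genotype, short_severe):
    f = simulate_rice(rice_genotype, short_severe).frame
    ok = f.deficit.to_numpy()[:-1] <= 1e-12
    diffs = np.diff(f.green_biomass_g.to_numpy())
    assert (diffs[ok] >= -1e-12).all()


def test_structural_biomass_never_decreases(rice_genotype, long_moderate):
    f = simulate_rice(rice_genotype, long_moderate).frame
    total = f.structural_biomass_g + f.root_mass_g
    assert (np.diff(total.to_numpy()) >= -1e-12).all()


def test_trajectory_deterministic(rice_genotype, short_severe):
    a = simulate_rice(rice_genotype, short_severe).frame
    b = simulate_rice(rice_genotype, short_severe).frame
    pd.testing.assert_frame_equal(a, b, check_exact=True)


def test_lower_transpiration_threshold_uses_more_water(short_severe):
    base = RiceGenotype()
    lo = dataclasses.replace(base, transpiration_th=0.1)
    hi = dataclasses.replace(base, transpiration_th=0.9)
    w_lo = simulate_rice(lo, short_severe).frame.transpiration_mm.sum()
    w_hi = simulate_rice(hi, short_severe).frame.transpiration_mm.sum()
    assert w_lo >= w_hi


def test_sustained_total_deficit_leads_to_decline_and_death():
    """No water at all: biomass plateaus, declines, and the plant dies."""
    g = RiceGenotype()
    weather = constant_weather(120, tmean=25.4, par=7.6, etp=1.85)
    sc = rainfed_scenario(weather, density=30.0, ttsw=8.0, footprint=0.01)
    f = simulate_rice(g, sc).frame
    assert not f.alive.iloc[-1]
    peak = f.green_biomass_g.max()
    assert f.green_biomass_g.iloc[-1] < 0.5 * peak


def test_deficit_day_senesces_oldest_leaves_first(rice_genotype):
    weather = constant_weather(60, tmean=25.4, par=7.6, etp=1.85)
    sc = rainfed_scenario(weather, density=30.0, ttsw=20.0, footprint=0.01)
    res = simulate_rice(rice_genotype, sc)
    main = res.state.axes[0]
    senesced = [lf.senesced_area > 1e-9 for lf in main.leaves]
    if any(senesced):
        # Senescence is contiguous from the oldest ranks upward.
        first_intact = senesced.index(False) if False in senesced else len(senesced)
        assert all(senesced[:first_intact])
        assert not any(senesced[first_intact + 1 :][:1])


def test_water_balance_closes(rice_genotype, long_moderate):
    f = simulate_rice(rice_genotype, long_moderate).frame
    start = long_moderate.soil.ttsw_mm * long_moderate.soil.initial_fill
    lhs = f.swc.iloc[-1] - start
    rhs = (f.irrigation_mm + f.rain_mm - f.transpiration_mm - f.drainage_mm).sum()
    assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)
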