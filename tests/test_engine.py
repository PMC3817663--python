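"""Unit and property tests for the daily carbon-water core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sourcesink.engine import (
    NO_DEMAND,
    ClimateDay,
    SoilBucket,
    compute_ftsw,
    daily_supply,
    index_of_competition,
    intercept_fraction,
    resolve_budget,
    step_soil,
    stress_factor,
    thermal_time_increment,
)
from tests.conftest import bucket


@pytest.mark.parametrize(
    "tmean,tbase,expected",
    [(25.4, 10.0, 15.4), (8.0, 10.0, 0.0), (10.0, 10.0, 0.0)],
)
def test_thermal_time_floors_at_zero(tmean, tbase, expected):
    assert thermal_time_increment(tmean, tbase) == pytest.approx(expected)


@pytest.mark.parametrize(
    "swc,expected",
    [(50.0, 1.0), (10.0, 0.0), (30.0, 0.5)],
)
def test_ftsw_is_linear_between_limits(swc, expected):
    assert compute_ftsw(bucket(swc)) == pytest.approx(expected)


def test_ftsw_requires_fc_above_min():
    with pytest.raises(ValueError):
        SoilBucket(swc=5.0, swc_fc=5.0, swc_min=5.0)


@pytest.mark.parametrize(
    "ftsw,th,expected",
    [
        (0.6, 0.5, 1.0),  # above threshold: unaffected
        (0.25, 0.5, 0.5),  # linear branch FTSW / threshold
        (0.0, 0.5, 0.0),  # dry limit
        (0.5, 0.0, 1.0),  # zero threshold: drought-insensitive
        (0.0, 0.0, 1.0),
    ],
)
def test_stress_factor_broken_stick(ftsw, th, expected):
    assert stress_factor(ftsw, th) == expected


@given(
    ftsw=st.floats(0, 1),
    th=st.floats(0, 1),
    dth=st.floats(0.001, 0.5),
)
@settings(deadline=None, derandomize=True)
def test_stress_factor_monotonicity(ftsw, th, dth):
    """Non-decreasing in FTSW; non-increasing in the threshold."""
    eps = 1e-6
    assert stress_factor(min(1.0, ftsw + eps), th) >= stress_factor(ftsw, th) - 1e-12
    hi = min(1.0, th + dth)
    assert stress_factor(ftsw, hi) <= stress_factor(ftsw, th) + 1e-12


@given(ftsw=st.floats(0, 1), th=st.floats(0.01, 1))
@settings(deadline=None, derandomize=True)
def test_stress_factor_continuity(ftsw, th):
    eps = 1e-9
    up = stress_factor(min(1.0, ftsw + eps), th)
    assert abs(up - stress_factor(ftsw, th)) < 1e-6


def test_intercept_fraction_limits():
    assert intercept_fraction(0.0, 0.5) == 0.0
    assert intercept_fraction(4.0, 0.5) == pytest.approx(1 - math.exp(-2.0), abs=1e-4)
    assert intercept_fraction(200.0, 0.5) == pytest.approx(1.0)


def test_daily_supply_worked_example():
    clim = ClimateDay(0, 25.4, par=7.6, etp=1.85)
    got = daily_supply(clim, fint=0.5, rue=4.0, transp_stress=1.0, density=30.0)
    assert got == pytest.approx(7.6 * 0.5 * 4.0 / 30.0)  # 0.5067
    assert daily_supply(ClimateDay(0, 25.0, 0.0, 1.0), 0.5, 4.0, 1.0, 30.0) == 0.0
    assert daily_supply(clim, 0.5, 4.0, 0.0, 30.0) == 0.0  # stomata shut


def test_index_of_competition():
    assert index_of_competition(4.0, 4.0) == 1.0
    assert index_of_competition(2.0, 4.0) == 0.5
    sentinel = index_of_competition(2.0, 0.0)
    assert sentinel == NO_DEMAND and sentinel >= 1.0


class TestResolveBudget:
    def test_surplus_splits_store_and_overflow(self):
        b = resolve_budget(10.0, 8.0, 0.0, 0.5, 0.4, math.inf)
        assert b.growth_realized == 8.0
        assert b.stored == pytest.approx(1.0)
        assert b.overflow == pytest.approx(1.0)
        assert b.deficit == 0.0
        b.check_conservation()

    def test_deficit_covered_by_mobilization(self):
        b = resolve_budget(5.0, 8.0, 10.0, 0.5, 0.4, math.inf)
        assert b.mobilized == pytest.approx(3.0)  # of 4.0 mobilizable
        assert b.growth_realized == pytest.approx(8.0)
        assert b.reserve == pytest.approx(7.0)
        assert b.deficit == 0.0

    def test_deficit_beyond_reserve(self):
        b = resolve_budget(5.0, 8.0, 2.0, 0.5, 1.0, math.inf)
        assert b.mobilized == pytest.approx(2.0)
        assert b.growth_realized == pytest.approx(7.0)
        assert b.deficit == pytest.approx(1.0)

    def test_storage_respects_capacity(self):
        b = resolve_budget(10.0, 2.0, 3.0, 1.0, 0.0, reserve_capacity=4.0)
        assert b.stored == pytest.approx(1.0)
        assert b.overflow == pytest.approx(7.0)

    @given(
        supply=st.floats(0, 100),
        demand=st.floats(0, 100),
        reserve=st.floats(0, 50),
        sf=st.floats(0, 1),
        mf=st.floats(0, 1),
        headroom=st.floats(0, 50),
    )
    @settings(deadline=None, derandomize=True)
    def test_conservation_property(self, supply, demand, reserve, sf, mf, headroom):
        b = resolve_budget(supply, demand, reserve, sf, mf, reserve + headroom)
        b.check_conservation()
        assert b.deficit >= 0 and b.stored >= 0 and b.overflow >= -1e-12


class TestStepSoil:
    def test_idle_day_changes_nothing(self):
        b0 = bucket(30.0)
        b1, transp, drain = step_soil(b0, 0.0, 0.5, 0.0)
        assert (b1.swc, transp, drain) == (30.0, 0.0, 0.0)

    def test_unstressed_draw(self):
        b0 = bucket(50.0)
        b1, transp, _ = step_soil(b0, 5.0, 0.5, 0.0)
        assert transp == pytest.approx(5.0)
        assert b1.swc == pytest.approx(45.0)

    def test_empty_store_stops_transpiration(self):
        b0 = bucket(10.0)  # at swc_min
        b1, transp, _ = step_soil(b0, 5.0, 0.5, 0.0)
        assert transp == 0.0
        assert b1.swc == 10.0

    def test_excess_water_drains(self):
        b0 = bucket(48.0)
        b1, transp, drain = step_soil(b0, 0.0, 0.5, 10.0)
        assert b1.swc == 50.0
        assert drain == pytest.approx(8.0)

    @given(
        forcing=st.lists(
            st.tuples(st.floats(0, 20), st.floats(0, 30)), min_size=1, max_size=60
        ),
        th=st.floats(0, 1),
        fill=st.floats(0, 1),
    )
    @settings(deadline=None, derandomize=True)
    def test_ftsw_stays_in_unit_interval_and_water_balances(self, forcing, th, fill):
        b = SoilBucket(swc=10.0 + 40.0 * fill, swc_fc=50.0, swc_min=10.0)
        start = b.swc
        total_in = total_out = 0.0
        for pot, rain in forcing:
            b, transp, drain = step_soil(b, pot, th, rain)
            assert 0.0 <= compute_ftsw(b) <= 1.0
            total_in += rain
            total_out += transp + drain
        assert b.swc - start == pytest.approx(total_in - total_out, rel=1e-9, abs=1e-9)
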